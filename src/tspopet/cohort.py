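"""Cohort-level pipeline orchestration and nonparametric statistics.

Implements the study-level quantities of a dual-tracer neuroinflammation
comparison: per-scan 40-60 min uptake summaries (%ID/cm^3) and
core/contralateral ratios, exact paired Wilcoxon signed-rank and unpaired
Mann-Whitney tests at the small sample sizes typical of preclinical work,
Spearman correlation between reference inputs, and :func:`run_study`, which
chains simulation, kinetic segmentation, class-database training, SRTM
fitting under contralateral / cerebellar / cluster-derived reference inputs
and the statistical comparisons into a reproducible report bundle.

Exact p-values are two-sided and computed by enumeration (dynamic
programming over rank sums) with average ranks for ties; zero differences
are dropped before ranking, following Wilcoxon's original prescription. No
multiple-testing correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TimeActivityCurve, extract_roi_tac, to_percent_id, window_mean
from .reference import build_class_database
from .segmentation import label_rois, segment_kinetic
from .simulate import CohortConfig, GroupSpec, default_training_groups, plan_cohort, realize_scan
from .srtm import fit_srtm_roiset

EXACT_WILCOXON_MAX_N = 25
EXACT_MANNWHITNEY_MAX_N = 20


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: int
    direction: str = ""        # sign of the median effect, "+", "-" or "0"
    method: str = "exact"
    rho: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["rho"] is None:
            del d["rho"]
        return d


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------


def core_contralateral_ratio(
    core: TimeActivityCurve, contralateral: TimeActivityCurve,
    window: tuple = (40.0, 60.0),
) -> float:
    """Ratio of core to contralateral window-mean uptake."""
    denom = window_mean(contralateral, *window)
    if denom <= 0:
        raise ValueError("contralateral window mean must be > 0")
    return window_mean(core, *window) / denom


# ---------------------------------------------------------------------------
# Exact rank tests
# ---------------------------------------------------------------------------


def _subset_sum_counts(values: np.ndarray) -> np.ndarray:
    """counts[s] = number of subsets with element sum s (integer values)."""
    total = int(values.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for v in values:
        v = int(v)
        counts[v:] += counts[: counts.size - v].copy()
    return counts


def wilcoxon_signed_rank_exact(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test, exact by enumeration for
    n <= 25 non-zero pairs (normal approximation with tie correction above).

    Zero differences are dropped; tied absolute differences receive average
    ranks.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    direction = "+" if np.median(d) > 0 else ("-" if np.median(d) < 0 else "0")

    if n <= EXACT_WILCOXON_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)      # doubled ranks are integers
        counts = _subset_sum_counts(r2)
        w2 = int(round(2 * w_plus))
        total = 2.0**n
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal-approx"
    return TestResult("wilcoxon_signed_rank", w_plus, float(p), n, direction, method)


def mann_whitney_exact(group_x, group_y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for
    n_x + n_y <= 20 (tie-corrected normal approximation above).
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = float(ranks[:nx].sum())
    u_x = rx - nx * (nx + 1) / 2.0
    direction = "+" if np.median(x) > np.median(y) else ("-" if np.median(x) < np.median(y) else "0")

    if nx + ny <= EXACT_MANNWHITNEY_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)
        total_sum = int(r2.sum())
        # dp[k, s] = number of size-k subsets of the pooled ranks with sum s
        dp = np.zeros((nx + 1, total_sum + 1))
        dp[0, 0] = 1.0
        for v in r2:
            dp[1:, v:] += dp[:-1, : total_sum + 1 - v].copy()
        dist = dp[nx]
        n_subsets = dist.sum()
        rx2 = int(round(2 * rx))
        p_le = dist[: rx2 + 1].sum() / n_subsets
        p_ge = dist[rx2:].sum() / n_subsets
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = nx * ny / 2.0
        n = nx + ny
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = nx * ny / 12.0 * (n + 1 - tie_term)
        z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal-approx"
    return TestResult("mann_whitney_u", float(u_x), float(p), nx + ny, direction, method)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector has no rank correlation")
    return float(sps.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Study configuration and per-scan summaries
# ---------------------------------------------------------------------------


def _default_cohort_with_controls() -> CohortConfig:
    base = CohortConfig()
    return CohortConfig(
        groups=base.groups + (GroupSpec("controls", 4, ("GE180",), kind="control"),)
    )


@dataclass
class StudyConfig:
    """Everything :func:`run_study` needs, serializable for exact rerun."""

    cohort: CohortConfig = field(default_factory=_default_cohort_with_controls)
    training_n: int = 6
    training_tracer: str = "PK11195"
    segmentation_k: int = 6
    min_region_size: int = 10
    purity_threshold: float = 0.9
    window: tuple = (40.0, 60.0)
    references: tuple = ("contralateral", "cerebellum", "cluster")


@dataclass
class ScanSummary:
    animal_id: str
    group: str
    tracer: str
    uptake: dict               # role -> window-mean %ID/cm^3
    ratio: float
    bp_nd: dict                # reference -> core BP_ND
    r1: dict                   # reference -> core R1


def summarize_scan(record, config: StudyConfig, class_db=None) -> ScanSummary:
    """Segment, label and fit one scan under the configured references."""
    image_pct = to_percent_id(record.image)
    brain_mask = record.truth.brain_mask
    seg = segment_kinetic(
        image_pct, brain_mask, k=config.segmentation_k,
        seed=record.plan.seed, min_region_size=config.min_region_size,
    )
    rois = label_rois(seg, record.truth.mask("cerebellum"), brain_mask,
                      window=config.window)

    uptake = {}
    for role in ("core", "edge1", "edge2", "edge3", "contralateral", "cerebellum"):
        if role in rois.present_roles():
            tac = extract_roi_tac(image_pct, rois.mask_for_role(role))
            uptake[role] = window_mean(tac, *config.window)
    ratio = uptake["core"] / uptake["contralateral"]

    bp_nd, r1 = {}, {}
    for reference in config.references:
        table = fit_srtm_roiset(
            image_pct, rois, reference=reference, class_db=class_db,
            brain_mask=brain_mask, purity_threshold=config.purity_threshold,
        )
        core_row = table[table["roi"] == "core"].iloc[0]
        bp_nd[reference] = float(core_row["BPND"])
        r1[reference] = float(core_row["R1"])
    return ScanSummary(
        animal_id=record.plan.animal_id,
        group=record.plan.group,
        tracer=record.plan.tracer,
        uptake=uptake,
        ratio=ratio,
        bp_nd=bp_nd,
        r1=r1,
    )


def train_class_database(config: StudyConfig, cohort_config: CohortConfig, seed: int):
    """Build the clustering class database from a stroke-like training
    cohort put through the same segmentation/labelling chain."""
    from dataclasses import replace

    train_cfg = replace(
        cohort_config,
        groups=default_training_groups(config.training_n, config.training_tracer),
    )
    training = []
    for plan in plan_cohort(train_cfg, seed):
        rec = realize_scan(plan, train_cfg)
        image_pct = to_percent_id(rec.image)
        seg = segment_kinetic(
            image_pct, rec.truth.brain_mask, k=config.segmentation_k,
            seed=plan.seed, min_region_size=config.min_region_size,
        )
        rois = label_rois(seg, rec.truth.mask("cerebellum"), rec.truth.brain_mask,
                          window=config.window)
        training.append((image_pct, rois))
    return build_class_database(training)


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    uptake_table: pd.DataFrame
    bpnd_table: pd.DataFrame
    stats: dict
    config: StudyConfig
    seed: int

    def to_dir(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.uptake_table.to_csv(outdir / "uptake_table.tsv", sep="\t",
                                 index=False, float_format="%.6g")
        self.bpnd_table.to_csv(outdir / "bpnd_table.tsv", sep="\t",
                               index=False, float_format="%.6g")
        (outdir / "stats.json").write_text(json.dumps(self.stats, indent=1, sort_keys=True))
        manifest = {
            "seed": self.seed,
            "config": json.loads(json.dumps(asdict(self.config), default=str)),
            "note": "no multiple-testing correction applied",
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return outdir


def run_study(config: StudyConfig | None = None, seed: int = 0,
              outdir=None) -> StudyReport:
    """Execute the full pipeline on a synthetic study and assemble the
    report bundle (uptake table, BP_ND table, paired/unpaired statistics).

    With a fixed seed the report tables are byte-identical across runs.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    training_seed = int(rng.integers(0, 2**31 - 1))
    cohort_seed = int(rng.integers(0, 2**31 - 1))

    class_db = None
    if "cluster" in config.references:
        class_db = train_class_database(config, config.cohort, training_seed)

    summaries = []
    for plan in plan_cohort(config.cohort, cohort_seed):
        record = realize_scan(plan, config.cohort)
        summaries.append(summarize_scan(record, config, class_db=class_db))

    uptake_rows, bpnd_rows = [], []
    for s in summaries:
        row = {"animal_id": s.animal_id, "group": s.group, "tracer": s.tracer}
        for role in ("core", "contralateral", "cerebellum", "edge1", "edge2", "edge3"):
            row[role] = s.uptake.get(role, float("nan"))
        row["core_contralateral_ratio"] = s.ratio
        uptake_rows.append(row)
        for reference in config.references:
            bpnd_rows.append(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "tracer": s.tracer,
                    "reference": reference,
                    "BPND_core": s.bp_nd[reference],
                    "R1_core": s.r1[reference],
                }
            )
    uptake_table = pd.DataFrame(uptake_rows)
    bpnd_table = pd.DataFrame(bpnd_rows)

    stats = _study_statistics(uptake_table, bpnd_table, config)
    report = StudyReport(uptake_table, bpnd_table, stats, config, seed)
    if outdir is not None:
        report.to_dir(outdir)
    return report


def _dual_groups(config: StudyConfig):
    for g in config.cohort.groups:
        if len(g.tracers) == 2 and g.kind == "lps":
            yield g


def _study_statistics(uptake: pd.DataFrame, bpnd: pd.DataFrame,
                      config: StudyConfig) -> dict:
    stats: dict = {"paired": {}, "unpaired": {}, "spearman": {}}

    for g in _dual_groups(config):
        t1, t2 = g.tracers
        sub = uptake[uptake["group"] == g.name].sort_values(["animal_id", "tracer"])
        r1v = sub[sub["tracer"] == t1].set_index("animal_id")["core_contralateral_ratio"]
        r2v = sub[sub["tracer"] == t2].set_index("animal_id")["core_contralateral_ratio"]
        common = r1v.index.intersection(r2v.index)
        test = wilcoxon_signed_rank_exact(r2v[common].to_numpy(), r1v[common].to_numpy())
        stats["paired"][f"{g.name}_ratio_{t2}_vs_{t1}"] = test.to_dict()
        for reference in config.references:
            bsub = bpnd[(bpnd["group"] == g.name) & (bpnd["reference"] == reference)]
            b1 = bsub[bsub["tracer"] == t1].set_index("animal_id")["BPND_core"]
            b2 = bsub[bsub["tracer"] == t2].set_index("animal_id")["BPND_core"]
            test = wilcoxon_signed_rank_exact(b2[common].to_numpy(), b1[common].to_numpy())
            stats["paired"][f"{g.name}_BPND_{reference}_{t2}_vs_{t1}"] = test.to_dict()
        # contralateral vs cluster / cerebellum reference, within group
        for reference in config.references:
            if reference == "contralateral":
                continue
            bsub = bpnd[bpnd["group"] == g.name]
            a = bsub[bsub["reference"] == "contralateral"].sort_values(
                ["animal_id", "tracer"])["BPND_core"].to_numpy()
            b = bsub[bsub["reference"] == reference].sort_values(
                ["animal_id", "tracer"])["BPND_core"].to_numpy()
            test = wilcoxon_signed_rank_exact(b, a)
            stats["paired"][f"{g.name}_BPND_{reference}_vs_contralateral"] = test.to_dict()
            stats["spearman"][f"{g.name}_BPND_contralateral_vs_{reference}"] = (
                spearman_rho(a, b)
            )

    # unpaired tracer comparisons on ratios (all scans of each F-18 tracer)
    lps_groups = {g.name for g in config.cohort.groups if g.kind == "lps"}
    lps = uptake[uptake["group"].isin(lps_groups)]
    by_tracer = {t: lps[lps["tracer"] == t]["core_contralateral_ratio"].to_numpy()
                 for t in lps["tracer"].unique()}
    tracers = sorted(by_tracer)
    for i, ta in enumerate(tracers):
        for tb in tracers[i + 1:]:
            test = mann_whitney_exact(by_tracer[ta], by_tracer[tb])
            stats["unpaired"][f"ratio_{ta}_vs_{tb}"] = test.to_dict()

    # pooled LPS contralateral uptake vs control low-uptake region
    control_groups = {g.name for g in config.cohort.groups if g.kind == "control"}
    if control_groups:
        ctrl = uptake[uptake["group"].isin(control_groups)]["contralateral"].to_numpy()
        lps_contra = lps["contralateral"].to_numpy()
        if ctrl.size and lps_contra.size:
            test = mann_whitney_exact(lps_contra, ctrl)
            stats["unpaired"]["contralateral_lps_vs_control"] = test.to_dict()
    return stats
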