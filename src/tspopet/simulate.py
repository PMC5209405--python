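"""Synthetic dynamic-PET cohort generator with known ground truth.

Emulates 60-min rodent TSPO-PET studies of focal neuroinflammation: an
arterial-like input function drives one-tissue-compartment reference
kinetics; lesioned tissue (a focal high-binding core with a surrounding
uptake gradient), cerebellum (distinct perfusion, optionally mild specific
binding) and binding-free normal tissue are generated from the SRTM forward
model; frames follow the default 16-frame histogramming and noise scales
with frame duration and physical decay.

Geometry is deliberately schematic — labelled geometric regions inside an
ellipsoidal brain on a 64x64x64 grid at scanner voxel size — because the
quantification chain under test operates on kinetics, not anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DynamicImage,
    FrameSchedule,
    TimeActivityCurve,
    decay_constant,
    write_dynamic,
)
from .srtm import (
    SrtmParams,
    convolve_exp,
    fine_time_grid,
    frame_average,
    srtm_forward,
)

# ---------------------------------------------------------------------------
# Arterial-like input function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputFunction:
    """Tri-exponential plasma input with a linear rise (Feng-style).

    For ``t >= delay`` (with ``u = t - delay``):

        C_p(u) = (A1*u - A2 - A3) * exp(-l1*u) + A2*exp(-l2*u) + A3*exp(-l3*u)

    and 0 before the delay; the form is continuous at the delay and is
    clipped at zero. A1 is in kBq/cm^3/min, A2 and A3 in kBq/cm^3, the decay
    rates l1 > l2 >= l3 >= 0 in 1/min.
    """

    A1: float
    A2: float
    A3: float
    l1: float
    l2: float
    l3: float
    delay: float = 0.5

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 >= self.l3 >= 0):
            raise ValueError("decay rates must satisfy l1 > l2 >= l3 >= 0")
        if self.A1 < 0:
            raise ValueError("A1 must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = t - self.delay
        with np.errstate(over="ignore"):
            val = (
                (self.A1 * u - self.A2 - self.A3) * np.exp(-self.l1 * u)
                + self.A2 * np.exp(-self.l2 * u)
                + self.A3 * np.exp(-self.l3 * u)
            )
        val = np.where(u >= 0, val, 0.0)
        return np.clip(val, 0.0, None)


#: Default input: Feng-type shape scaled so that the default reference
#: tissue (K1 = 0.12 ml/cm^3/min, k2 = 0.25 /min) averages ~16 kBq/cm^3 over
#: 40-60 min — i.e. ~0.08 %ID/cm^3 at the default 20 MBq injected dose,
#: matching healthy-tissue uptake in rodent TSPO scans.
DEFAULT_INPUT_SCALE = 2.4145
DEFAULT_INPUT = InputFunction(
    A1=851.1 * DEFAULT_INPUT_SCALE,
    A2=20.81 * DEFAULT_INPUT_SCALE,
    A3=21.88 * DEFAULT_INPUT_SCALE,
    l1=4.134,
    l2=0.119,
    l3=0.0104,
    delay=0.5,
)


#: Step (minutes) of the simulators' fine grid. Finer than the SRTM
#: convolution grid because the bolus peak of the input function has much
#: higher curvature than any tissue curve.
SIM_GRID_STEP_MIN = 0.01


def input_function(params: InputFunction, schedule: FrameSchedule) -> TimeActivityCurve:
    """Frame-averaged input function on a schedule (for plotting/inspection)."""
    t_fine = fine_time_grid(schedule, SIM_GRID_STEP_MIN)
    values = frame_average(params(t_fine), schedule, SIM_GRID_STEP_MIN)
    return TimeActivityCurve(schedule=schedule, values=values, units="kBq/cm3")


# ---------------------------------------------------------------------------
# Compartment-model simulators
# ---------------------------------------------------------------------------


def _fine_input(cp, schedule: FrameSchedule):
    t_fine = fine_time_grid(schedule, SIM_GRID_STEP_MIN)
    return t_fine, cp(t_fine) if callable(cp) else np.asarray(cp, dtype=float)


def simulate_1tc(cp, K1: float, k2: float, schedule: FrameSchedule) -> TimeActivityCurve:
    """One-tissue-compartment TAC: C(t) = K1 * (Cp (x) exp(-k2 t)).

    ``cp`` is an :class:`InputFunction` (or any callable of minutes). The
    convolution runs on the fine grid and is averaged within frames.
    """
    if K1 < 0 or k2 < 0:
        raise ValueError("rate constants must be >= 0")
    _, cp_fine = _fine_input(cp, schedule)
    c_fine = K1 * convolve_exp(cp_fine, k2, SIM_GRID_STEP_MIN)
    return TimeActivityCurve(
        schedule=schedule,
        values=frame_average(c_fine, schedule, SIM_GRID_STEP_MIN))


def simulate_2tc(cp, K1: float, k2: float, k3: float, k4: float,
                 schedule: FrameSchedule) -> TimeActivityCurve:
    """Two-tissue-compartment TAC (total C1 + C2) via its bi-exponential
    impulse response convolved with the input on the fine grid.

    With k3 = k4 = 0 this reduces exactly to the one-tissue model.
    """
    if min(K1, k2, k3, k4) < 0:
        raise ValueError("rate constants must be >= 0")
    _, cp_fine = _fine_input(cp, schedule)
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    a1 = 0.5 * (s - disc)
    a2 = 0.5 * (s + disc)
    if a2 == a1:  # repeated eigenvalue: K1*(1 + (k3+k4-a1)t)e^{-a1 t}; handle via limit
        c_fine = K1 * convolve_exp(cp_fine, a1, SIM_GRID_STEP_MIN)
    else:
        w1 = (k3 + k4 - a1) / (a2 - a1)
        w2 = (a2 - k3 - k4) / (a2 - a1)
        c_fine = K1 * (w1 * convolve_exp(cp_fine, a1, SIM_GRID_STEP_MIN)
                       + w2 * convolve_exp(cp_fine, a2, SIM_GRID_STEP_MIN))
    return TimeActivityCurve(
        schedule=schedule,
        values=frame_average(c_fine, schedule, SIM_GRID_STEP_MIN))


# ---------------------------------------------------------------------------
# Region kinetics and phantom geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionKineticSpec:
    """Kinetics of one phantom region.

    Reference-like tissue (``bp_nd = 0``, ``R1 = 1``) is simulated by a
    one-tissue model from the input function; all other regions by the SRTM
    forward model from the reference curve, with target efflux
    ``k2 = R1 * k2_ref``.
    """

    role: str
    R1: float = 1.0
    bp_nd: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 < 0 or self.bp_nd < 0:
            raise ValueError("R1 and BP_ND must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and kinetics of a synthetic scan."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (0.776, 0.776, 0.796)
    brain_semiaxes_mm: tuple = (11.6, 9.3, 8.0)
    lesion_offset_mm: float = 6.2        # lateral (+x) shift of the lesion centre
    core_volume_mm3: float = 86.0
    edge1_volume_mm3: float = 202.0
    edge2_volume_mm3: float = 498.0
    contralateral_volume_mm3: float = 217.0
    cerebellum_plane_mm: float = 7.0     # posterior (+y) cap beyond this offset
    regions: tuple = (
        RegionKineticSpec("core", R1=1.0, bp_nd=1.5),
        RegionKineticSpec("edge1", R1=1.0, bp_nd=0.9),
        RegionKineticSpec("edge2", R1=1.0, bp_nd=0.45),
        RegionKineticSpec("contralateral", R1=1.0, bp_nd=0.0),
        # higher cerebellar perfusion plus mild specific binding, the
        # scenario that biases a cerebellar reference input
        RegionKineticSpec("cerebellum", R1=1.25, bp_nd=0.5),
        # brain tissue outside the lesion shares the binding-free normal
        # kinetics of the contralateral reference
        RegionKineticSpec("background", R1=1.0, bp_nd=0.0),
    )
    K1_ref: float = 0.12                 # ml/cm^3/min
    k2_ref: float = 0.25                 # 1/min


def mcao_phantom_config() -> PhantomConfig:
    """Stroke-like training anatomy: a large activated territory with an
    intermediate rim, used to define the clustering class database."""
    return PhantomConfig(
        core_volume_mm3=450.0,
        edge1_volume_mm3=350.0,
        edge2_volume_mm3=0.0,
        regions=(
            RegionKineticSpec("core", R1=0.9, bp_nd=2.4),
            RegionKineticSpec("edge1", R1=0.95, bp_nd=1.5),
            RegionKineticSpec("contralateral", R1=1.0, bp_nd=0.0),
            RegionKineticSpec("cerebellum", R1=1.25, bp_nd=0.3),
            # diffuse post-ischaemic change outside the infarct territory
            RegionKineticSpec("background", R1=1.0, bp_nd=0.2),
        ),
    )


def control_phantom_config() -> PhantomConfig:
    """Naive-control anatomy: no specific binding anywhere."""
    base = PhantomConfig()
    return replace(
        base,
        regions=tuple(replace(r, bp_nd=0.0) for r in base.regions),
    )


#: Truth label codes shared by phantoms and their serialized form.
TRUTH_LABELS = {
    "core": 1,
    "edge1": 2,
    "edge2": 3,
    "contralateral": 4,
    "cerebellum": 5,
    "background": 6,
}


@dataclass
class PhantomTruth:
    """Ground truth attached to a synthetic scan."""

    labels: np.ndarray                     # 0 outside brain, else TRUTH_LABELS
    specs: dict                            # role -> RegionKineticSpec (resolved)
    region_tacs: dict                      # role -> noiseless TimeActivityCurve
    noise_alpha: float
    seed: int
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.array([0.776, 0.776, 0.796]))

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def mask(self, role: str) -> np.ndarray:
        return self.labels == TRUTH_LABELS[role]

    def true_tac(self, role: str) -> TimeActivityCurve:
        return self.region_tacs[role]

    def to_json(self, path) -> None:
        payload = {
            "noise_alpha": self.noise_alpha,
            "seed": self.seed,
            "voxel_size_mm": list(map(float, self.voxel_size_mm)),
            "regions": {
                role: {"R1": s.R1, "bp_nd": s.bp_nd} for role, s in self.specs.items()
            },
            "region_tacs": {
                role: list(map(float, tac.values)) for role, tac in self.region_tacs.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _ellipsoid_mask(shape, voxel_size, center_mm, semiaxes_mm) -> np.ndarray:
    coords = [np.arange(n) * v for n, v in zip(shape, voxel_size)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return (
        ((x - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((y - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((z - center_mm[2]) / semiaxes_mm[2]) ** 2
    ) <= 1.0


def _sphere_radius_mm(volume_mm3: float) -> float:
    return (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def phantom_labels(config: PhantomConfig) -> np.ndarray:
    """Voxelize the phantom geometry into a truth label map."""
    shape = config.grid_shape
    voxel = np.asarray(config.voxel_size_mm)
    center = (np.asarray(shape) - 1) / 2.0 * voxel
    brain = _ellipsoid_mask(shape, voxel, center, config.brain_semiaxes_mm)

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = TRUTH_LABELS["background"]

    roles = {r.role for r in config.regions}

    # posterior cerebellar cap
    if "cerebellum" in roles:
        coords_y = np.arange(shape[1]) * voxel[1]
        cereb = brain & (coords_y[None, :, None] >= center[1] + config.cerebellum_plane_mm)
        labels[cereb] = TRUTH_LABELS["cerebellum"]

    # lesion: concentric core + edge shells, clipped to brain, ipsilateral
    lesion_center = center + np.array([config.lesion_offset_mm, 0.0, 0.0])
    r_core = _sphere_radius_mm(config.core_volume_mm3)
    radii = [r_core]
    cumulative = config.core_volume_mm3
    for extra in (config.edge1_volume_mm3, config.edge2_volume_mm3):
        if extra > 0:
            cumulative += extra
            radii.append(_sphere_radius_mm(cumulative))
    shell_roles = [r for r in ("core", "edge1", "edge2") if r in roles][: len(radii)]
    for role, radius in zip(reversed(shell_roles), reversed(radii[: len(shell_roles)])):
        sphere = _ellipsoid_mask(shape, voxel, lesion_center, [radius] * 3)
        labels[sphere & brain & (labels != TRUTH_LABELS["cerebellum"])] = TRUTH_LABELS[role]

    # mirrored contralateral sphere
    contra_center = center - np.array([config.lesion_offset_mm, 0.0, 0.0])
    r_contra = _sphere_radius_mm(config.contralateral_volume_mm3)
    contra = _ellipsoid_mask(shape, voxel, contra_center, [r_contra] * 3)
    labels[contra & (labels == TRUTH_LABELS["background"])] = TRUTH_LABELS["contralateral"]
    return labels


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------


def noise_sd(values: np.ndarray, schedule: FrameSchedule, alpha: float,
             isotope: str = "none") -> np.ndarray:
    """Per-frame noise SD: alpha * sqrt(max(v, 0) * exp(lambda*t_mid) / dur).

    Variance grows with physical decay (fewer true counts late in the scan)
    and shrinks with frame duration, the standard behaviour of reconstructed
    dynamic PET; for isotope ``none`` the decay factor is 1.
    """
    lam = decay_constant(isotope) if isotope != "none" else 0.0
    decay_term = np.exp(lam * schedule.midpoints)
    return alpha * np.sqrt(np.clip(values, 0.0, None) * decay_term / schedule.durations)


def add_noise(obj, alpha: float, seed: int):
    """Additive Gaussian noise on a TAC or dynamic image (negatives kept)."""
    if alpha < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(obj, DynamicImage):
        sd = noise_sd(obj.data, obj.schedule, alpha, obj.isotope)
        return obj.copy(data=obj.data + rng.standard_normal(obj.data.shape) * sd)
    sd = noise_sd(obj.values, obj.schedule, alpha, obj.isotope)
    return obj.copy(values=obj.values + rng.standard_normal(obj.values.shape) * sd)


# ---------------------------------------------------------------------------
# Phantom assembly
# ---------------------------------------------------------------------------


def region_tacs(
    config: PhantomConfig,
    schedule: FrameSchedule,
    cp: InputFunction = DEFAULT_INPUT,
    bp_multiplier: float = 1.0,
    r1_multiplier: float = 1.0,
) -> dict:
    """Noiseless per-region TACs (kBq/cm^3).

    The reference curve is a one-tissue simulation from the input function;
    every region with ``R1 != 1`` or ``bp_nd != 0`` is generated by the SRTM
    forward model from that curve. Animal-level multipliers scale lesional
    BP_ND and R1 (the contralateral/background reference stays binding-free).
    """
    reference = simulate_1tc(cp, config.K1_ref, config.k2_ref, schedule)
    out = {}
    for spec in config.regions:
        bp = spec.bp_nd * bp_multiplier
        r1 = spec.R1 if spec.role in ("contralateral", "background") else spec.R1 * r1_multiplier
        if bp == 0.0 and r1 == 1.0:
            out[spec.role] = reference.copy()
        else:
            params = SrtmParams.from_bp(R1=r1, k2=r1 * config.k2_ref, bp_nd=bp)
            out[spec.role] = srtm_forward(reference, params)
    return out


def build_phantom(
    config: PhantomConfig | None = None,
    schedule: FrameSchedule | None = None,
    cp: InputFunction = DEFAULT_INPUT,
    noise_alpha: float = 0.0,
    seed: int = 0,
    isotope: str = "F18",
    injected_dose_MBq: float = 20.0,
    bp_multiplier: float = 1.0,
    r1_multiplier: float = 1.0,
):
    """Assemble a synthetic dynamic scan and its ground truth.

    Returns ``(DynamicImage, PhantomTruth)``; with the same seed the result
    is bit-identical across calls.
    """
    config = config or PhantomConfig()
    schedule = schedule or FrameSchedule.default()
    roles = [r.role for r in config.regions]
    if len(set(roles)) != len(roles):
        raise ValueError("phantom regions must have unique roles")
    labels = phantom_labels(config)
    tacs = region_tacs(config, schedule, cp, bp_multiplier, r1_multiplier)

    shape = tuple(config.grid_shape) + (schedule.n_frames,)
    data = np.zeros(shape)
    specs = {}
    for spec in config.regions:
        mask = labels == TRUTH_LABELS[spec.role]
        if not mask.any():
            continue
        data[mask] = tacs[spec.role].values
        bp = spec.bp_nd * bp_multiplier
        r1 = spec.R1 if spec.role in ("contralateral", "background") else spec.R1 * r1_multiplier
        specs[spec.role] = RegionKineticSpec(spec.role, R1=r1, bp_nd=bp)

    image = DynamicImage(
        data=data,
        voxel_size_mm=np.asarray(config.voxel_size_mm),
        schedule=schedule,
        units="kBq/cm3",
        isotope=isotope,
        injected_dose_MBq=injected_dose_MBq,
        decay_corrected=True,
    )
    if noise_alpha > 0:
        image = add_noise(image, noise_alpha, seed)
    truth = PhantomTruth(
        labels=labels,
        specs=specs,
        region_tacs={role: tacs[role] for role in specs},
        noise_alpha=noise_alpha,
        seed=seed,
        voxel_size_mm=np.asarray(config.voxel_size_mm),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TracerSpec:
    """Tracer identity: isotope and a multiplicative effect on lesional BP_ND."""

    name: str
    isotope: str
    bp_scale: float = 1.0


#: Default tracers, echoing first- and second-generation TSPO ligands:
#: the C-11 reference compound and two F-18 tracers with larger specific
#: signal in dual-scanned animals.
DEFAULT_TRACERS = {
    "PK11195": TracerSpec("PK11195", "C11", 1.0),
    "GE180": TracerSpec("GE180", "F18", 1.55),
    "DPA714": TracerSpec("DPA714", "F18", 1.40),
}


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    tracers: tuple            # one tracer -> single scan, two -> dual scan
    kind: str = "lps"         # lps | control | mcao

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.kind not in ("lps", "control", "mcao"):
            raise ValueError(f"unknown group kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Study design: groups, tracers, noise and between-animal variability."""

    groups: tuple = (
        GroupSpec("group1", 6, ("PK11195", "GE180")),
        GroupSpec("group2", 6, ("PK11195", "DPA714")),
        GroupSpec("group3", 5, ("GE180",)),
        GroupSpec("group4", 5, ("DPA714",)),
    )
    tracers: dict = field(default_factory=lambda: dict(DEFAULT_TRACERS))
    noise_alpha: float = 0.5
    bp_sigma: float = 0.25        # log-normal SD of the animal-level BP multiplier
    r1_sigma: float = 0.04        # log-normal SD of the animal-level R1 multiplier
    dose_MBq: float = 20.0
    dose_sigma: float = 0.10      # log-normal SD of injected dose


def default_training_groups(n: int = 6, tracer: str = "PK11195") -> tuple:
    return (GroupSpec("mcao_training", n, (tracer,), kind="mcao"),)


@dataclass
class ScanPlan:
    """Deterministic recipe for one scan (realized lazily)."""

    animal_id: str
    group: str
    kind: str
    tracer: str
    bp_multiplier: float
    r1_multiplier: float
    dose_MBq: float
    seed: int


@dataclass
class ScanRecord:
    plan: ScanPlan
    image: DynamicImage
    truth: PhantomTruth


def plan_cohort(config: CohortConfig, seed: int) -> list:
    """Draw animal-level effects and per-scan seeds for the whole design.

    Dual-scan animals share their anatomy and animal-level multipliers
    across both scans; only tracer effect, dose and noise differ.
    """
    rng = np.random.default_rng(seed)
    plans = []
    for group in config.groups:
        for i in range(group.n):
            animal_id = f"{group.name}_a{i + 1:02d}"
            if group.kind == "control":
                bp_mult = 0.0
            else:
                bp_mult = float(np.exp(rng.normal(0.0, config.bp_sigma)))
            r1_mult = float(np.exp(rng.normal(0.0, config.r1_sigma)))
            for tracer_name in group.tracers:
                tracer = config.tracers[tracer_name]
                dose = float(config.dose_MBq * np.exp(rng.normal(0.0, config.dose_sigma)))
                scan_seed = int(rng.integers(0, 2**31 - 1))
                plans.append(
                    ScanPlan(
                        animal_id=animal_id,
                        group=group.name,
                        kind=group.kind,
                        tracer=tracer_name,
                        bp_multiplier=bp_mult * tracer.bp_scale,
                        r1_multiplier=r1_mult,
                        dose_MBq=dose,
                        seed=scan_seed,
                    )
                )
    return plans


def realize_scan(plan: ScanPlan, config: CohortConfig) -> ScanRecord:
    """Generate the dynamic image + truth for one planned scan."""
    if plan.kind == "mcao":
        pconfig = mcao_phantom_config()
    elif plan.kind == "control":
        pconfig = control_phantom_config()
    else:
        pconfig = PhantomConfig()
    tracer = config.tracers[plan.tracer]
    image, truth = build_phantom(
        config=pconfig,
        noise_alpha=config.noise_alpha,
        seed=plan.seed,
        isotope=tracer.isotope,
        injected_dose_MBq=plan.dose_MBq,
        bp_multiplier=plan.bp_multiplier,
        r1_multiplier=plan.r1_multiplier,
    )
    return ScanRecord(plan=plan, image=image, truth=truth)


def generate_cohort(config: CohortConfig, seed: int) -> list:
    """Materialize every scan of a study design (list of :class:`ScanRecord`)."""
    return [realize_scan(plan, config) for plan in plan_cohort(config, seed)]


def write_cohort(records, outdir) -> Path:
    """Write a cohort as NIfTI+JSON scans plus a TSV manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.plan.animal_id}_{rec.plan.tracer}"
        scan_path = outdir / f"{stem}.nii"
        truth_path = outdir / f"{stem}_truth.json"
        write_dynamic(rec.image, scan_path)
        rec.truth.to_json(truth_path)
        rows.append(
            {
                "animal_id": rec.plan.animal_id,
                "group": rec.plan.group,
                "tracer": rec.plan.tracer,
                "scan_path": scan_path.name,
                "truth_path": truth_path.name,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
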