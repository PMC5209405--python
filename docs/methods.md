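# Methods

This note documents the models, numerical choices and design decisions
behind `tspopet`, and what the synthetic validation does and does not show
about real data.

## Containers and units

All times are minutes; activities are kBq/cm³ until conversion to %ID/cm³
(`100 · kBq/cm³ / (dose_MBq · 1000)`). The frame timestamp used for
kinetics is the arithmetic frame midpoint; a decay-weighted mean time was
considered and rejected — for 1–10 min frames of C-11/F-18 the difference
is well below every tolerance used here, and the arithmetic midpoint keeps
the timing grid independent of the isotope. Half-lives are fixed constants
(C-11: 20.364 min, F-18: 109.771 min). Dynamic images are NIfTI-1 volumes
with a JSON sidecar (`frame_durations_min`, `isotope`, `injected_dose_MBq`,
`units`), keeping the image file standard. Window means over [t0, t1) are
duration-weighted with pro-rata handling of partially covered frames; the
40–60 min analysis window aligns with frame boundaries of the default
schedule, so the convention is invisible there.

ROI TACs are unweighted voxel means. Whether fragment-wise volume weighting
would be more faithful to any particular scanner pipeline is unknowable
from first principles; the unweighted mean is the simplest defensible
choice and is used consistently.

## SRTM forward model and fit

The operational SRTM equation is evaluated with the dispersion term
`C_R ⊗ exp(−k2a t)` computed by trapezoidal convolution on a 0.05-min grid,
with C_R linearly interpolated from its frame midpoints (anchored at
C_R(0) = 0, held constant beyond the last midpoint) and averaged back into
frames. The delivery term `R1·C_R` is applied at frame resolution, so
R1 = 1, BP_ND = 0 reproduces the reference exactly and a self-fit returns
(R1, BP_ND) = (1, 0) to machine precision.

Fitting is the basis-function method: 100 log-spaced k2a candidates in
[0.006, 3] min⁻¹ (bracketing plausible rodent TSPO kinetics over a 60-min
scan), weighted linear least squares per candidate, then a bounded scalar
refinement of k2a between the winning grid point's neighbours. Grid-edge
optima are flagged (`k2a_boundary`), never silently accepted; negative
BP_ND estimates are reported with a flag, never clipped. Fit weights
default to frame durations (uniform weights available); nothing in the
basis-function algebra depends on that choice at zero noise.

Validation: the forward model agrees with an adaptive ODE integration of
the same equations to < 10⁻³ relative over a 27-point parameter grid
(R1 ∈ [0.8, 1.3], k2 ∈ [0.1, 0.6] min⁻¹, BP_ND ∈ [0, 3]); noiseless
recovery over that grid is exact to refinement tolerance (≪ 1%); at the
study noise level the median BP_ND bias over 200 replicates is well below
5%.

## Synthetic cohort

The generator's defaults are the study conditions, not tuning knobs.

* **Input function**: Feng-type tri-exponential with linear rise
  (λ = 4.134, 0.119, 0.0104 min⁻¹; 0.5 min delay), scaled once so that the
  default reference tissue (K1 = 0.12 ml/cm³/min, k2 = 0.25 min⁻¹) averages
  ≈ 0.08 %ID/cm³ over 40–60 min at a 20 MBq dose — healthy-tissue uptake on
  the scale reported for rodent TSPO tracers.
* **Geometry** (64³ grid, 0.776 × 0.776 × 0.796 mm voxels): ellipsoidal
  brain (≈ 3600 mm³); spherical lesion core of 86 mm³ (≈ 2% of brain
  voxels) with two concentric rim shells (202 and 498 mm³); mirrored
  contralateral sphere (217 mm³); posterior cerebellar cap (≈ 155 mm³);
  the remaining brain is normal tissue.
* **Kinetics**: lesion core BP_ND = 1.5, rims 0.9 / 0.45, contralateral and
  background 0 (binding-free normal tissue), cerebellum R1 = 1.25 with
  BP_ND = 0.5 — higher perfusion plus mild specific binding, the scenario
  that biases a cerebellar reference input. Normal tissue outside the
  lesion shares the contralateral kinetics, mirroring the observed
  equivalence of contralateral and naïve-control uptake. Stroke-like
  training anatomy uses a large activated territory (450 mm³, BP_ND = 2.4,
  R1 = 0.9), a slow-washout rim (BP_ND = 1.5) and mild diffuse
  post-ischaemic change (BP_ND = 0.2) outside it, which keeps the
  lowest-uptake (contralateral) training ROI clean.
* **Tracers**: identity affects the isotope (decay in the noise model) and
  a multiplicative lesional BP_ND scale (PK11195-like 1.0, GE180-like 1.55,
  DPA714-like 1.40, echoing reported dual-scan effect sizes). One shared
  input shape per study; no tracer chemistry is modelled.
* **Cohort**: four groups (6 + 6 dual-scanned, 5 + 5 single-scanned) plus
  naïve controls (BP_ND = 0 everywhere) and a 6-animal training cohort.
  Animal-level log-normal multipliers (SD 0.25 on BP_ND, 0.04 on R1, 0.10
  on dose) are shared across a dual-scanned animal's two scans.
* **Noise**: additive Gaussian per voxel and frame with
  SD = α·sqrt(max(v,0)·e^(λ·t_mid)/Δt) — variance grows with physical decay
  and shrinks with frame duration, the standard behaviour of reconstructed
  dynamic PET. The study level is α = 0.5 (≈ 10% per voxel and frame at
  tissue activity); negatives are kept, as in reconstructed images. Noise
  is independent across voxels, which is *less* forgiving than real OSEM
  images at matched variance (no spatial correlation to average over) but
  unrealistic in texture; see "Smoothing" below.

The simulators (1-tissue, 2-tissue, SRTM forward) run on a 0.01-min grid —
finer than the SRTM fitting grid because the bolus peak of the input
function has far higher curvature than any tissue curve; at 0.05 min the
frame-0 error against an adaptive ODE oracle is ≈ 0.7%, at 0.01 min
< 0.03%.

## Kinetic segmentation

A brain-only re-implementation in spirit of local-means-analysis
segmentation: k-means (deterministic furthest-point seeding, k = 6 by
default — core, rims, normal tissue, cerebellum, spare) on z-normalized
voxel TACs, split into 26-connected components, followed by three cleanup
steps:

1. **smoothing before feature extraction** (2 mm FWHM Gaussian inside the
   brain mask, normalized convolution so nothing bleeds across the mask) —
   on the order of the scanner point-spread function, and necessary because
   the phantom's voxel noise is spatially independent;
2. **boundary refinement on raw kinetics**: voxels adjoining another
   region are iteratively reassigned to the adjacent region with the
   nearest mean raw kinetic, which removes the smoothing-induced mixture
   shells exactly at zero noise;
3. **merging**: adjacent regions with coinciding mean kinetics (tolerance
   10⁻⁶, i.e. only true duplicates) become one region, and components below
   10 voxels merge into their kinetically nearest neighbour.

Region mean TACs always come from raw, unsmoothed values. Zero-variance
voxels form a dedicated constant class. Everything is deterministic for a
fixed seed.

Roles follow the uptake-rank scheme on the 40–60 min window: highest →
core, then edge 1, edge 2 (edge 3 only when ≥ 5 rankable regions), lowest →
contralateral; ties break to the lower label. The cerebellum is identified
by maximal fractional overlap with a supplied anatomical mask (regions
≥ 50% inside the mask are excluded from ranking); if only a marginal
overlap exists and claiming it would leave fewer than two rankable regions,
no cerebellum role is assigned. The skull edge is the one-voxel outer shell
of the brain mask and is excluded from every quantitative output.

Because normal tissue inside and outside the mirrored contralateral sphere
is kinetically identical, the segmentation cannot (and should not)
distinguish them: the "contralateral" role denotes the lowest-uptake
binding-free tissue, and recovery is scored accordingly (the core label
covers the true core; the contralateral label selects true binding-free
tissue). At double the study noise (α = 1) the core region dilutes into the
rim shell — a known limitation analogous to partial-volume spill-over,
affecting region purity but not role identity.

## Supervised-clustering reference extraction

Class kinetics (activated / intermediate / normal) are trained from a
stroke-like cohort run through the same segmentation/labelling chain: per
animal, the core ROI defines activated, the contralateral ROI normal, and
rim + cerebellum the intermediate class; TACs are z-normalized per curve
(population SD), averaged across animals and re-normalized. The
normalization reading — per-curve mean/SD across frames — follows the
clinical supervised-clustering lineage; the alternative (per-frame
population statistics) would destroy the per-voxel scale invariance the
method depends on. Three classes are the default; no blood-pool class is
modelled (sub-resolution in rodents).

On a study scan, each brain voxel's normalized TAC (after the same 2 mm
within-mask smoothing) is decomposed by non-negative least squares onto the
class kinetics. Weights are *not* constrained to sum to one; assignment is
the argmax class and normal-purity is w_normal/Σw, making both scale-free.
Reference voxels are those assigned normal with purity ≥ 0.9 (a documented
choice — the original implementation's rule is not public), and the
reference TAC is the unweighted mean of their raw TACs; with no qualifying
voxel an explicit error tells the caller to lower the threshold.

Under the default conditions the cluster-derived reference pool is
essentially the true binding-free tissue, so cluster- and
contralateral-reference BP_ND coincide on phantoms. The downward bias of a
contaminated data-driven reference — reported for real data — appears here
only when it is simulated: with mild specific binding around the reference
ROI and a tolerant purity threshold, cluster-reference BP_ND drops strictly
below the contralateral-reference value (covered by a dedicated test), and
a cerebellar reference with true cerebellar binding is biased low on every
phantom animal.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test with exact two-sided
p-values for up to 25 non-zero pairs, computed by dynamic programming over
doubled (hence integer) average ranks — equivalent to enumerating all 2^n
sign patterns, but O(n³). Zero differences are dropped (Wilcoxon's original
rule); ties get average ranks. Unpaired comparisons use the Mann-Whitney U
test, exact by subset-sum enumeration for combined n ≤ 20; both fall back
to tie-corrected normal approximations with continuity correction above
those sizes. Spearman correlation uses average ranks. Two-sided p-values
throughout; no multiple-testing correction is applied (none is applied in
the workflow this mirrors), noted in the report manifest.

`run_study` chains simulation → segmentation → labelling → class-database
training → per-scan SRTM fits under contralateral, cerebellar and
cluster-derived references → report tables (per-scan uptake and ratios;
per-scan, per-reference core BP_ND and R1) → paired/unpaired tests and
Spearman correlations, and archives config + seed for exact rerun. Reports
are byte-identical for a fixed seed.

## Problem sizes

Tests run reduced designs (2–6 animals per group, 2-animal training
cohorts) chosen to exercise every code path with clear margins;
`scripts/acceptance.py` runs the full four-group design (6+6+5+5 LPS
animals, 4 controls, 6 training animals) plus the SRTM and clustering
validations. All randomness in both derives from the supplied seed.

## Known limitations

* Geometric phantoms with region-homogeneous kinetics: no anatomical
  texture, no partial-volume mixing at acquisition (only the noise/
  smoothing interplay at analysis), no motion, no attenuation/scatter
  residuals, no reconstruction artefacts. Passing tests validate the
  quantification chain, not robustness to those effects.
* The class database and study scans share the simulator family, so
  supervised clustering faces no model mismatch beyond noise and the
  deliberately contaminated scenarios.
* Specific-activity effects are not modelled.
* ROI-level fitting only; no voxelwise parametric maps, no plasma-input
  models, no multilinear reference variants.
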