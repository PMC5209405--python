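# tspopet

Reference-tissue kinetic quantification for dynamic TSPO-PET of rodent
neuroinflammation — with a synthetic dynamic-PET cohort generator so that
every stage of the chain can be validated against known ground truth.

## The problem

TSPO (18 kDa translocator protein) PET images microglial activation, but
quantifying specific binding in the brain is hard when no arterial input is
available and no anatomically defined binding-free region exists. The
standard preclinical workaround chains together:

1. **kinetic segmentation** of the dynamic image into regions of similar
   time-activity behaviour, labelled by uptake rank (lesion core, edge 1-3,
   contralateral reference, cerebellum, skull edge);
2. a **reference-tissue model fit** of each region against a chosen
   reference input; and
3. optionally a **data-driven reference**: supervised clustering of voxel
   kinetics against a trained class database (activated / intermediate /
   normal tissue) to extract binding-free voxels without anatomy.

This package implements that chain for 60-min scans histogrammed into 16
frames (5×1, 5×2, 3×5, 3×10 min), along with the cohort-level statistics
used to compare tracers (exact paired Wilcoxon signed-rank, exact
Mann-Whitney U, Spearman correlation between reference choices).

## The model

The simplified reference tissue model (SRTM) assumes one-tissue kinetics in
target and reference and links the target TAC C_T to the reference TAC C_R
without blood sampling:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) · C_R(t) ⊗ e^(−k2a·t)

with R1 = K1/K1′ the relative delivery, k2 the target efflux rate and
k2a = k2/(1 + BP_ND) the apparent efflux rate; the outcome measure is the
non-displaceable binding potential **BP_ND = k2/k2a − 1**. Fitting uses the
basis-function method: the convolution is precomputed on a log-spaced k2a
grid (100 points in [0.006, 3] min⁻¹), each candidate reduces to a
2-parameter weighted linear least squares, and the grid optimum is refined
by a bounded scalar search — deterministic and robust at preclinical noise
levels.

The synthetic cohort generator drives a one-tissue reference region from a
tri-exponential (Feng-type) input function and builds lesion, rim,
cerebellar and normal tissue from the SRTM forward model, on a 64³ grid at
0.776×0.776×0.796 mm scanner voxels, with Gaussian noise scaled by frame
duration and physical decay (C-11 or F-18). Study designs with dual-scanned
animals (shared anatomy and animal-level effects), single-scan groups,
naïve controls and stroke-like training cohorts are generated from a
declarative config with full seed reproducibility.

## Worked example

```python
import numpy as np
from tspopet import (build_phantom, extract_roi_tac, fit_srtm, to_percent_id,
                     window_mean, core_contralateral_ratio)

# one synthetic LPS-like scan, moderate noise
image, truth = build_phantom(noise_alpha=0.5, seed=42)
image = to_percent_id(image)                      # kBq/cm3 -> %ID/cm3

core = extract_roi_tac(image, truth.mask("core"))
contra = extract_roi_tac(image, truth.mask("contralateral"))
cereb = extract_roi_tac(image, truth.mask("cerebellum"))

print(f"core 40-60 min uptake:   {window_mean(core, 40, 60):.3f} %ID/cm3")
print(f"contralateral uptake:    {window_mean(contra, 40, 60):.3f} %ID/cm3")
print(f"core/contralateral ratio: {core_contralateral_ratio(core, contra):.2f}")

for name, ref in [("contralateral", contra), ("cerebellum", cereb)]:
    fit = fit_srtm(core, ref)
    print(f"SRTM core vs {name:13s} R1={fit.params.R1:.3f}  "
          f"BP_ND={fit.bp_nd:.3f}  ({fit.flags})")
```

prints

```
core 40-60 min uptake:   0.218 %ID/cm3
contralateral uptake:    0.080 %ID/cm3
core/contralateral ratio: 2.73
SRTM core vs contralateral R1=1.009  BP_ND=1.504  (ok)
SRTM core vs cerebellum    R1=0.803  BP_ND=0.670  (ok)
```

The configured truth for this phantom is core BP_ND = 1.5 with a
contralateral region free of specific binding: the contralateral-reference
fit recovers it within noise, while the cerebellar reference — a region
given higher perfusion and mild specific binding — under-estimates BP_ND,
the classic reference-choice bias.

The full study pipeline (simulate → segment → label → train class database
→ fit under all three reference inputs → statistics) runs via

```python
from tspopet import run_study
report = run_study(seed=1, outdir="out/")   # uptake_table.tsv, bpnd_table.tsv, stats.json
```

or from the shell: `tspopet run-study --seed 1 --outdir out/` (see
`tspopet --help` for the stage-by-stage subcommands).

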