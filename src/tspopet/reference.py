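"""Data-driven reference-tissue extraction by supervised clustering.

A training cohort with known tissue classes (activated infarct core,
intermediate-binding rim + cerebellum, normal contralateral tissue) defines
a small database of normalized class kinetics. On a study scan, each brain
voxel's normalized TAC is decomposed onto those class kinetics by
non-negative least squares; voxels assigned to the normal class with high
purity supply the binding-free reference TAC for SRTM fitting — without
requiring an anatomically defined reference region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .core import (
    DynamicImage,
    FrameSchedule,
    RoiSet,
    TimeActivityCurve,
    extract_roi_tac,
    smooth_within_mask,
)

CLASS_NAMES = ("activated", "intermediate", "normal")

#: Mapping from ROI roles to training classes: the infarct core defines
#: activated tissue, the contralateral ROI normal tissue, and the rim
#: (edge ROIs) together with the cerebellum the intermediate class.
ROLE_TO_CLASS = {
    "core": "activated",
    "contralateral": "normal",
    "edge1": "intermediate",
    "edge2": "intermediate",
    "edge3": "intermediate",
    "cerebellum": "intermediate",
}


class NoReferenceVoxelsError(RuntimeError):
    """No voxel passed the normal-class purity threshold."""


def normalize_tac(tac: TimeActivityCurve) -> TimeActivityCurve:
    """Per-curve z-normalization across frames (population SD).

    The output has zero mean and unit SD and is invariant to any positive
    affine transform of the input, so clustering compares kinetic shape
    only, not amplitude.
    """
    if tac.schedule.n_frames < 2:
        raise ValueError("need at least 2 frames to normalize")
    values = tac.values
    sd = values.std()
    if sd == 0:
        raise ValueError("constant TAC cannot be normalized")
    return tac.copy(values=(values - values.mean()) / sd, units="normalized")


def _znorm(values: np.ndarray) -> np.ndarray:
    return (values - values.mean()) / values.std()


@dataclass
class ClassDatabase:
    """Normalized population class kinetics on a shared frame schedule."""

    schedule: FrameSchedule
    kinetics: dict                     # class name -> np.ndarray (normalized)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vec in self.kinetics.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.schedule.n_frames,):
                raise ValueError(f"class {name!r} kinetic length mismatch")
            self.kinetics[name] = vec

    @property
    def class_names(self) -> list:
        return list(self.kinetics)

    def matrix(self) -> np.ndarray:
        """Frames x classes design matrix."""
        m = np.column_stack([self.kinetics[n] for n in self.class_names])
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("class kinetics are collinear/duplicated")
        return m

    def to_json(self, path) -> None:
        payload = {
            "frame_durations_min": list(map(float, self.schedule.durations)),
            "classes": {n: list(map(float, v)) for n, v in self.kinetics.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ClassDatabase":
        payload = json.loads(Path(path).read_text())
        return cls(
            schedule=FrameSchedule.from_durations(payload["frame_durations_min"]),
            kinetics={n: np.asarray(v) for n, v in payload["classes"].items()},
            provenance=payload.get("provenance", {}),
        )


def build_class_database(training, n_classes: int = 3) -> ClassDatabase:
    """Average normalized class TACs over a training cohort.

    Parameters
    ----------
    training
        List of ``(DynamicImage, RoiSet)`` pairs; each animal must provide
        ROIs covering all classes (core, contralateral, and rim and/or
        cerebellum for the intermediate class).
    n_classes
        3 (default) keeps activated/intermediate/normal; no more than three
        kinetically distinct classes are separable in mild-inflammation
        rodent data, but the database itself is agnostic.
    """
    if not training:
        raise ValueError("training cohort is empty")
    if n_classes != 3:
        raise ValueError("only the three-class database is supported")
    schedule = training[0][0].schedule
    per_class = {name: [] for name in CLASS_NAMES}
    for image, rois in training:
        if image.schedule != schedule:
            raise ValueError("training scans must share a frame schedule")
        class_masks = {name: None for name in CLASS_NAMES}
        for role in rois.present_roles():
            cls = ROLE_TO_CLASS.get(role)
            if cls is None:
                continue
            mask = rois.mask_for_role(role)
            class_masks[cls] = mask if class_masks[cls] is None else class_masks[cls] | mask
        for name, mask in class_masks.items():
            if mask is None or not mask.any():
                raise ValueError(f"training animal lacks a {name!r} class ROI")
            tac = extract_roi_tac(image, mask)
            per_class[name].append(normalize_tac(tac).values)
    kinetics = {
        name: _znorm(np.mean(np.stack(curves), axis=0))
        for name, curves in per_class.items()
    }
    return ClassDatabase(
        schedule=schedule,
        kinetics=kinetics,
        provenance={"n_animals": len(training)},
    )


@dataclass
class ClusterWeights:
    """Per-voxel non-negative class weights on the brain mask."""

    class_names: list
    weights: np.ndarray            # (x, y, z, n_classes); 0 outside mask
    assignment: np.ndarray         # argmax class index, -1 outside/unassigned
    purity: np.ndarray             # w_normal / sum(w), nan where unassigned
    brain_mask: np.ndarray

    def class_map(self, name: str) -> np.ndarray:
        return self.weights[..., self.class_names.index(name)]

    def reference_mask(self, purity_threshold: float = 0.9) -> np.ndarray:
        normal_idx = self.class_names.index("normal")
        with np.errstate(invalid="ignore"):
            return (self.assignment == normal_idx) & (self.purity >= purity_threshold)


def supervised_cluster(
    image: DynamicImage,
    db: ClassDatabase,
    brain_mask: np.ndarray,
    purity_threshold: float = 0.9,
    smoothing_fwhm_mm: float = 2.0,
):
    """Decompose every brain voxel onto the class kinetics; extract the
    reference TAC.

    The dynamic image is first smoothed within the brain mask (Gaussian,
    default 2 mm FWHM — on the order of the scanner point-spread function,
    and standard practice before voxel-wise kinetic classification). Each
    voxel's normalized TAC ``y`` is then fitted by non-negative least
    squares ``min ||M w - y||^2, w >= 0`` where the columns of ``M`` are the
    class kinetics. The voxel is assigned to its largest-weight class;
    normal-class purity is ``w_normal / sum(w)``. Reference voxels are those
    assigned normal with purity at or above the threshold, and the
    reference TAC is the unweighted mean of their raw (unsmoothed,
    unnormalized) TACs.

    Returns ``(ClusterWeights, TimeActivityCurve)``.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if image.schedule != db.schedule:
        raise ValueError("image and class database schedules differ")
    m = db.matrix()
    names = db.class_names
    normal_idx = names.index("normal")

    if smoothing_fwhm_mm > 0:
        smoothed = smooth_within_mask(image.data, brain_mask, smoothing_fwhm_mm,
                                      image.voxel_size_mm)
        tacs = smoothed[brain_mask]
    else:
        tacs = image.data[brain_mask]
    z, flat = _znorm_rows_safe(tacs)
    n_vox = tacs.shape[0]
    w = np.zeros((n_vox, m.shape[1]))
    for i in range(n_vox):
        if flat[i]:
            continue
        w[i], _ = nnls(m, z[i])

    total = w.sum(axis=1)
    assigned = (~flat) & (total > 0)
    assignment_flat = np.where(assigned, np.argmax(w, axis=1), -1)
    purity_flat = np.full(n_vox, np.nan)
    purity_flat[assigned] = w[assigned, normal_idx] / total[assigned]

    shape = image.data.shape[:3]
    weights = np.zeros(shape + (m.shape[1],))
    weights[brain_mask] = w
    assignment = np.full(shape, -1, dtype=int)
    assignment[brain_mask] = assignment_flat
    purity = np.full(shape, np.nan)
    purity[brain_mask] = purity_flat

    cw = ClusterWeights(
        class_names=names,
        weights=weights,
        assignment=assignment,
        purity=purity,
        brain_mask=brain_mask,
    )
    ref_mask = cw.reference_mask(purity_threshold)
    if not ref_mask.any():
        raise NoReferenceVoxelsError(
            f"no voxel assigned 'normal' with purity >= {purity_threshold}; "
            "consider lowering the threshold"
        )
    ref_tac = extract_roi_tac(image, ref_mask)
    return cw, ref_tac


def _znorm_rows_safe(tacs: np.ndarray):
    mean = tacs.mean(axis=1, keepdims=True)
    sd = tacs.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    return (tacs - mean) / sd, flat
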