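"""Core containers for dynamic PET quantification.

Frame schedules, time-activity curves (TACs), 4D dynamic images and labelled
region sets, together with the unit-handling primitives every downstream
stage relies on: radioactive decay correction, normalisation to percent
injected dose per cm³ (%ID/cm³), ROI TAC extraction and time-window means.

Conventions used throughout the package:

* all times are minutes, all activities kBq/cm³ until conversion to %ID/cm³;
* the frame timestamp used for kinetics is the arithmetic frame midpoint;
* voxel indices are 0-based and world coordinates are ``index * voxel_size``
  (axis-aligned, no rotation);
* dynamic images are stored as float arrays indexed ``(x, y, z, frame)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

# ---------------------------------------------------------------------------
# Package-wide configuration constants
# ---------------------------------------------------------------------------

#: Physical half-lives in minutes of the isotopes the package knows about.
HALF_LIFE_MIN = {"C11": 20.364, "F18": 109.771}

#: Step of the fine time grid (minutes) used for all convolutions.
FINE_GRID_STEP_MIN = 0.05

#: Frame durations (minutes) of the default 60-min acquisition:
#: 5 x 1 min, 5 x 2 min, 3 x 5 min, 3 x 10 min -> 16 frames.
DEFAULT_FRAME_DURATIONS_MIN = [1.0] * 5 + [2.0] * 5 + [5.0] * 3 + [10.0] * 3

VALID_UNITS = ("kBq/cm3", "%ID/cm3", "normalized")
VALID_ISOTOPES = ("C11", "F18", "none")

ROI_ROLES = (
    "core",
    "edge1",
    "edge2",
    "edge3",
    "contralateral",
    "cerebellum",
    "skull_edge",
    "unassigned",
)


class InvalidScheduleError(ValueError):
    """Raised when a frame schedule cannot be constructed."""


class UnitsError(ValueError):
    """Raised when an operation receives data in the wrong units/state."""


# ---------------------------------------------------------------------------
# Frame schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-acquisition timing grid shared by TACs and images.

    Frames start at t = 0 and are contiguous:
    ``starts[i+1] == starts[i] + durations[i]``.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape or starts.size == 0:
            raise InvalidScheduleError("starts/durations must be equal-length 1-D, non-empty")
        if np.any(durations <= 0):
            raise InvalidScheduleError("all frame durations must be > 0")
        if starts[0] != 0:
            raise InvalidScheduleError("first frame must start at t = 0")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], rtol=0, atol=1e-9):
            raise InvalidScheduleError("frames must be contiguous")

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        if durations.size == 0:
            raise InvalidScheduleError("duration list is empty")
        if np.any(durations <= 0):
            raise InvalidScheduleError("all frame durations must be > 0")
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts=starts, durations=durations)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The default 16-frame, 60-minute acquisition."""
        return cls.from_durations(DEFAULT_FRAME_DURATIONS_MIN)

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])

    def __eq__(self, other) -> bool:  # frozen dataclass with array fields
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.allclose(self.starts, other.starts, rtol=0, atol=1e-9)
            and np.allclose(self.durations, other.durations, rtol=0, atol=1e-9)
        )

    def __hash__(self) -> int:
        return hash((self.starts.tobytes(), self.durations.tobytes()))


def build_frame_schedule(durations) -> FrameSchedule:
    """Build a contiguous :class:`FrameSchedule` from per-frame durations."""
    return FrameSchedule.from_durations(durations)


# ---------------------------------------------------------------------------
# Time-activity curve
# ---------------------------------------------------------------------------


@dataclass
class TimeActivityCurve:
    """Activity versus time for one region or voxel.

    ``values[i]`` is the mean activity concentration during frame ``i`` of
    ``schedule``, in ``units``. The curve carries its decay-correction state
    and isotope so transformations can refuse inconsistent inputs.
    """

    schedule: FrameSchedule
    values: np.ndarray
    units: str = "kBq/cm3"
    decay_corrected: bool = True
    isotope: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError("values length must equal number of frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if self.units not in VALID_UNITS:
            raise UnitsError(f"unknown units {self.units!r}")
        if self.isotope not in VALID_ISOTOPES:
            raise ValueError(f"unknown isotope {self.isotope!r}")

    def copy(self, **changes) -> "TimeActivityCurve":
        out = replace(self, **changes)
        out.values = out.values.copy()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_min": self.schedule.starts,
                "frame_duration_min": self.schedule.durations,
                "value": self.values,
                "units": self.units,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **meta) -> "TimeActivityCurve":
        df = pd.read_csv(path, sep="\t")
        sched = FrameSchedule.from_durations(df["frame_duration_min"].to_numpy())
        units = str(df["units"].iloc[0]) if "units" in df else "kBq/cm3"
        return cls(schedule=sched, values=df["value"].to_numpy(), units=units, **meta)


def decay_constant(isotope: str) -> float:
    """ln(2) / half-life, in 1/min."""
    if isotope not in HALF_LIFE_MIN:
        raise ValueError(f"isotope {isotope!r} has no known half-life")
    return float(np.log(2.0) / HALF_LIFE_MIN[isotope])


def decay_correct(tac: TimeActivityCurve, reference_time: float = 0.0) -> TimeActivityCurve:
    """Correct a measured TAC for physical decay back to ``reference_time``.

    Each frame value is multiplied by ``exp(lambda * (t_mid - reference_time))``
    where ``lambda = ln(2)/half-life`` of the curve's isotope.
    """
    if tac.decay_corrected:
        raise UnitsError("TAC is already decay-corrected")
    lam = decay_constant(tac.isotope)
    factor = np.exp(lam * (tac.schedule.midpoints - reference_time))
    return tac.copy(values=tac.values * factor, decay_corrected=True)


def decay_uncorrect(tac: TimeActivityCurve, reference_time: float = 0.0) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct` (re-applies physical decay)."""
    if not tac.decay_corrected:
        raise UnitsError("TAC is not decay-corrected")
    lam = decay_constant(tac.isotope)
    factor = np.exp(-lam * (tac.schedule.midpoints - reference_time))
    return tac.copy(values=tac.values * factor, decay_corrected=False)


# ---------------------------------------------------------------------------
# Dynamic image and ROI sets
# ---------------------------------------------------------------------------


@dataclass
class DynamicImage:
    """4D dynamic PET volume with acquisition metadata.

    ``data`` is indexed ``(x, y, z, frame)``; ``voxel_size_mm`` gives the
    edge lengths of a voxel along each spatial axis.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    schedule: FrameSchedule
    units: str = "kBq/cm3"
    isotope: str = "none"
    injected_dose_MBq: float = float("nan")
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("4th dimension must equal the number of frames")
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel size must be three positive lengths")
        if self.units not in VALID_UNITS:
            raise UnitsError(f"unknown units {self.units!r}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def copy(self, **changes) -> "DynamicImage":
        out = replace(self, **changes)
        out.data = out.data.copy()
        return out


@dataclass
class RoiSet:
    """Integer label map plus a role per label.

    Roles follow the uptake-rank scheme: core (highest uptake), edge1..3,
    contralateral (lowest), cerebellum, skull_edge. Skull-edge voxels are
    excluded from every quantitative output.
    """

    labels: np.ndarray
    roles: dict = field(default_factory=dict)  # label (int) -> role (str)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        for label, role in self.roles.items():
            if role not in ROI_ROLES:
                raise ValueError(f"unknown role {role!r} for label {label}")
        for unique_role in ("core", "contralateral"):
            labs = [l for l, r in self.roles.items() if r == unique_role]
            if len(labs) > 1:
                raise ValueError(f"role {unique_role!r} must map to exactly one label")
            if len(labs) == 1 and not np.any(self.labels == labs[0]):
                raise ValueError(f"label for role {unique_role!r} is empty")

    def labels_for_role(self, role: str) -> list:
        return sorted(l for l, r in self.roles.items() if r == role)

    def mask_for_role(self, role: str) -> np.ndarray:
        labs = self.labels_for_role(role)
        if not labs:
            raise KeyError(f"no label carries role {role!r}")
        return np.isin(self.labels, labs)

    def present_roles(self) -> list:
        return sorted(set(self.roles.values()))

    def role_table(self, volume_per_voxel_mm3: float | None = None) -> pd.DataFrame:
        rows = []
        for label in sorted(self.roles):
            n_vox = int(np.count_nonzero(self.labels == label))
            row = {"label": label, "role": self.roles[label], "n_voxels": n_vox}
            if volume_per_voxel_mm3 is not None:
                row["volume_mm3"] = n_vox * volume_per_voxel_mm3
            rows.append(row)
        return pd.DataFrame(rows)


def smooth_within_mask(data: np.ndarray, mask: np.ndarray,
                       fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Frame-wise Gaussian smoothing of a 4D image restricted to a mask.

    Normalized convolution (data*mask and mask smoothed separately, then
    divided) so that values outside the mask never bleed in. Used as
    preprocessing before voxel-wise kinetic classification; reconstructed
    PET has comparable intrinsic resolution, so the operation mimics the
    scanner point-spread function rather than discarding information.
    """
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size_mm)
    mask = np.asarray(mask, dtype=bool)
    weight = gaussian_filter(mask.astype(float), sigma=sigma_vox)
    out = np.empty_like(data)
    for f in range(data.shape[3]):
        num = gaussian_filter(data[..., f] * mask, sigma=sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[..., f] = np.where(weight > 1e-6, num / weight, 0.0)
    return out


def extract_roi_tac(image: DynamicImage, mask: np.ndarray) -> TimeActivityCurve:
    """Unweighted per-frame mean TAC over the voxels selected by ``mask``."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    if mask.shape != image.data.shape[:3]:
        raise ValueError("mask shape must match the image's spatial grid")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    values = image.data[mask].mean(axis=0)
    return TimeActivityCurve(
        schedule=image.schedule,
        values=values,
        units=image.units,
        decay_corrected=image.decay_corrected,
        isotope=image.isotope,
    )


# ---------------------------------------------------------------------------
# Unit conversion and window statistics
# ---------------------------------------------------------------------------


def to_percent_id(obj, injected_dose_MBq: float | None = None):
    """Convert a TAC or dynamic image from kBq/cm³ to %ID/cm³.

    ``%ID/cm³ = 100 * activity[kBq/cm³] / (dose[MBq] * 1000)``; the input
    must be decay-corrected to injection time so the dose is comparable.
    """
    if isinstance(obj, DynamicImage) and injected_dose_MBq is None:
        injected_dose_MBq = obj.injected_dose_MBq
    if injected_dose_MBq is None or not np.isfinite(injected_dose_MBq):
        raise ValueError("injected dose is required")
    if injected_dose_MBq <= 0:
        raise ValueError("injected dose must be > 0")
    if obj.units != "kBq/cm3":
        raise UnitsError(f"expected kBq/cm3 input, got {obj.units!r}")
    if not obj.decay_corrected:
        raise UnitsError("input must be decay-corrected to injection time")
    scale = 100.0 / (injected_dose_MBq * 1000.0)
    if isinstance(obj, DynamicImage):
        return obj.copy(data=obj.data * scale, units="%ID/cm3")
    return obj.copy(values=obj.values * scale, units="%ID/cm3")


def window_mean(tac: TimeActivityCurve, t0: float, t1: float) -> float:
    """Duration-weighted mean of a TAC over the half-open window [t0, t1).

    Frames partially covered by the window contribute pro-rata by their
    overlapped duration.
    """
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    sched = tac.schedule
    overlap = np.minimum(sched.ends, t1) - np.maximum(sched.starts, t0)
    overlap = np.clip(overlap, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(f"window [{t0}, {t1}) does not overlap the schedule")
    return float(np.dot(overlap, tac.values) / total)


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_dynamic(image: DynamicImage, path) -> None:
    """Write a dynamic image as NIfTI-1 plus a JSON frame-schedule sidecar."""
    path = Path(path)
    affine = np.diag(list(image.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))
    sidecar = {
        "frame_durations_min": list(map(float, image.schedule.durations)),
        "isotope": image.isotope,
        "injected_dose_MBq": float(image.injected_dose_MBq),
        "units": image.units,
        "decay_corrected": bool(image.decay_corrected),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_dynamic(path) -> DynamicImage:
    """Read a dynamic image written by :func:`write_dynamic`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    nifti = nib.load(str(path))
    data = np.asanyarray(nifti.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    durations = sidecar["frame_durations_min"]
    if data.shape[3] != len(durations):
        raise ValueError(
            f"sidecar lists {len(durations)} frames but image has {data.shape[3]}"
        )
    voxel_size = np.abs(np.diag(nifti.affine)[:3])
    return DynamicImage(
        data=data,
        voxel_size_mm=voxel_size,
        schedule=FrameSchedule.from_durations(durations),
        units=sidecar.get("units", "kBq/cm3"),
        isotope=sidecar.get("isotope", "none"),
        injected_dose_MBq=float(sidecar.get("injected_dose_MBq", float("nan"))),
        decay_corrected=bool(sidecar.get("decay_corrected", True)),
    )


def write_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(np.asarray(voxel_size_mm, dtype=float)) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.int16), affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.int16)
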