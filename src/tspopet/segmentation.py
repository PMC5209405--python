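"""Kinetic segmentation of dynamic brain PET and uptake-rank ROI labelling.

Voxels inside the brain mask are clustered by the shape of their
time-activity curves (local-means-analysis style: kinetic similarity plus
spatial contiguity), then the resulting regions are labelled by the
uptake-rank scheme: highest 40-60 min uptake = lesion core, next = edge 1,
edge 2 (and edge 3 where enough regions exist), lowest = contralateral
reference; the cerebellum is identified by overlap with an anatomical
cerebellum mask, and a one-voxel outer shell of the brain mask is labelled
skull edge and excluded from all quantitative outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import (
    DynamicImage,
    RoiSet,
    TimeActivityCurve,
    extract_roi_tac,
    smooth_within_mask,
    window_mean,
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Partition of the brain mask into kinetically homogeneous regions."""

    labels: np.ndarray          # 0 outside mask, regions numbered from 1
    region_tacs: dict           # label -> TimeActivityCurve (raw values)
    volumes_mm3: dict           # label -> float
    params: dict

    @property
    def region_labels(self) -> list:
        return sorted(self.region_tacs)


def _znorm_rows(tacs: np.ndarray):
    """Row-wise z-normalization; returns (normalized, zero-variance mask)."""
    mean = tacs.mean(axis=1, keepdims=True)
    sd = tacs.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    return (tacs - mean) / sd, flat


def _farthest_point_init(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic furthest-point seeding: start from the point farthest
    from the data mean, then repeatedly add the point farthest from its
    nearest chosen centre (ties -> lowest index)."""
    d0 = np.linalg.norm(x - x.mean(axis=0), axis=1)
    centers = [int(np.argmax(d0))]
    dist = np.linalg.norm(x - x[centers[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(x - x[nxt], axis=1))
    return x[centers]


def segment_kinetic(
    image: DynamicImage,
    brain_mask: np.ndarray,
    k: int = 6,
    seed: int = 0,
    min_region_size: int = 10,
    smoothing_fwhm_mm: float = 2.0,
) -> SegmentationResult:
    """Segment brain voxels into spatially contiguous kinetic regions.

    The image is smoothed within the brain mask (default 2 mm FWHM, on the
    order of the scanner point-spread function) before feature extraction;
    each voxel TAC is then z-normalized (zero-variance voxels go to a
    dedicated constant class), clustered by k-means with deterministic
    furthest-point initialization, split into 26-connected components, and
    components smaller than ``min_region_size`` are merged into the
    kinetically nearest adjacent region. Region mean TACs are computed from
    the raw, unsmoothed values.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    n_vox = int(brain_mask.sum())
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_vox:
        raise ValueError("k exceeds the number of brain voxels")

    if smoothing_fwhm_mm > 0:
        features = smooth_within_mask(image.data, brain_mask, smoothing_fwhm_mm,
                                      image.voxel_size_mm)
        tacs = features[brain_mask]                     # (n_vox, n_frames)
    else:
        tacs = image.data[brain_mask]
    z, flat = _znorm_rows(tacs)

    cluster_of = np.full(n_vox, -1, dtype=int)
    active = ~flat
    x = z[active]
    if x.shape[0] >= k:
        km = KMeans(n_clusters=k, init=_farthest_point_init(x, k), n_init=1,
                    max_iter=300, random_state=seed)
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # duplicate TACs (noiseless phantoms) may collapse clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            cluster_of[active] = km.fit_predict(x)
    else:
        cluster_of[active] = 0
    if flat.any():
        cluster_of[flat] = cluster_of.max() + 1          # constant class

    # split clusters into 26-connected components
    cluster_map = np.full(image.data.shape[:3], -1, dtype=int)
    cluster_map[brain_mask] = cluster_of
    region_map = np.zeros(image.data.shape[:3], dtype=int)
    next_label = 1
    for c in np.unique(cluster_of):
        comp, n_comp = ndimage.label(cluster_map == c, structure=_CONN26)
        for j in range(1, n_comp + 1):
            region_map[comp == j] = next_label
            next_label += 1

    region_map = _merge_small_regions(region_map, z, brain_mask, min_region_size)

    # boundary refinement on raw kinetics: smoothing mixes classes at region
    # borders, so reassign voxels that touch another region to the adjacent
    # region whose mean raw kinetic is nearest (exact class boundaries at
    # zero noise)
    raw_z, raw_flat = _znorm_rows(image.data[brain_mask])
    for _ in range(10):  # peel mixed boundary layers to a fixed point
        refined = _refine_boundaries(region_map, raw_z, raw_flat, brain_mask)
        if np.array_equal(refined, region_map):
            break
        region_map = refined
    region_map = _split_components(region_map)
    region_map = _merge_duplicate_regions(region_map, raw_z, brain_mask)
    region_map = _merge_small_regions(region_map, raw_z, brain_mask, min_region_size)

    # relabel compactly in deterministic order
    final_labels = np.zeros_like(region_map)
    for new, old in enumerate(np.unique(region_map[region_map > 0]), start=1):
        final_labels[region_map == old] = new

    region_tacs, volumes = {}, {}
    for label in np.unique(final_labels[final_labels > 0]):
        mask = final_labels == label
        region_tacs[int(label)] = extract_roi_tac(image, mask)
        volumes[int(label)] = float(mask.sum()) * image.voxel_volume_mm3

    return SegmentationResult(
        labels=final_labels,
        region_tacs=region_tacs,
        volumes_mm3=volumes,
        params={"k": k, "seed": seed, "min_region_size": min_region_size,
                "connectivity": 26, "smoothing_fwhm_mm": smoothing_fwhm_mm},
    )


def _merge_small_regions(region_map, z, brain_mask, min_size):
    """Merge sub-threshold connected regions into their kinetically nearest
    adjacent region (smallest regions first; deterministic)."""
    region_map = region_map.copy()
    z_map_idx = np.full(region_map.shape, -1, dtype=int)
    z_map_idx[brain_mask] = np.arange(z.shape[0])

    def region_mean(label):
        idx = z_map_idx[region_map == label]
        return z[idx].mean(axis=0)

    while True:
        labels, counts = np.unique(region_map[region_map > 0], return_counts=True)
        if labels.size <= 1:
            break
        small = labels[counts < min_size]
        if small.size == 0:
            break
        label = int(small[np.argmin(counts[counts < min_size])])
        mask = region_map == label
        halo = ndimage.binary_dilation(mask, structure=_CONN26) & ~mask
        neighbours = np.unique(region_map[halo])
        neighbours = neighbours[neighbours > 0]
        candidates = neighbours if neighbours.size else labels[labels != label]
        mu = region_mean(label)
        dists = [np.linalg.norm(region_mean(int(n)) - mu) for n in candidates]
        target = int(candidates[int(np.argmin(dists))])
        region_map[mask] = target
    return region_map


def _merge_duplicate_regions(region_map, z_raw, brain_mask, tol: float = 1e-6):
    """Merge adjacent regions whose mean raw kinetics coincide (within a
    tight tolerance): identical kinetics are one region by definition.
    Arises for noiseless inputs when k exceeds the number of distinct
    kinetic classes."""
    region_map = region_map.copy()
    idx_map = np.full(region_map.shape, -1, dtype=int)
    idx_map[brain_mask] = np.arange(z_raw.shape[0])
    changed = True
    while changed:
        changed = False
        labels = list(np.unique(region_map[region_map > 0]))
        means = {int(l): z_raw[idx_map[region_map == l]].mean(axis=0) for l in labels}
        for label in labels:
            mask = region_map == label
            halo = ndimage.binary_dilation(mask, structure=_CONN26) & ~mask
            for other in np.unique(region_map[halo]):
                if other <= 0 or other == label:
                    continue
                if np.linalg.norm(means[int(label)] - means[int(other)]) < tol:
                    region_map[region_map == other] = label
                    changed = True
                    break
            if changed:
                break
    return region_map


def _split_components(region_map: np.ndarray) -> np.ndarray:
    """Renumber regions so that every region is 26-connected."""
    out = np.zeros_like(region_map)
    next_label = 1
    for label in np.unique(region_map[region_map > 0]):
        comp, n_comp = ndimage.label(region_map == label, structure=_CONN26)
        for j in range(1, n_comp + 1):
            out[comp == j] = next_label
            next_label += 1
    return out


def _refine_boundaries(region_map, z_raw, flat, brain_mask):
    """One reassignment pass: each voxel adjoining another region moves to
    the neighbouring region whose mean raw kinetic it matches best."""
    region_map = region_map.copy()
    idx_map = np.full(region_map.shape, -1, dtype=int)
    idx_map[brain_mask] = np.arange(z_raw.shape[0])

    labels = np.unique(region_map[region_map > 0])
    means = {}
    for label in labels:
        idx = idx_map[region_map == label]
        means[int(label)] = z_raw[idx].mean(axis=0)

    interior = ndimage.minimum_filter(region_map, footprint=_CONN26) == \
        ndimage.maximum_filter(region_map, footprint=_CONN26)
    boundary = brain_mask & ~interior
    new_map = region_map.copy()
    coords = np.argwhere(boundary)
    shape = region_map.shape
    for x, y, zc in coords:
        i = idx_map[x, y, zc]
        if i < 0 or flat[i]:
            continue
        sl = (slice(max(x - 1, 0), x + 2), slice(max(y - 1, 0), y + 2),
              slice(max(zc - 1, 0), zc + 2))
        cands = np.unique(region_map[sl])
        cands = cands[cands > 0]
        voxel = z_raw[i]
        best, best_d = None, np.inf
        for c in cands:
            d = float(np.linalg.norm(voxel - means[int(c)]))
            if d < best_d:
                best, best_d = int(c), d
        new_map[x, y, zc] = best
    return new_map


def skull_edge_mask(brain_mask: np.ndarray) -> np.ndarray:
    """One-voxel morphological outer shell of the brain mask."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    return ndimage.binary_dilation(brain_mask, structure=_CONN26) & ~brain_mask


def label_rois(
    seg: SegmentationResult,
    cerebellum_mask: np.ndarray,
    brain_mask: np.ndarray,
    window: tuple = (40.0, 60.0),
) -> RoiSet:
    """Assign core/edge/contralateral/cerebellum roles to segmented regions.

    Regions are ranked by their window-mean uptake after removing the
    cerebellar regions (those with most of their volume inside the
    cerebellum mask; the single best-overlapping region carries the
    cerebellum role, tie-broken by lowest label — unless claiming a
    marginally-overlapping region would leave fewer than two rankable
    regions, in which case no cerebellum role is assigned). The top-ranked region is
    the core, followed by edge 1, edge 2 and — when at least five rankable
    regions exist — edge 3; the lowest-uptake region is the contralateral
    reference. Ties in window mean resolve to the lower label. The skull
    edge is the one-voxel outer shell of the brain mask.
    """
    cerebellum_mask = np.asarray(cerebellum_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    labels = seg.region_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 segmented regions to assign roles")

    overlap_frac = {}
    for label in labels:
        region = seg.labels == label
        overlap_frac[label] = float((region & cerebellum_mask).sum()) / float(region.sum())
    if max(overlap_frac.values()) == 0:
        raise ValueError("no segmented region overlaps the cerebellum mask")
    cereb_label = min(
        (l for l in labels), key=lambda l: (-overlap_frac[l], l)
    )
    excluded = {l for l in labels if overlap_frac[l] >= 0.5}
    # a marginally-overlapping best candidate is claimed as cerebellum only
    # when enough regions remain to rank core and contralateral
    if overlap_frac[cereb_label] >= 0.5 or len(labels) - len(excluded | {cereb_label}) >= 2:
        excluded.add(cereb_label)
    else:
        cereb_label = None

    rankable = [l for l in labels if l not in excluded]
    if len(rankable) < 2:
        raise ValueError("fewer than 2 rankable regions after cerebellum exclusion")
    means = {l: window_mean(seg.region_tacs[l], *window) for l in rankable}
    order = sorted(rankable, key=lambda l: (-means[l], l))

    roles = {} if cereb_label is None else {cereb_label: "cerebellum"}
    ranked_roles = ["core", "edge1", "edge2"]
    if len(order) >= 5:
        ranked_roles.append("edge3")
    for role, label in zip(ranked_roles, order[:-1]):
        roles[label] = role
    roles[order[-1]] = "contralateral"
    for label in labels:
        roles.setdefault(label, "unassigned")

    out_labels = seg.labels.astype(np.int16).copy()
    shell = skull_edge_mask(brain_mask)
    skull_label = max(labels) + 1
    out_labels[shell] = skull_label
    roles[skull_label] = "skull_edge"
    return RoiSet(labels=out_labels, roles=roles)
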