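"""Two-stage object identification: nuclei, then somata by constrained expansion.

Mirrors the CellProfiler-style workflow used for smFISH quantification:
primary objects (nuclei) are found by smoothing, a global threshold scaled by
a correction factor and clipped to bounds, optional distance-transform
watershed declumping and a diameter filter; secondary objects (somata) are
the nuclei expanded outwards by a maximum Euclidean distance, each background
pixel going to its nearest nucleus with ties broken towards the lower label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"
    threshold_correction: float = 1.0
    threshold_bounds: tuple[float, float] = (0.0, np.inf)
    declump: bool = True
    min_diameter: float = 6.0
    max_diameter: float = 40.0
    exclude_border: bool = False

    def validate(self) -> None:
        if not 0 < self.min_diameter < self.max_diameter:
            raise ValueError("require 0 < min_diameter < max_diameter")
        if self.threshold_correction <= 0:
            raise ValueError("threshold correction factor must be > 0")
        lo, hi = self.threshold_bounds
        if lo > hi:
            raise ValueError("lower threshold bound exceeds upper bound")
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def _check_2d(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    return image.astype(np.float64, copy=False)


def effective_threshold(method_threshold: float, params: SegmentationParams) -> float:
    """clip(method_threshold * correction_factor, lower, upper)."""
    lo, hi = params.threshold_bounds
    return float(np.clip(method_threshold * params.threshold_correction, lo, hi))


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..N preserving ascending original label order."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids != 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size and labels.max() > 0 else 1,
                   dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def is_contiguous(labels: np.ndarray) -> bool:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    return bool(np.array_equal(ids, np.arange(1, len(ids) + 1)))


def detect_nuclei(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Identify nuclei as primary objects.

    Smoothing -> global Otsu x correction factor, clipped to the threshold
    bounds -> connected components -> optional distance-transform watershed
    declumping (peak seeds at least ``min_diameter`` apart, per labeled
    clump) -> diameter and border filters -> contiguous relabeling. An image
    without foreground yields an empty (all-zero) label map, not an error.
    """
    image = _check_2d(image)
    params.validate()
    smoothed = (
        ndi.gaussian_filter(image, params.smoothing_sigma)
        if params.smoothing_sigma > 0
        else image
    )
    if smoothed.max() == smoothed.min():
        return np.zeros(image.shape, dtype=np.int32)
    eff = effective_threshold(threshold_otsu(smoothed), params)
    mask = smoothed > eff
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    labels, _ = ndi.label(mask)

    if params.declump:
        dist = ndi.distance_transform_edt(mask)
        dist = ndi.gaussian_filter(dist, 1.0)
        seeds_xy = peak_local_max(
            dist,
            min_distance=max(1, int(round(params.min_diameter))),
            labels=labels,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(seeds_xy, start=1):
            markers[r, c] = i
        labels = watershed(-dist, markers, mask=mask)

    # diameter filter on equivalent circular diameter
    areas = np.bincount(labels.ravel())
    diam = 2.0 * np.sqrt(areas / np.pi)
    bad = (diam < params.min_diameter) | (diam > params.max_diameter)
    bad[0] = False
    if bad.any():
        labels = np.where(bad[labels], 0, labels)
    if params.exclude_border:
        labels = _drop_border_objects(labels)
    return relabel_sequential(labels)


def _drop_border_objects(labels: np.ndarray) -> np.ndarray:
    edge = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    edge = edge[edge != 0]
    if len(edge):
        labels = np.where(np.isin(labels, edge), 0, labels)
    return labels


def expand_to_soma(nuclei: np.ndarray, max_distance_px: float) -> np.ndarray:
    """Expand nuclei into somata by nearest-nucleus Euclidean assignment.

    Every background pixel whose Euclidean distance to the nearest nucleus
    pixel is at most ``max_distance_px`` receives that nucleus's label;
    exact-distance ties between different nuclei go to the lower label.
    Nucleus pixels are never overwritten, so each soma contains its nucleus.
    """
    nuclei = np.asarray(nuclei)
    if nuclei.ndim != 2:
        raise ValueError("nuclei label map must be 2-D")
    if max_distance_px < 0:
        raise ValueError("max_distance_px must be >= 0")
    soma = nuclei.astype(np.int32).copy()
    if max_distance_px == 0 or not (nuclei > 0).any():
        return soma

    src = np.argwhere(nuclei > 0)  # (row, col) of labeled pixels
    src_labels = nuclei[src[:, 0], src[:, 1]]
    tree = cKDTree(src)
    bg = np.argwhere(nuclei == 0)
    k = min(8, len(src))
    dd, ii = tree.query(bg, k=k)
    if k == 1:
        dd = dd[:, None]
        ii = ii[:, None]
    # squared distances between integer grid points are integers: compare exactly
    d2 = np.rint(dd**2).astype(np.int64)
    within = dd[:, 0] <= max_distance_px
    cand_labels = src_labels[ii]
    tied = d2 == d2[:, [0]]
    chosen = np.where(tied, cand_labels, np.iinfo(np.int32).max).min(axis=1)

    # pixels where every one of the k neighbours ties could hide an even lower
    # label beyond k: resolve those few by an exhaustive radius query
    all_tied = tied.all(axis=1) & within & (k > 1)
    for idx in np.nonzero(all_tied)[0]:
        hits = tree.query_ball_point(bg[idx], r=dd[idx, 0] + 1e-9)
        chosen[idx] = src_labels[hits].min()

    rows, cols = bg[within, 0], bg[within, 1]
    soma[rows, cols] = chosen[within]
    return soma


def filter_objects(
    labels: np.ndarray,
    min_area: float = 0.0,
    max_area: float = np.inf,
    border_policy: str = "keep",
) -> np.ndarray:
    """Remove objects outside [min_area, max_area] px^2 and, optionally,
    objects touching the image border; relabel contiguously."""
    if min_area > max_area:
        raise ValueError("min_area exceeds max_area")
    if border_policy not in ("keep", "exclude"):
        raise ValueError("border_policy must be 'keep' or 'exclude'")
    labels = np.asarray(labels).astype(np.int32).copy()
    areas = np.bincount(labels.ravel())
    bad = (areas < min_area) | (areas > max_area)
    bad[0] = False
    if bad.any():
        labels = np.where(bad[labels], 0, labels)
    if border_policy == "exclude":
        labels = _drop_border_objects(labels)
    return relabel_sequential(labels)


def object_table(labels: np.ndarray):
    """Object table (label, centroid x/y, area) for a label map."""
    import pandas as pd

    ids = np.unique(labels)
    ids = ids[ids != 0]
    if len(ids) == 0:
        return pd.DataFrame(columns=["label", "x", "y", "area"])
    coms = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
    return pd.DataFrame(
        {
            "label": ids,
            "x": [c[1] for c in coms],
            "y": [c[0] for c in coms],
            "area": areas.astype(int),
        }
    )
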