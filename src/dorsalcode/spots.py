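"""Probe-dot detection and spot-to-cell assignment.

Signal dots are local maxima of a Laplacian-of-Gaussian band-pass response
above an effective threshold (method threshold x correction factor, clipped
to bounds — the same convention used per slide in the original workflow).
Each dot is then related to the soma label under its rounded pixel position;
dots over background keep parent 0 and never contribute to dots/cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu


@dataclass
class SpotDetectParams:
    scale_px: float = 1.0  # LoG sigma, matched to the rendered/physical spot size
    threshold_correction: float = 1.0
    threshold_bounds: tuple[float, float] = (0.0, np.inf)
    min_separation_px: float = 2.0

    def validate(self) -> None:
        if self.scale_px <= 0:
            raise ValueError("scale_px must be > 0")
        if self.threshold_correction <= 0:
            raise ValueError("threshold correction factor must be > 0")
        lo, hi = self.threshold_bounds
        if lo > hi:
            raise ValueError("lower threshold bound exceeds upper bound")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")


def detect_spots(
    probe_channel: np.ndarray,
    params: SpotDetectParams,
    gene: str | None = None,
) -> pd.DataFrame:
    """Detect dots in one probe channel.

    Returns one record per spot with sub-pixel position (3x3 response
    centroid around the peak), peak image intensity and the gene name if
    given. Deterministic: spots are ordered by (y, x).
    """
    img = np.asarray(probe_channel)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D probe channel, got shape {img.shape}")
    params.validate()
    f = img.astype(np.float64, copy=False)
    empty = pd.DataFrame(columns=["x", "y", "gene", "peak_intensity"])
    if f.max() == f.min():
        return empty

    # scale-normalised LoG: positive response at bright blobs of width ~scale
    response = -ndi.gaussian_laplace(f, params.scale_px) * params.scale_px**2
    pos = np.clip(response, 0.0, None)
    if pos.max() == 0:
        return empty
    lo, hi = params.threshold_bounds
    eff = float(np.clip(threshold_otsu(pos) * params.threshold_correction, lo, hi))
    peaks = peak_local_max(
        response,
        min_distance=max(1, int(math.ceil(params.min_separation_px))),
        threshold_abs=eff,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return empty

    H, W = img.shape
    xs, ys, amps = [], [], []
    for r, c in peaks:
        r0, r1 = max(0, r - 1), min(H, r + 2)
        c0, c1 = max(0, c - 1), min(W, c + 2)
        w = np.clip(response[r0:r1, c0:c1], 0.0, None)
        tot = w.sum()
        if tot > 0:
            yy, xx = np.mgrid[r0:r1, c0:c1]
            ys.append(float((w * yy).sum() / tot))
            xs.append(float((w * xx).sum() / tot))
        else:  # pragma: no cover - flat response around a peak
            ys.append(float(r))
            xs.append(float(c))
        amps.append(float(img[r, c]))
    out = pd.DataFrame({"x": xs, "y": ys, "gene": gene, "peak_intensity": amps})
    return out.sort_values(["y", "x"], ignore_index=True)


def detect_all_channels(image_stack, params: SpotDetectParams) -> pd.DataFrame:
    """Run :func:`detect_spots` on every probe channel of an ImageStack."""
    frames = [
        detect_spots(image_stack.channel(g), params, gene=g)
        for g in image_stack.probe_channels
    ]
    return pd.concat(frames, ignore_index=True)


def relate_spots_to_cells(
    spots: pd.DataFrame, somata: np.ndarray
) -> pd.DataFrame:
    """Assign each spot the soma label at its rounded pixel position.

    Spots over background get parent 0. The total number of spots is
    preserved: nothing is dropped here, only labeled.
    """
    somata = np.asarray(somata)
    if somata.ndim != 2:
        raise ValueError("soma label map must be 2-D")
    out = spots.copy()
    if len(out) == 0:
        out["parent"] = pd.Series(dtype=int)
        return out
    H, W = somata.shape
    px = np.clip(np.rint(out["x"].to_numpy()).astype(int), 0, W - 1)
    py = np.clip(np.rint(out["y"].to_numpy()).astype(int), 0, H - 1)
    if (out["x"] < -0.5).any() or (out["x"] > W - 0.5).any() or (
        out["y"] < -0.5
    ).any() or (out["y"] > H - 0.5).any():
        raise ValueError("spot coordinates fall outside the label-map frame")
    out["parent"] = somata[py, px]
    return out


def dots_per_cell(
    spots: pd.DataFrame,
    somata: np.ndarray,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Dots-per-cell table: one row per soma label, one count column per gene.

    Cells with zero dots in every channel are included; unassigned spots
    (parent 0) are excluded from all counts.
    """
    from .segment import object_table

    if "parent" not in spots.columns:
        spots = relate_spots_to_cells(spots, somata)
    cells = object_table(somata).rename(columns={"label": "cell_id"})
    if genes is None:
        genes = sorted(spots["gene"].dropna().unique())
    assigned = spots[spots["parent"] != 0]
    for gene in genes:
        counts = (
            assigned[assigned["gene"] == gene].groupby("parent").size()
            if len(assigned)
            else pd.Series(dtype=int)
        )
        cells[f"count_{gene}"] = (
            counts.reindex(cells["cell_id"], fill_value=0).to_numpy()
            if len(cells)
            else []
        )
    return cells
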