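"""Section-to-template alignment and laminar distribution of cell types.

Sections are aligned to the lamina template with a landmark-based
least-squares affine transform; cell centroids are then mapped into template
coordinates and binned into laminae by point-in-polygon tests, giving
per-lamina, per-hemisection counts of expressing cells. Laminae are tested
dorsal to ventral and boundary points go to the dorsal-most matching lamina;
cells outside every lamina are labeled ``outside``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .classify import _level_col
from .template import TissueTemplate

OUTSIDE = "outside"


@dataclass
class AffineTransform2D:
    """2-D affine map p -> matrix @ p + translation (section -> template)."""

    matrix: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(matrix=inv, translation=-inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(matrix=np.eye(2), translation=np.zeros(2))


def fit_alignment(
    landmarks_section, landmarks_template
) -> AffineTransform2D:
    """Least-squares affine mapping section landmarks onto template landmarks.

    Needs at least 3 non-collinear landmark pairs; reports the RMS residual
    of the fit over all landmarks.
    """
    src = np.atleast_2d(np.asarray(landmarks_section, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_template, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("landmark lists must be matched (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    design = np.column_stack([src, np.ones(n)])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("landmarks are collinear; affine fit is degenerate")
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = params[:2].T
    translation = params[2]
    resid = design @ params - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(matrix=matrix, translation=translation, residual_rms=rms)


def assign_lamina(
    cells: pd.DataFrame,
    transform: AffineTransform2D,
    template: TissueTemplate,
    x_col: str = "x",
    y_col: str = "y",
    out_col: str = "lamina_assigned",
) -> pd.DataFrame:
    """Map cell centroids through the transform and bin them into laminae.

    Boundary-inclusive containment (``covers``) plus the dorsal-to-ventral
    template order means a point on a shared lamina boundary goes to the
    dorsal-most matching lamina; each cell gets exactly one label.
    """
    out = cells.copy()
    pts = transform.apply(out[[x_col, y_col]].to_numpy())
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    label = np.full(len(out), OUTSIDE, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for name, poly in template.laminae:
        hit = unassigned & shapely.covers(poly, geoms)
        label[hit] = name
        unassigned &= ~hit
    out[out_col] = label
    return out


def lamina_counts(
    cells: pd.DataFrame,
    gene: str,
    template: TissueTemplate,
    level: str = "any",
    lamina_col: str = "lamina_assigned",
) -> pd.DataFrame:
    """Counts of level-passing cells per lamina per hemisection (long format).

    Every (animal, hemisection, lamina) combination appears, including zero
    counts and the ``outside`` bin, so counts over laminae + outside always
    partition the positive cells of a hemisection.
    """
    col = _level_col(gene, level)
    if col not in cells.columns:
        raise KeyError(f"no positivity calls for gene {gene!r}")
    laminae = template.lamina_names + [OUTSIDE]
    recs = []
    for (animal, section), sub in cells.groupby(["animal_id", "section_id"]):
        on = sub[sub[col].fillna(False).astype(bool)]
        counts = on[lamina_col].value_counts()
        for lam in laminae:
            recs.append(
                {
                    "gene": gene,
                    "lamina": lam,
                    "hemisection": section,
                    "animal": animal,
                    "count": int(counts.get(lam, 0)),
                }
            )
    return pd.DataFrame(recs)


def lamina_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-lamina mean/SD over hemisections (individual values kept
    in the long table; this is the overlay statistic)."""
    return (
        counts.groupby(["gene", "lamina"])["count"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n_hemisections"})
        .reset_index()
    )
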