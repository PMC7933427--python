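"""Positivity calling and co-expression quantification.

Background is calibrated per channel from a matched negative-control section:
the 90th nearest-rank percentile of its dots/cell distribution becomes the
threshold strictly above which a cell counts as positive. A second, fixed
threshold of 20 dots/cell (also strict) marks high expressors; a high call
implies a positive call. From the calls, triple-probe Venn region counts,
per-animal averages and pairwise co-expression matrices at two stringency
levels are computed. Ratios are always formed per animal (hemisections
pooled) and then averaged unweighted across animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BACKGROUND_PERCENTILE = 90.0
DEFAULT_HIGH_THRESHOLD = 20.0
#: study design defaults
DEFAULT_N_ANIMALS = 3
DEFAULT_HEMISECTIONS_PER_ANIMAL = 2

LEVELS = ("any", "high")


def nearest_rank_percentile(values, percentile: float) -> float:
    """Type-1 (nearest-rank) percentile: sorted value at rank ceil(p/100 * n).

    Integer-valued on integer count data, which keeps thresholds attainable;
    interpolating conventions would not.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty distribution")
    rank = math.ceil(percentile / 100.0 * arr.size)
    return float(arr[rank - 1])


@dataclass
class ThresholdSet:
    """Per-channel background thresholds plus the high-expression cutoff."""

    thresholds: dict[str, float]
    percentile: float = DEFAULT_BACKGROUND_PERCENTILE
    high_threshold: float = DEFAULT_HIGH_THRESHOLD

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.thresholds.values()):
            raise ValueError("background thresholds must be >= 0")

    def __getitem__(self, gene: str) -> float:
        return self.thresholds[gene]


def background_threshold(
    negctrl_cells: pd.DataFrame,
    genes: list[str] | None = None,
    percentile: float = DEFAULT_BACKGROUND_PERCENTILE,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> ThresholdSet:
    """Calibrate per-channel thresholds from a negative-control cell table.

    The negative control must come from the same probe combination and
    amplification scheme as the sections it calibrates.
    """
    if len(negctrl_cells) == 0:
        raise ValueError("negative-control cell table is empty: cannot calibrate")
    if genes is None:
        genes = [c[len("count_"):] for c in negctrl_cells.columns if c.startswith("count_")]
    thr = {
        g: nearest_rank_percentile(negctrl_cells[f"count_{g}"].to_numpy(), percentile)
        for g in genes
    }
    return ThresholdSet(thresholds=thr, percentile=percentile, high_threshold=high_threshold)


def call_positive(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Add per-gene positive/high boolean calls to a dots-per-cell table.

    positive <=> dots strictly above the background threshold;
    high <=> dots strictly above the high threshold AND positive.
    Calls are independent across genes. Count columns containing NaN (gene
    not hybridised on that section) yield NA calls.
    """
    out = cells.copy()
    genes = [c[len("count_"):] for c in cells.columns if c.startswith("count_")]
    for gene in genes:
        if gene not in thresholds.thresholds:
            raise KeyError(f"no background threshold for channel {gene!r}")
        dots = out[f"count_{gene}"]
        pos = dots > thresholds[gene]
        high = (dots > thresholds.high_threshold) & pos
        missing = dots.isna()
        out[f"pos_{gene}"] = pos.astype("boolean").mask(missing)
        out[f"high_{gene}"] = high.astype("boolean").mask(missing)
    return out


def _level_col(gene: str, level: str) -> str:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    return f"{'pos' if level == 'any' else 'high'}_{gene}"


def venn_counts(
    calls: pd.DataFrame, genes: tuple[str, str, str], level: str = "any"
) -> pd.DataFrame:
    """Triple-probe Venn region counts per animal, hemisections pooled.

    Returns a long table (animal_id, region, count) whose eight regions —
    the seven positive combinations plus ``none`` — partition the cells.
    Region labels join the positive genes with '+', e.g. ``A+B``.
    """
    if len(genes) != 3:
        raise ValueError("venn_counts needs exactly 3 genes")
    cols = [_level_col(g, level) for g in genes]
    for g, c in zip(genes, cols):
        if c not in calls.columns:
            raise KeyError(f"gene {g!r} absent from calls")
    recs = []
    for animal, sub in calls.groupby("animal_id"):
        flags = sub[cols].fillna(False).to_numpy(dtype=bool)
        for bits in range(8):
            sel = np.ones(len(sub), dtype=bool)
            members = []
            for j, g in enumerate(genes):
                if bits >> j & 1:
                    sel &= flags[:, j]
                    members.append(g)
                else:
                    sel &= ~flags[:, j]
            region = "+".join(members) if members else "none"
            recs.append({"animal_id": animal, "region": region, "count": int(sel.sum())})
    return pd.DataFrame(recs)


@dataclass
class CoexpressionMatrix:
    """Pairwise co-expression fractions plus the underlying counts.

    ``fraction[g, h]`` is the percentage of g-expressing cells that also
    express h, averaged unweighted over animals. ``n_expressing`` and
    ``n_both`` store the per-animal counts the fractions derive from, so the
    reciprocity identity 100 * N_gh = F[g,h] * N_g = F[h,g] * N_h can be
    checked before rounding.
    """

    genes: list[str]
    fraction: pd.DataFrame
    n_expressing: dict[int, pd.Series]
    n_both: dict[int, pd.DataFrame]
    #: n_denominator[a].loc[g, h] = number of g-expressing cells among the
    #: cells of animal a where genes g and h were hybridised together — the
    #: denominator behind fraction[g, h] for that animal.
    n_denominator: dict[int, pd.DataFrame] = field(default_factory=dict)
    per_animal_fraction: dict[int, pd.DataFrame] = field(default_factory=dict)
    level: str = "any"
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_animals(self) -> int:
        return len(self.n_expressing)


def pairwise_matrix(
    calls: pd.DataFrame,
    level: str = "any",
    high_both: bool = True,
) -> CoexpressionMatrix:
    """Pairwise co-expression matrix over all probe combinations.

    Only cells from sections where both genes of a pair were hybridised
    together enter that pair's counts (NaN counts mark unmeasured genes).
    At ``level='high'`` the >20 dots rule is applied to both genes of the
    pair by default (symmetric, keeps reciprocity meaningful); with
    ``high_both=False`` only the denominator gene must be high and the
    partner merely positive. Fractions are per-animal, then averaged
    unweighted. Pairs never co-hybridised are NaN and reported in
    ``missing_pairs`` with a warning.
    """
    genes = [c[len("pos_"):] for c in calls.columns if c.startswith("pos_")]
    animals = sorted(calls["animal_id"].unique())
    n_expr: dict[int, pd.Series] = {}
    n_both: dict[int, pd.DataFrame] = {}
    per_animal: dict[int, pd.DataFrame] = {}
    n_denom: dict[int, pd.DataFrame] = {}
    for a in animals:
        sub = calls[calls["animal_id"] == a]
        ne = pd.Series(0, index=genes, dtype=float)
        nb = pd.DataFrame(np.nan, index=genes, columns=genes)
        nd = pd.DataFrame(np.nan, index=genes, columns=genes)
        frac = pd.DataFrame(np.nan, index=genes, columns=genes)
        for g in genes:
            gcol = _level_col(g, level)
            for h in genes:
                hcol = _level_col(h, level)
                both_measured = sub[f"pos_{g}"].notna() & sub[f"pos_{h}"].notna()
                if not both_measured.any():
                    continue
                m = sub[both_measured]
                g_on = m[gcol].fillna(False).to_numpy(dtype=bool)
                if level == "high" and not high_both:
                    h_on = m[f"pos_{h}"].fillna(False).to_numpy(dtype=bool)
                else:
                    h_on = m[hcol].fillna(False).to_numpy(dtype=bool)
                n_g = int(g_on.sum())
                n_gh = int((g_on & h_on).sum())
                nb.loc[g, h] = n_gh
                nd.loc[g, h] = n_g
                if g == h:
                    ne[g] = max(ne[g], n_g)
                if n_g > 0:
                    frac.loc[g, h] = 100.0 * n_gh / n_g
        n_expr[a], n_both[a], n_denom[a], per_animal[a] = ne, nb, nd, frac

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair slices
        mean = (
            pd.concat(per_animal.values()).groupby(level=0).mean().reindex(genes)[genes]
        )
    missing = [
        (g, h)
        for g in genes
        for h in genes
        if g != h and all(np.isnan(n_both[a].loc[g, h]) for a in animals)
    ]
    for g, h in missing:
        warnings.warn(f"gene pair ({g}, {h}) never co-hybridised; fraction is missing")
    return CoexpressionMatrix(
        genes=genes,
        fraction=mean,
        n_expressing=n_expr,
        n_both=n_both,
        n_denominator=n_denom,
        per_animal_fraction=per_animal,
        level=level,
        missing_pairs=missing,
    )


def per_animal_average(values) -> tuple[float, float, int]:
    """Unweighted mean over animals, SD across animals (0 for n=1), and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one animal")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def matrix_to_json_bundle(matrix: CoexpressionMatrix) -> dict:
    """JSON-serialisable bundle of a co-expression matrix (counts + fractions)."""
    return {
        "level": matrix.level,
        "genes": matrix.genes,
        "n_animals": matrix.n_animals,
        "fraction_pct": matrix.fraction.round(6).to_dict(),
        "n_expressing": {int(a): s.to_dict() for a, s in matrix.n_expressing.items()},
        "n_both": {int(a): df.to_dict() for a, df in matrix.n_both.items()},
        "missing_pairs": [list(p) for p in matrix.missing_pairs],
    }
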