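"""Count-level translatome filtering and comparison logic.

Works on gene x sample matrices of raw counts with gene lengths and library
sizes. Normalized counts are reads per kilobase of gene per million mapped
reads; "expressed" genes exceed 10 normalized counts, in-situ-detectable
genes exceed 100 (both strict, on group means by default). Differential
gene sets are filtered at FDR <= 0.05 and fold ratio >= 2 (inclusive, as
printed), and the congruence of two comparisons is their gene-set overlap.

The FDR column is an external input in normal use (the published analysis
used dedicated DGEA packages, out of scope here); a built-in fixed-dispersion
negative-binomial likelihood-ratio test with Benjamini-Hochberg correction is
provided purely as a test oracle for simulated matrices and is not equivalent
to the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

EXPRESSED_THRESHOLD = 10.0
DETECTABLE_THRESHOLD = 100.0
DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_FOLD = 2.0


def normalize_counts(
    raw: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase per million: raw / (library/1e6) / (length/1e3)."""
    lengths = gene_lengths.reindex(raw.index)
    libs = library_sizes.reindex(raw.columns)
    if lengths.isna().any() or libs.isna().any():
        raise ValueError("gene lengths / library sizes do not cover the matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    return raw.div(libs / 1e6, axis=1).div(lengths / 1e3, axis=0)


def _group_columns(samples: pd.DataFrame, group: str) -> list[str]:
    cols = samples.loc[samples["group"] == group, "sample"].tolist()
    if not cols:
        raise KeyError(f"unknown group {group!r}")
    return cols


def count_expressed(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    group: str,
    threshold: float = EXPRESSED_THRESHOLD,
    per_sample_min: bool = False,
) -> int:
    """Number of genes whose group-mean normalized count strictly exceeds
    ``threshold`` (or whose per-sample minimum does, with ``per_sample_min``)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cols = _group_columns(samples, group)
    stat = normalized[cols].min(axis=1) if per_sample_min else normalized[cols].mean(axis=1)
    return int((stat > threshold).sum())


def de_filter(
    table: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> dict[str, set[str]]:
    """Split an enrichment table into direction gene sets.

    ``up``: FDR <= fdr_max and fold >= min_fold (enriched in group A);
    ``down``: FDR <= fdr_max and fold <= 1/min_fold (enriched in group B).
    Inequalities are inclusive at both boundaries. ``fold`` is the A/B ratio
    of group-mean normalized counts; the table index holds gene ids.
    """
    if "fdr" not in table.columns:
        raise ValueError("enrichment table must carry an 'fdr' column")
    if "fold" not in table.columns:
        raise ValueError("enrichment table must carry a 'fold' column")
    sig = table["fdr"] <= fdr_max
    up = set(table.index[sig & (table["fold"] >= min_fold)])
    down = set(table.index[sig & (table["fold"] <= 1.0 / min_fold)])
    return {"up": up, "down": down}


@dataclass
class Congruence:
    n_a: int
    n_b: int
    n_common: int

    @property
    def pct_of_a(self) -> float:
        return 100.0 * self.n_common / self.n_a if self.n_a else float("nan")

    @property
    def pct_of_b(self) -> float:
        return 100.0 * self.n_common / self.n_b if self.n_b else float("nan")


def congruence(set_a, set_b) -> Congruence:
    """Overlap of two enriched gene sets: |A|, |B|, |A ∩ B| and fractions."""
    a, b = set(set_a), set(set_b)
    return Congruence(n_a=len(a), n_b=len(b), n_common=len(a & b))


# --------------------------------------------------------------------------
# built-in NB test oracle
# --------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 0:  # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_rate(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of theta in mu_j = theta * s_j under NB with fixed dispersion."""
    naive = max(y.sum() / s.sum(), 1e-12)
    if alpha <= 0 or np.allclose(s, s[0]):
        return naive  # closed form: (weighted) mean
    res = optimize.minimize_scalar(
        lambda t: -_nb_loglik(y, np.exp(t) * s, alpha),
        bracket=(np.log(naive) - 2, np.log(naive) + 2),
        method="brent",
    )
    return float(np.exp(res.x))


def nb_two_group_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    gene_lengths: pd.Series,
    dispersion: float = 0.1,
) -> pd.DataFrame:
    """Fixed-dispersion NB likelihood-ratio test per gene, BH-corrected.

    A deliberately simple oracle for simulated matrices with known
    dispersion: means scale with library size, the null shares one rate
    across both groups, and 2*(ll1 - ll0) is referred to chi-square(1).
    Returns a table with group means (normalized), fold (A/B), p-value and
    BH FDR, indexed by gene. Not the published DGEA.
    """
    cols_a = _group_columns(samples, group_a)
    cols_b = _group_columns(samples, group_b)
    libs = samples.set_index("sample")["library_size"]
    s_a = (libs[cols_a] / 1e6).to_numpy()
    s_b = (libs[cols_b] / 1e6).to_numpy()
    norm = normalize_counts(counts, gene_lengths, libs)
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)

    pvals = np.ones(len(counts))
    for i, gene in enumerate(counts.index):
        ya = counts.loc[gene, cols_a].to_numpy(dtype=float)
        yb = counts.loc[gene, cols_b].to_numpy(dtype=float)
        if ya.sum() + yb.sum() == 0:
            continue
        y = np.concatenate([ya, yb])
        s = np.concatenate([s_a, s_b])
        th0 = _fit_rate(y, s, dispersion)
        ll0 = _nb_loglik(y, np.maximum(th0 * s, 1e-12), dispersion)
        tha = _fit_rate(ya, s_a, dispersion)
        thb = _fit_rate(yb, s_b, dispersion)
        ll1 = _nb_loglik(ya, np.maximum(tha * s_a, 1e-12), dispersion) + _nb_loglik(
            yb, np.maximum(thb * s_b, 1e-12), dispersion
        )
        lr = max(0.0, 2.0 * (ll1 - ll0))
        pvals[i] = stats.chi2.sf(lr, df=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b
    fold = fold.where(mean_b > 0, np.inf).where(mean_a + mean_b > 0, np.nan)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold": fold,
            "pvalue": pvals,
            "fdr": stats.false_discovery_control(pvals, method="bh"),
        },
        index=counts.index,
    )
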