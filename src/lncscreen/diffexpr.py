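"""FPKM computation, negative-binomial differential expression and the
clustering transform.

The differential-expression caller is a transparent stand-in for a full
DESeq2-style analysis: counts are normalized by median-of-ratios size
factors, per-gene dispersion is estimated by method of moments, and a Wald
test on the log fold change gives a two-sided p-value which is then
Benjamini-Hochberg adjusted.  It is isolated behind :func:`nb_test` /
:func:`de_table` so an externally produced DE table can be substituted.

Significance thresholds follow the strict conventions ``|log2FC| >
threshold`` and ``p_adj < alpha``, with threshold 2.0 for lncRNA calling and
1.0 for mRNA-level DEG calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEConfig",
    "LNCRNA_DE_CONFIG",
    "MRNA_DE_CONFIG",
    "compute_fpkm",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "call_de",
    "de_table",
    "cluster_transform",
]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for calling differential expression.

    ``lfc_threshold`` is on the log2 scale (2.0 for lncRNAs, 1.0 for mRNA
    DEGs); ``alpha`` bounds the BH-adjusted p-value; ``pseudocount`` (in
    normalized-count units) stabilizes fold changes at zero means.
    """

    lfc_threshold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


LNCRNA_DE_CONFIG = DEConfig(lfc_threshold=2.0)
MRNA_DE_CONFIG = DEConfig(lfc_threshold=1.0)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    ``FPKM[g, s] = counts[g, s] / (length_kb[g] * totals[s] / 1e6)``.
    ``totals`` defaults to per-sample column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be > 0")
    length_kb = lengths.to_numpy(dtype=float) / 1e3
    denom = np.outer(length_kb, totals.to_numpy(dtype=float) / 1e6)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / denom, index=counts.index, columns=counts.columns
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; genes with any zero count are excluded
    from the geometric reference (DESeq convention)."""
    x = counts.to_numpy(dtype=float)
    keep = (x > 0).all(axis=1)
    if not keep.any():
        return pd.Series(1.0, index=counts.columns)
    logx = np.log(x[keep])
    ref = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def _group_moments(norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return norm.mean(axis=1), norm.var(axis=1, ddof=1)


def nb_test(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    sf_a: np.ndarray | None = None,
    sf_b: np.ndarray | None = None,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Wald test of B vs A under a negative-binomial model.

    Counts are divided by size factors (estimated jointly by median-of-ratios
    when not given).  The log2 fold change is
    ``log2((mean_B + pc) / (mean_A + pc))`` on normalized counts.  A per-gene
    dispersion ``alpha`` (variance = mu + alpha * mu^2) is estimated by
    method of moments pooled across the two groups and floored at
    ``dispersion_floor``; the Wald statistic ``log(FC) / SE`` is referred to
    a t distribution with ``n_A + n_B - 1`` degrees of freedom, a
    small-sample reference that keeps the null rejection rate at the nominal
    level for n=3 designs (a normal reference is anticonservative there).

    Genes with all-zero counts in both groups get ``log2FC = 0, p = 1``.
    Returns ``(log2fc, p)`` arrays, two-sided.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("groups must be 2-D with matching gene rows")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per group")
    if sf_a is None or sf_b is None:
        joint = size_factors(
            pd.DataFrame(np.hstack([a, b]))
        ).to_numpy()
        sf_a, sf_b = joint[:n_a], joint[n_a:]
    na = a / np.asarray(sf_a)
    nb = b / np.asarray(sf_b)

    mu_a, var_a = _group_moments(na)
    mu_b, var_b = _group_moments(nb)
    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))

    # pooled MoM dispersion: alpha = (var - mu) / mu^2, averaged over groups
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
        alpha_b = np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
    alpha = np.maximum((alpha_a + alpha_b) / 2.0, dispersion_floor)

    # Var(log mean) ~ Var(mean) / mean^2 with NB variance mu + alpha mu^2
    mu_a_s = mu_a + pseudocount
    mu_b_s = mu_b + pseudocount
    se2 = (1.0 / mu_a_s + alpha) / n_a + (1.0 / mu_b_s + alpha) / n_b
    wald = np.log(mu_b_s / mu_a_s) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n_a + n_b - 1)

    allzero = (mu_a == 0) & (mu_b == 0)
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    return log2fc, np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, config: DEConfig = LNCRNA_DE_CONFIG
) -> pd.DataFrame:
    """Flag significance: ``|log2FC| > threshold`` and ``p_adj < alpha``,
    both strict."""
    out = results.copy()
    out["significant"] = (np.abs(out["log2FC"]) > config.lfc_threshold) & (
        out["p_adj"] < config.alpha
    )
    return out


def de_table(
    counts: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    config: DEConfig = LNCRNA_DE_CONFIG,
) -> pd.DataFrame:
    """Full DE pipeline for one contrast (B vs A): test, adjust, flag."""
    log2fc, p = nb_test(
        counts[samples_a], counts[samples_b], pseudocount=config.pseudocount
    )
    out = pd.DataFrame(
        {"log2FC": log2fc, "p": p, "p_adj": bh_adjust(p)}, index=counts.index
    )
    return call_de(out, config)


def cluster_transform(fpkm: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Heatmap-ready transform: ``log10(FPKM + 1e-6)``, then per-row z-score.

    Rows with zero variance map to all-zeros rather than NaN.
    """
    x = np.log10(fpkm.to_numpy(dtype=float) + pseudocount)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    return pd.DataFrame(z, index=fpkm.index, columns=fpkm.columns)
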