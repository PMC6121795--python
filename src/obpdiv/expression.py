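"""Count normalization, negative-binomial differential expression, and the
enrichment / direction / distribution-shift statistics.

The DE test is a deliberately transparent simplification of the shrinkage
estimators in mainstream RNA-Seq packages: median-of-ratios size factors, a
single pooled method-of-moments NB dispersion, and a normal-reference Wald
test on the log2 fold change.  The normal reference is appropriate because
the Wald standard error comes from the pooled model fit (thousands of
genes), not from a per-gene sample variance, so no small-sample t
correction applies.  The simplification is recorded in the result metadata
so downstream reports can say exactly what was run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_METHOD = "median-of-ratios + pooled MoM NB dispersion + normal Wald"


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2_fold_change: float
    p_value: float
    bh_adjusted_p: float
    significant: bool
    direction: int  # sign of the fold change (+1/-1/0)


@dataclass
class EnrichmentResult:
    statistic_name: str  # chi2-df1 | binomial-one-sided | ks-two-sample
    statistic: float
    p_value: float
    inputs: dict = field(default_factory=dict)


def size_factors(counts: pd.DataFrame, center: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene expressed in every sample, compute count / geometric mean
    across samples; a sample's factor is the median of those ratios (taken
    on the ratio scale).  With ``center=True`` factors are divided by their
    median so the typical sample has factor 1; only factor ratios are
    identified, so relative statements are centering-invariant.
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[expressed]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    if center:
        factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def pooled_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Single NB dispersion alpha pooled across genes, method of moments.

    Within-group variance and mean per gene give per-gene estimates
    alpha_g = (var - mean) / (mean^2 - var/n)  (the denominator corrects
    E[mean^2] for sampling noise), which are averaged into one pooled
    value; floor at 1e-8.
    """
    ests = []
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        mu_sq = m**2 - v / n
        ok = (m > 0) & (mu_sq > 0)
        ests.append((v[ok] - m[ok]) / mu_sq[ok])
    if not ests:
        return 1e-8
    all_ests = np.concatenate(ests)
    if all_ests.size == 0:
        return 1e-8
    return float(max(np.mean(all_ests), 1e-8))


def nb_wald_test(
    counts: pd.DataFrame,
    condition: pd.Series,
    alpha: float = 0.05,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Two-group differential expression on a gene x sample count matrix.

    ``condition`` maps sample -> one of exactly two levels; the log2 fold
    change is level2 over level1 (levels sorted).  All-zero genes are
    reported with NA statistics and excluded from the BH adjustment.
    Returns a DataFrame with one row per gene.
    """
    cond = condition.loc[counts.columns]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    idx_a = np.where(cond.to_numpy() == levels[0])[0]
    idx_b = np.where(cond.to_numpy() == levels[1])[0]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each condition needs >= 2 samples")
    sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    if dispersion is None:
        dispersion = pooled_dispersion(norm, [idx_a, idx_b])
    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    nonzero = (mu_a > 0) & (mu_b > 0)
    # Var(log mu_hat) ~ (1/mu + alpha) / n for NB counts, delta method
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_b / mu_a)
        var_log = (1 / mu_a + dispersion) / len(idx_a) + (
            1 / mu_b + dispersion
        ) / len(idx_b)
        se_lfc = np.sqrt(var_log) / np.log(2)
        wald = lfc / se_lfc
    pvals = np.full(len(counts), np.nan)
    pvals[nonzero] = 2 * stats.norm.sf(np.abs(wald[nonzero]))
    padj = np.full(len(counts), np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": norm.mean(axis=1),
            "log2_fold_change": np.where(nonzero, lfc, np.nan),
            "p_value": pvals,
            "bh_adjusted_p": padj,
        }
    )
    out["significant"] = out["bh_adjusted_p"] < alpha
    out["direction"] = np.sign(out["log2_fold_change"]).fillna(0).astype(int)
    out.attrs["method"] = DE_METHOD
    out.attrs["dispersion"] = dispersion
    out.attrs["comparison"] = f"{levels[1]} vs {levels[0]}"
    return out


def region_enrichment_chi2(
    n_de_in_region: int, n_de_total: int, expected_proportion: float
) -> EnrichmentResult:
    """One-proportion goodness-of-fit chi-square (df=1, no continuity
    correction) for over-representation of DE genes in a region."""
    if n_de_total <= 0:
        raise ValueError("zero DE genes")
    if not 0 < expected_proportion < 1:
        raise ValueError("expected proportion must be in (0, 1)")
    if n_de_in_region > n_de_total:
        raise ValueError("region count exceeds total")
    e_in = n_de_total * expected_proportion
    e_out = n_de_total - e_in
    o_in, o_out = n_de_in_region, n_de_total - n_de_in_region
    chi2 = (o_in - e_in) ** 2 / e_in + (o_out - e_out) ** 2 / e_out
    return EnrichmentResult(
        statistic_name="chi2-df1",
        statistic=float(chi2),
        p_value=chi2_upper_p(chi2),
        inputs={
            "observed_proportion": n_de_in_region / n_de_total,
            "expected_proportion": expected_proportion,
            "n": n_de_total,
        },
    )


def chi2_upper_p(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value."""
    return float(stats.chi2.sf(statistic, df))


def direction_binomial_test(k_same_direction: int, n_significant: int) -> EnrichmentResult:
    """One-sided exact binomial tail P(X >= k | n, 1/2): do significant
    genes share a direction more often than a fair coin would?"""
    if n_significant == 0:
        raise ValueError("no significant genes to test")
    if k_same_direction > n_significant:
        raise ValueError("k exceeds n")
    res = stats.binomtest(k_same_direction, n_significant, p=0.5, alternative="greater")
    return EnrichmentResult(
        statistic_name="binomial-one-sided",
        statistic=float(k_same_direction),
        p_value=float(res.pvalue),
        inputs={"k": k_same_direction, "n": n_significant, "null_p": 0.5},
    )


def ks_pvalue_shift(
    target_pvalues: Sequence[float], rest_pvalues: Sequence[float]
) -> EnrichmentResult:
    """Two-sample two-sided Kolmogorov-Smirnov test: are the target set's
    DE p-values shifted relative to the remaining genes?  Exact enumeration
    when both samples have n <= 10, asymptotic otherwise."""
    a = np.asarray(target_pvalues, dtype=float)
    b = np.asarray(rest_pvalues, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both p-value sets must be non-empty")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return EnrichmentResult(
        statistic_name="ks-two-sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        inputs={"n_target": int(a.size), "n_rest": int(b.size), "method": method},
    )
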