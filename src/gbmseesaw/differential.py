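"""Per-gene differential methylation and expression between two conditions.

Differential methylation
------------------------
Each gene's per-sample (methylated, total) read-count pairs are modelled
as binomial with a common methylation proportion per condition. Because
the two-group binomial GLM has closed-form maximum-likelihood estimates
(the condition-pooled proportions), the likelihood-ratio statistic against
the intercept-only model is computed exactly and referred to chi-square
with 1 df. An optional Pearson overdispersion correction divides the
statistic by the null-model dispersion when that exceeds 1. Effects are
reported both as percentage-point differences of pooled percents and as a
log2 ratio of pseudocounted pooled proportions.

Differential expression
-----------------------
Counts are normalized with median-of-ratios size factors. The effect is
the log2 ratio of pseudocounted normalized condition means. Each gene's
negative-binomial dispersion is estimated by method of moments pooled
across the two conditions; the Wald statistic divides the log2 fold
change by a delta-method standard error whose variance term is the NB
plug-in floored at the empirical variance of the group means, and is
referred to a t distribution with n1 + n2 - 2 df. The empirical floor
and t reference keep the test's size near nominal at the small replicate
numbers (3-6 per group) typical of these designs, where a plain normal
reference on the plug-in variance is markedly anticonservative.

Both tables are Benjamini-Hochberg adjusted over their tested genes.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import ContrastSpec, GbmError, MethLevelTable, validate_count_matrix

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over ascending p-values, capped
    at 1 and mapped back to input order. Missing entries are excluded from
    n and returned missing.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise GbmError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    q = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    qv = np.empty(n)
    qv[order] = q
    out[mask] = qv
    return out


def _binom_ll(m: np.ndarray, c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel; exact at the p in {0,1} boundary."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(m > 0, m * np.log(np.where(p > 0, p, 1.0)), 0.0)
        t2 = np.where(c - m > 0, (c - m) * np.log(np.where(p < 1, 1 - p, 1.0)), 0.0)
    # impossible data under the hypothesised p (m>0 with p=0 etc.) -> -inf
    t1 = np.where((m > 0) & (p == 0), -np.inf, t1)
    t2 = np.where((c - m > 0) & (p == 1), -np.inf, t2)
    return t1 + t2


def _resolve_groups(
    columns: pd.Index, groups: Mapping[str, str], contrast: ContrastSpec
) -> tuple[list[str], list[str]]:
    s1 = [s for s in columns if groups.get(s) == contrast.condition1]
    s2 = [s for s in columns if groups.get(s) == contrast.condition2]
    if not s1 or not s2:
        raise GbmError(
            f"contrast {contrast.condition1!r} vs {contrast.condition2!r}: "
            f"both conditions need samples among {list(columns)}"
        )
    return s1, s2


def diff_methylation(
    levels: MethLevelTable,
    groups: Mapping[str, str],
    contrast: ContrastSpec,
    overdispersion: str = "none",
    min_samples_per_condition: int = 2,
    ratio_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Binomial-GLM likelihood-ratio test for differential methylation.

    Parameters
    ----------
    levels
        Gene x sample summed counts from the quantification step; cells
        already filtered to missing there are ineligible here.
    groups
        sample_id -> condition label.
    contrast
        Effects are condition2 minus/over condition1.
    overdispersion
        'pearson' divides the LRT statistic by the null-model Pearson
        dispersion when it exceeds 1; 'none' uses the plain statistic.
    min_samples_per_condition
        Genes with fewer eligible samples in either condition are left
        untested (NaN p and q).

    Returns
    -------
    DataFrame indexed by gene_id with columns meth_diff (percentage
    points), log2_meth_ratio, p_value, q_value, tested, separated.
    """
    if overdispersion not in {"none", "pearson"}:
        raise GbmError(f"unknown overdispersion mode {overdispersion!r}")
    if min_samples_per_condition < 1:
        raise GbmError("min_samples_per_condition must be >= 1")
    s1, s2 = _resolve_groups(levels.samples, groups, contrast)

    meth = levels.meth.to_numpy(dtype=float)
    cov = levels.cov.to_numpy(dtype=float)
    eligible = levels.pct.notna().to_numpy()
    idx1 = levels.samples.get_indexer(s1)
    idx2 = levels.samples.get_indexer(s2)

    def pooled(idx):
        el = eligible[:, idx]
        m = np.where(el, meth[:, idx], 0.0).sum(axis=1)
        c = np.where(el, cov[:, idx], 0.0).sum(axis=1)
        return m, c, el.sum(axis=1)

    m1, c1, n1 = pooled(idx1)
    m2, c2, n2 = pooled(idx2)
    tested = (n1 >= min_samples_per_condition) & (n2 >= min_samples_per_condition)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(c1 > 0, m1 / np.where(c1 > 0, c1, 1), np.nan)
        p2 = np.where(c2 > 0, m2 / np.where(c2 > 0, c2, 1), np.nan)
        p0 = np.where(c1 + c2 > 0, (m1 + m2) / np.where(c1 + c2 > 0, c1 + c2, 1), np.nan)

    # group MLEs are the pooled proportions, so the LRT is closed-form
    ll_full = _binom_ll(m1, c1, p1) + _binom_ll(m2, c2, p2)
    ll_null = _binom_ll(m1, c1, p0) + _binom_ll(m2, c2, p0)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)

    if overdispersion == "pearson":
        idx12 = np.concatenate([idx1, idx2])
        el = eligible[:, idx12]
        mi = np.where(el, meth[:, idx12], 0.0)
        ci = np.where(el, cov[:, idx12], 0.0)
        mu = ci * p0[:, None]
        denom = ci * (p0 * (1 - p0))[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(denom > 0, (mi - mu) ** 2 / np.where(denom > 0, denom, 1), 0.0)
        n_el = el.sum(axis=1)
        df_disp = np.maximum(n_el - 1, 1)
        phi = contrib.sum(axis=1) / df_disp
        lrt = np.where(phi > 1, lrt / np.where(phi > 1, phi, 1), lrt)

    p_value = stats.chi2.sf(lrt, df=1)
    p_value[~tested] = np.nan

    meth_diff = 100.0 * (p2 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(
            ((m2 + ratio_pseudocount) / (c2 + 2 * ratio_pseudocount))
            / ((m1 + ratio_pseudocount) / (c1 + 2 * ratio_pseudocount))
        )
    boundary = (np.isin(p1, (0.0, 1.0)) | np.isin(p2, (0.0, 1.0)))
    separated = tested & boundary & (p1 != p2)

    out = pd.DataFrame(
        {
            "meth_diff": np.where(tested, meth_diff, np.nan),
            "log2_meth_ratio": np.where(tested, log2_ratio, np.nan),
            "p_value": p_value,
            "q_value": bh_fdr(p_value),
            "tested": tested,
            "separated": separated,
        },
        index=levels.gene_ids,
    )
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    Each sample's factor is the median over genes of count divided by the
    gene's geometric mean across samples, using genes whose geometric
    mean is positive. When no gene is positive in every sample, the
    geometric mean is taken over each gene's positive entries and each
    sample's median runs over genes positive in that sample (logged).
    """
    counts = validate_count_matrix(counts)
    arr = counts.to_numpy(dtype=float)
    if arr.shape[0] == 0:
        raise GbmError("size_factors: empty count matrix")
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0][0]
        raise GbmError(f"size_factors: sample {bad!r} has no nonzero counts")
    all_pos = (arr > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logs = np.log(arr, where=arr > 0, out=np.full_like(arr, np.nan))
    if all_pos.any():
        geo = np.exp(logs[all_pos].mean(axis=1))
        ratios = arr[all_pos] / geo[:, None]
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "size_factors: no gene positive in every sample; falling back "
            "to per-sample medians over that sample's positive genes"
        )
        pos_any = (arr > 0).any(axis=1)
        geo = np.exp(np.nanmean(logs[pos_any], axis=1))
        sub = arr[pos_any]
        factors = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            col = sub[:, j]
            factors[j] = np.median(col[col > 0] / geo[col > 0])
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise GbmError("size_factors: non-positive or non-finite factor")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def diff_expression(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    contrast: ContrastSpec,
    min_total: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test for differential expression.

    Parameters
    ----------
    counts
        Raw gene x sample counts; only the contrast's samples are used.
    min_total
        Genes whose raw count total over the contrast samples falls below
        this are untested.
    pseudocount
        Normalized units added to each condition mean before the log2
        ratio.

    Returns
    -------
    DataFrame indexed by gene_id with columns log2_fold_change, base_mean,
    dispersion, p_value, q_value, tested.
    """
    counts = validate_count_matrix(counts)
    s1, s2 = _resolve_groups(counts.columns, groups, contrast)
    if len(s1) < 2 or len(s2) < 2:
        raise GbmError("diff_expression requires >= 2 samples per condition")
    sub = counts[s1 + s2]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    n1, n2 = len(s1), len(s2)
    y1, y2 = norm[:, :n1], norm[:, n1:]

    total_raw = sub.to_numpy().sum(axis=1)
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    tested = (total_raw >= min_total) & ((m1 > 0) | (m2 > 0))

    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    # method-of-moments NB dispersion pooled across conditions
    num = (v1 - m1) * (n1 - 1) + (v2 - m2) * (n2 - 1)
    den = m1**2 * (n1 - 1) + m2**2 * (n2 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    ln2sq = np.log(2.0) ** 2
    c1 = 1.0 / ((m1 + pseudocount) ** 2 * ln2sq)
    c2 = 1.0 / ((m2 + pseudocount) ** 2 * ln2sq)
    v_nb = (m1 + alpha * m1**2) / n1 * c1 + (m2 + alpha * m2**2) / n2 * c2
    v_emp = v1 / n1 * c1 + v2 / n2 * c2
    var = np.maximum(v_nb, v_emp)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(var > 0, log2fc / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    p_value = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    p_value = np.minimum(p_value, 1.0)
    p_value[~tested] = np.nan

    out = pd.DataFrame(
        {
            "log2_fold_change": np.where(tested, log2fc, np.nan),
            "base_mean": norm.mean(axis=1),
            "dispersion": np.where(tested, alpha, np.nan),
            "p_value": p_value,
            "q_value": bh_fdr(p_value),
            "tested": tested,
        },
        index=counts.index,
    )
    return out
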