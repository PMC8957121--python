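"""Methylation classes, GBM-expression correlations, and the seesaw test.

Invertebrate gene-body methylation is bimodal, splitting coding genes
into a lowly and a highly methylated class; here the split is a hard
cutoff on mean percent methylation (default 2.5%, ties to the high
class). The module quantifies

* baseline relationships: correlation of log2 GBM with mean expression,
  with the magnitude of between-condition expression differences, and
  with the coefficient of variation across control replicates;
* differential relationships: correlation between per-gene methylation
  changes and expression changes, optionally restricted to significantly
  differentially expressed or methylated genes;
* the three-component "seesaw" hypothesis: (1) the two classes shift
  their methylation in opposite directions between conditions, (2) they
  shift their transcription in opposite directions, and (3) within each
  class transcription moves opposite to methylation. Class-level mean
  shifts get percentile bootstrap confidence intervals over genes; a
  component is "supported" only when the relevant CIs exclude zero with
  the required sign pattern, "inconclusive" when a class has too few
  genes to call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import differential, methylation_quant
from .types import (
    ContrastSpec,
    CorrelationResult,
    GbmError,
    INCONCLUSIVE,
    MethLevelTable,
    NEGATIVE,
    NOT_SUPPORTED,
    NULL,
    POSITIVE,
    SUPPORTED,
    SeesawSummary,
)

logger = logging.getLogger(__name__)


def assign_classes(
    mean_pct: pd.Series | MethLevelTable, cutoff: float = 2.5
) -> pd.DataFrame:
    """Split genes into lowly/highly methylated classes at a hard cutoff.

    A gene is ``high`` iff its mean percent methylation is >= ``cutoff``
    (a closed upper class makes the tie deterministic). Genes with a
    missing basis are omitted.

    Returns a DataFrame indexed by gene_id with columns ``meth_class``
    and ``basis``.
    """
    if isinstance(mean_pct, MethLevelTable):
        mean_pct = mean_pct.mean_pct
    basis = mean_pct.dropna()
    cls = np.where(basis >= cutoff, "high", "low")
    return pd.DataFrame({"meth_class": cls, "basis": basis}, index=basis.index)


def bimodality_valley_width(
    values, bin_width: float = 0.25, rel_height: float = 0.25
) -> float:
    """Width (in x units) of the deepest valley separating two modes.

    Histograms the values, takes the global maximum bin as one mode, and
    for every candidate second mode measures the widest contiguous run of
    bins between the two peaks whose counts fall below ``rel_height``
    times the smaller peak; the best such run's width is returned (0.0
    when the distribution has no such valley, i.e. looks unimodal).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10 or np.ptp(v) == 0:
        return 0.0
    edges = np.arange(v.min(), v.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    i1 = int(np.argmax(counts))
    best = 0.0
    for j in range(len(counts)):
        a, b = min(i1, j), max(i1, j)
        if b - a < 2:
            continue
        thresh = rel_height * min(counts[i1], counts[j])
        if thresh <= 0:
            continue
        below = counts[a + 1 : b] < thresh
        run = longest = 0
        for flag in below:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        best = max(best, longest * bin_width)
    return best


def _paired(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    return joined["x"].to_numpy(), joined["y"].to_numpy()


def _correlate(xv: np.ndarray, yv: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(xv, yv).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xv, yv).statistic)
    raise GbmError(f"unknown correlation method {method!r}")


def baseline_correlation(
    gbm: pd.Series,
    expr_summary: pd.Series,
    method: str = "pearson",
    variable_x: str = "log2_gbm",
    variable_y: str = "expr_summary",
) -> CorrelationResult:
    """Correlate a per-gene GBM summary with a per-gene expression summary.

    Pairs with either value missing are dropped; fewer than 3 complete
    pairs is an error, zero variance on either axis yields a missing r
    with a warning.
    """
    xv, yv = _paired(gbm, expr_summary)
    if len(xv) < 3:
        raise GbmError(f"baseline_correlation: only {len(xv)} complete pairs (< 3)")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("baseline_correlation: zero variance on one axis")
        r = np.nan
    else:
        r = _correlate(xv, yv, method)
    return CorrelationResult(variable_x, variable_y, n=len(xv), r=r, method=method)


def coefficient_of_variation(rpkm: pd.DataFrame) -> pd.Series:
    """Per-gene CV (sd / mean, n-1 denominator) across control replicates.

    Missing where the mean is zero. Requires >= 2 control columns.
    """
    if rpkm.shape[1] < 2:
        raise GbmError("coefficient_of_variation requires >= 2 control samples")
    mean = rpkm.mean(axis=1)
    sd = rpkm.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    cv.name = "cv"
    return cv


def delta_correlation(
    dm: pd.DataFrame,
    de: pd.DataFrame,
    subset: str = "all",
    alpha: float = 0.1,
    method: str = "pearson",
    meth_effect: str = "log2_meth_ratio",
    expr_effect: str = "log2_fold_change",
) -> CorrelationResult:
    """Correlate per-gene methylation changes with expression changes.

    ``subset='de_only'`` keeps genes with expression q <= alpha,
    ``'dm_only'`` keeps genes with methylation q <= alpha. When fewer
    than 3 genes remain the result carries a missing r and the n that
    was left.
    """
    if subset not in {"all", "de_only", "dm_only"}:
        raise GbmError(f"unknown subset {subset!r}")
    x = dm[meth_effect]
    y = de[expr_effect]
    if subset == "de_only":
        keep = de.index[de["q_value"] <= alpha]
        x, y = x.reindex(keep), y.reindex(keep)
    elif subset == "dm_only":
        keep = dm.index[dm["q_value"] <= alpha]
        x, y = x.reindex(keep), y.reindex(keep)
    xv, yv = _paired(x, y)
    if len(xv) < 3:
        logger.warning("delta_correlation: %d genes after subsetting (< 3)", len(xv))
        r = np.nan
    elif np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("delta_correlation: zero variance on one axis")
        r = np.nan
    else:
        r = _correlate(xv, yv, method)
    return CorrelationResult(
        meth_effect, expr_effect, n=len(xv), r=r, method=method, subset=subset
    )


def _boot_mean_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator, chunk: int = 250
) -> tuple[float, float]:
    """Percentile 95% CI of the mean by gene resampling, chunked for memory."""
    n = values.size
    means = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        means[done : done + b] = values[idx].mean(axis=1)
        done += b
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def _verdict(ci_lo: float, ci_hi: float) -> str:
    if ci_lo > 0:
        return POSITIVE
    if ci_hi < 0:
        return NEGATIVE
    return NULL


def seesaw_test(
    classes: pd.DataFrame,
    dm: pd.DataFrame,
    de: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    min_class_size: int = 20,
    meth_effect: str = "log2_meth_ratio",
    expr_effect: str = "log2_fold_change",
) -> SeesawSummary:
    """Class-level mean shifts in methylation and transcription.

    For each class x variable the mean shift over all genes with a
    non-missing effect is reported with a seeded percentile bootstrap
    95% CI (gene resampling); classes below ``min_class_size`` genes get
    no verdict and make the affected components inconclusive. Gene
    values are processed in gene-id order so results do not depend on
    input row order.
    """
    rng = np.random.default_rng(seed)
    effects = {"delta_gbm": dm[meth_effect], "delta_expr": de[expr_effect]}
    rows = []
    verdicts: dict[tuple[str, str], str | None] = {}
    for cls in ("low", "high"):
        genes_in_class = classes.index[classes["meth_class"] == cls]
        for var, series in effects.items():
            vals = series.reindex(genes_in_class).dropna().sort_index()
            v = vals.to_numpy(dtype=float)
            if v.size < min_class_size:
                logger.warning(
                    "seesaw: class %r has %d genes with %s (< %d); inconclusive",
                    cls, v.size, var, min_class_size,
                )
                rows.append((cls, var, np.nan, np.nan, np.nan, v.size, INCONCLUSIVE))
                verdicts[(cls, var)] = None
                continue
            lo, hi = _boot_mean_ci(v, n_boot, rng)
            verdict = _verdict(lo, hi)
            rows.append((cls, var, float(v.mean()), lo, hi, v.size, verdict))
            verdicts[(cls, var)] = verdict
    class_stats = pd.DataFrame(
        rows, columns=["meth_class", "variable", "mean", "ci_lo", "ci_hi", "n", "verdict"]
    ).set_index(["meth_class", "variable"])

    def reciprocal(var: str) -> str:
        a, b = verdicts[("low", var)], verdicts[("high", var)]
        if a is None or b is None:
            return INCONCLUSIVE
        if {a, b} == {POSITIVE, NEGATIVE}:
            return SUPPORTED
        return NOT_SUPPORTED

    def opposite_within_classes() -> str:
        states = []
        for cls in ("low", "high"):
            g, e = verdicts[(cls, "delta_gbm")], verdicts[(cls, "delta_expr")]
            if g is None or e is None:
                return INCONCLUSIVE
            states.append({g, e} == {POSITIVE, NEGATIVE})
        return SUPPORTED if all(states) else NOT_SUPPORTED

    return SeesawSummary(
        class_stats=class_stats,
        c1_reciprocal_gbm=reciprocal("delta_gbm"),
        c2_reciprocal_expression=reciprocal("delta_expr"),
        c3_opposite_directions=opposite_within_classes(),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass
class AnalysisParams:
    """Tunables for a full study run, with the pipeline's defaults."""

    cutoff: float = 2.5
    min_gene_cov: int = 10
    promoter_width: int = 1000
    alpha_fdr: float = 0.1
    min_total: int = 10
    n_boot: int = 2000
    seed: int = 0
    corr_method: str = "pearson"
    overdispersion: str = "none"
    min_class_size: int = 20


@dataclass
class StudyResult:
    """Everything :func:`run_study` computes for one study."""

    params: AnalysisParams
    gbm_levels: MethLevelTable
    log2_gbm: pd.Series
    classes: pd.DataFrame
    rpkm: pd.DataFrame
    mean_log2_rpkm: pd.Series
    cv: pd.Series | None
    diff_gbm: pd.DataFrame
    diff_expr: pd.DataFrame
    promoter_levels: MethLevelTable | None
    diff_promoter: pd.DataFrame | None
    correlations: list[CorrelationResult] = field(default_factory=list)
    seesaw: SeesawSummary | None = None

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.correlations])


def run_study(
    cpg_reports: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    rnaseq_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: ContrastSpec,
    params: AnalysisParams | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> StudyResult:
    """Run the full analysis for one study on in-memory inputs.

    Quantifies gene-body and promoter methylation from the per-sample
    cytosine reports, expression from the RNA-seq counts, computes the
    baseline correlations, differential tables, change-change
    correlations (gene body and promoter, including FDR-restricted
    subsets), class assignment, and the seesaw summary.
    """
    params = params or AnalysisParams()
    groups = sample_sheet["condition"].to_dict()

    wgbs_samples = [s for s in cpg_reports if s in sample_sheet.index]
    if set(cpg_reports) - set(wgbs_samples):
        raise GbmError("cytosine reports include samples absent from the sheet")

    levels = methylation_quant.gene_percent_methylation(
        cpg_reports, genes, min_gene_cov=params.min_gene_cov
    )
    log2_gbm = methylation_quant.log2_with_zero_rule(levels.mean_pct)
    classes = assign_classes(levels.mean_pct, cutoff=params.cutoff)

    rna_sheet = sample_sheet[sample_sheet["assay"] == "rnaseq"]
    rna_counts = rnaseq_counts[[s for s in rnaseq_counts.columns if s in rna_sheet.index]]
    rpkm_table = methylation_quant.rpkm(rna_counts, genes)
    mean_rpkm = rpkm_table.mean(axis=1)
    mean_rpkm.name = "mean_rpkm"
    mean_log2_rpkm = methylation_quant.log2_with_zero_rule(mean_rpkm)

    control_cols = rna_sheet.index[rna_sheet["is_control"]]
    cv = None
    if len(control_cols) >= 2:
        cv = coefficient_of_variation(rpkm_table[list(control_cols)])

    diff_gbm = differential.diff_methylation(
        levels, groups, contrast, overdispersion=params.overdispersion
    )
    diff_expr = differential.diff_expression(
        rna_counts, groups, contrast, min_total=params.min_total
    )

    windows = methylation_quant.promoter_windows(
        genes, width=params.promoter_width, contig_lengths=contig_lengths
    )
    promoter_levels = diff_promoter = None
    if len(windows):
        promoter_levels = methylation_quant.promoter_percent_methylation(
            cpg_reports, windows, min_cov=params.min_gene_cov
        )
        diff_promoter = differential.diff_methylation(
            promoter_levels, groups, contrast, overdispersion=params.overdispersion
        )

    correlations = [
        baseline_correlation(
            log2_gbm, mean_log2_rpkm, method=params.corr_method,
            variable_x="log2_gbm", variable_y="mean_log2_rpkm",
        ),
        baseline_correlation(
            log2_gbm, diff_expr["log2_fold_change"].abs(), method=params.corr_method,
            variable_x="log2_gbm", variable_y="abs_log2_fold_change",
        ),
    ]
    if cv is not None:
        correlations.append(
            baseline_correlation(
                log2_gbm, cv, method=params.corr_method,
                variable_x="log2_gbm", variable_y="cv",
            )
        )
    for subset in ("all", "de_only", "dm_only"):
        correlations.append(
            delta_correlation(
                diff_gbm, diff_expr, subset=subset,
                alpha=params.alpha_fdr, method=params.corr_method,
            )
        )
    if diff_promoter is not None:
        res = delta_correlation(
            diff_promoter, diff_expr, subset="all",
            alpha=params.alpha_fdr, method=params.corr_method,
        )
        res.variable_x = "promoter_" + res.variable_x
        correlations.append(res)

    seesaw = seesaw_test(
        classes, diff_gbm, diff_expr,
        n_boot=params.n_boot, seed=params.seed,
        min_class_size=params.min_class_size,
    )

    return StudyResult(
        params=params,
        gbm_levels=levels,
        log2_gbm=log2_gbm,
        classes=classes,
        rpkm=rpkm_table,
        mean_log2_rpkm=mean_log2_rpkm,
        cv=cv,
        diff_gbm=diff_gbm,
        diff_expr=diff_expr,
        promoter_levels=promoter_levels,
        diff_promoter=diff_promoter,
        correlations=correlations,
        seesaw=seesaw,
    )
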