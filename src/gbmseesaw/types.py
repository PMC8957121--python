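"""Shared domain types and table schemas.

Tabular data flows through the pipeline as pandas objects with fixed,
documented schemas rather than as collections of record objects:

``cpg table``
    One cytosine per row: columns ``chrom`` (str), ``pos`` (int, 1-based),
    ``strand`` ({'+','-'}), ``meth_count`` (int >= 0), ``unmeth_count``
    (int >= 0). Sorted by (chrom, pos). Only CpG-context cytosines are kept.

``gene table``
    Indexed by unique ``gene_id``: columns ``chrom``, ``start``, ``end``
    (1-based inclusive, start <= end), ``strand``, ``length``
    (= end - start + 1). Promoter windows reuse this schema.

``count matrix``
    genes x samples DataFrame of non-negative integers; index is gene_id,
    columns are sample_ids.

``sample sheet``
    Indexed by ``sample_id``: columns ``condition``, ``assay`` (one of
    {'wgbs','rnaseq','mbd','mdrad'}), ``fraction`` ({'captured','unbound',
    'none'}), ``is_control`` (bool). MBD sheets additionally carry
    ``pair_id`` linking each captured column to its unbound partner.

``differential table``
    Indexed by gene_id: effect column(s), ``p_value``, ``q_value``,
    ``tested`` (bool). Untested genes carry NaN p and q.

The light-weight record/spec classes below exist for row-wise construction,
validation, and for carrying results that are not naturally tabular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

VALID_STRANDS = frozenset({"+", "-"})
VALID_ASSAYS = frozenset({"wgbs", "rnaseq", "mbd", "mdrad"})
VALID_FRACTIONS = frozenset({"captured", "unbound", "none"})

CPG_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count"]
GENE_COLUMNS = ["chrom", "start", "end", "strand", "length"]


class GbmError(ValueError):
    """Base class for data and contract violations raised by this package."""


class ParseError(GbmError):
    """A malformed input file; the message names the offending line."""


class CpGRecord(NamedTuple):
    """One cytosine's methylated/unmethylated read counts for one sample."""

    chrom: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    def validate(self) -> "CpGRecord":
        if self.pos < 1:
            raise GbmError(f"CpG position must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise GbmError(f"invalid strand {self.strand!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise GbmError("negative methylation counts")
        return self


class GeneModel(NamedTuple):
    """A gene's span on a contig; coordinates are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate(self) -> "GeneModel":
        if not (1 <= self.start <= self.end):
            raise GbmError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end}]"
            )
        if self.strand not in VALID_STRANDS:
            raise GbmError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        return self


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast: condition2 is compared against condition1."""

    condition1: str
    condition2: str
    assay: str = "rnaseq"
    alpha_fdr: float = 0.1

    def __post_init__(self) -> None:
        if self.condition1 == self.condition2:
            raise GbmError("contrast requires two distinct condition labels")
        if not (0 < self.alpha_fdr <= 1):
            raise GbmError(f"alpha_fdr must be in (0, 1], got {self.alpha_fdr}")


@dataclass
class MethLevelTable:
    """Gene x sample methylation levels plus the summed counts behind them.

    Attributes
    ----------
    meth, cov : DataFrame (genes x samples)
        Methylated read counts and total read coverage summed over all CpG
        sites inside each gene (or promoter window) per sample.
    pct : DataFrame (genes x samples)
        ``100 * meth / cov`` where coverage passes the minimum filter, NaN
        otherwise.
    mean_pct : Series (genes)
        Per-gene percent methylation averaged over non-missing samples.
    """

    meth: pd.DataFrame
    cov: pd.DataFrame
    pct: pd.DataFrame
    mean_pct: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_pct is None:
            self.mean_pct = self.pct.mean(axis=1, skipna=True)
            self.mean_pct.name = "mean_pct_meth"

    @property
    def gene_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def samples(self) -> pd.Index:
        return self.meth.columns


@dataclass
class CorrelationResult:
    """A named correlation between two per-gene summaries."""

    variable_x: str
    variable_y: str
    n: int
    r: float
    method: str = "pearson"
    subset: str = "all"

    def as_row(self) -> dict:
        return {
            "variable_x": self.variable_x,
            "variable_y": self.variable_y,
            "n": self.n,
            "r": self.r,
            "method": self.method,
            "subset": self.subset,
        }


#: verdict labels for class-level mean shifts
POSITIVE, NEGATIVE, NULL = "positive", "negative", "null"
SUPPORTED, NOT_SUPPORTED, INCONCLUSIVE = "supported", "not_supported", "inconclusive"


@dataclass
class SeesawSummary:
    """Class-level mean shifts in methylation and expression with verdicts.

    ``class_stats`` is indexed by (meth_class, variable) with variable in
    {'delta_gbm', 'delta_expr'} and columns mean, ci_lo, ci_hi, n, verdict.
    The three component checks mirror the seesaw hypothesis: (1) reciprocal
    class-level methylation shifts, (2) reciprocal class-level transcription
    shifts, (3) transcription moving opposite to methylation within each
    class.
    """

    class_stats: pd.DataFrame
    c1_reciprocal_gbm: str
    c2_reciprocal_expression: str
    c3_opposite_directions: str
    n_boot: int
    seed: int | None = None

    @property
    def components(self) -> dict:
        return {
            "c1_reciprocal_gbm": self.c1_reciprocal_gbm,
            "c2_reciprocal_expression": self.c2_reciprocal_expression,
            "c3_opposite_directions": self.c3_opposite_directions,
        }


def validate_count_matrix(counts: pd.DataFrame, name: str = "count matrix") -> pd.DataFrame:
    """Check a genes x samples count matrix for the type's invariants."""
    if counts.index.has_duplicates:
        raise GbmError(f"{name}: duplicate gene ids")
    if counts.columns.has_duplicates:
        raise GbmError(f"{name}: duplicate sample ids")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise GbmError(f"{name}: non-integer counts")
        counts = counts.round().astype(np.int64)
        arr = counts.to_numpy()
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise GbmError(
            f"{name}: negative count at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    return counts


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene table's invariants (unique ids, valid spans/strands)."""
    if genes.index.has_duplicates:
        dup = genes.index[genes.index.duplicated()][0]
        raise GbmError(f"duplicate gene_id {dup!r}")
    bad = genes.index[genes["start"] > genes["end"]]
    if len(bad):
        raise GbmError(f"gene {bad[0]!r}: start > end")
    if (genes["start"] < 1).any():
        raise GbmError("gene coordinates must be >= 1 (1-based inclusive)")
    bad_strand = set(genes["strand"]) - VALID_STRANDS
    if bad_strand:
        raise GbmError(f"invalid strand value(s): {sorted(bad_strand)}")
    expected = genes["end"] - genes["start"] + 1
    if "length" not in genes.columns:
        genes = genes.assign(length=expected)
    elif not (genes["length"] == expected).all():
        raise GbmError("gene length column inconsistent with start/end")
    return genes
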