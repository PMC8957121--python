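"""Gene-body and promoter methylation levels from per-CpG counts.

The gene-body methylation (GBM) level of a gene in one sample is the
percent methylation computed from read counts pooled over every CpG site
inside the gene's bounds:

    pct_meth = 100 * sum(methylated reads) / sum(all reads)

Both strands' records are pooled; symmetric-CpG collapsing is not
performed. Cells whose summed coverage falls below ``min_gene_cov`` are
treated as missing, as are genes containing no covered CpG at all. For
plotting and correlation on the log2 scale, zeros are first replaced by
the smallest non-zero value in the dataset (``log2_with_zero_rule``).

Two capture-based proxies of GBM are supported alongside WGBS:

* MBD-seq: the MBD-score, the log2 ratio of captured-fraction to
  unbound-fraction RPKM (pseudocounted), averaged over library pairs.
* mdRAD: plain RPKM of methylation-dependent restriction reads.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GbmError, MethLevelTable, validate_count_matrix, validate_gene_table

logger = logging.getLogger(__name__)


def _sum_counts_in_intervals(
    cpgs: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Sum meth/total counts over CpGs inside each 1-based inclusive interval.

    Works per contig with cumulative sums over position-sorted records, so
    overlapping intervals each receive every CpG in their own bounds.
    Returns (meth_sums, cov_sums) aligned to ``intervals``' row order.
    """
    meth_out = np.zeros(len(intervals), dtype=np.int64)
    cov_out = np.zeros(len(intervals), dtype=np.int64)
    if cpgs.empty or intervals.empty:
        return meth_out, cov_out
    seen_chroms = set()
    by_chrom = dict(tuple(cpgs.groupby("chrom", sort=False)))
    interval_chroms = intervals["chrom"].to_numpy()
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    for chrom in pd.unique(interval_chroms):
        mask = interval_chroms == chrom
        sub = by_chrom.get(chrom)
        if sub is None:
            if chrom not in seen_chroms:
                logger.warning(
                    "contig %r has gene models but no CpG records", chrom
                )
                seen_chroms.add(chrom)
            continue
        pos = sub["pos"].to_numpy()
        # cytosine reports are sorted, but do not rely on it
        if len(pos) > 1 and (np.diff(pos) < 0).any():
            order = np.argsort(pos, kind="mergesort")
            sub = sub.iloc[order]
            pos = sub["pos"].to_numpy()
        meth = sub["meth_count"].to_numpy()
        cov = meth + sub["unmeth_count"].to_numpy()
        meth_cum = np.concatenate(([0], np.cumsum(meth)))
        cov_cum = np.concatenate(([0], np.cumsum(cov)))
        lo = np.searchsorted(pos, starts[mask], side="left")
        hi = np.searchsorted(pos, ends[mask], side="right")
        meth_out[mask] = meth_cum[hi] - meth_cum[lo]
        cov_out[mask] = cov_cum[hi] - cov_cum[lo]
    return meth_out, cov_out


def gene_percent_methylation(
    cpgs: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    min_gene_cov: int = 10,
) -> MethLevelTable:
    """Pool CpG counts per gene per sample and compute percent methylation.

    Parameters
    ----------
    cpgs
        Mapping sample_id -> CpG table (see :mod:`gbmseesaw.types`).
    genes
        Gene table; promoter windows (same schema) work identically.
    min_gene_cov
        Gene x sample cells with summed coverage below this are set
        missing (0 disables the filter).

    Returns
    -------
    MethLevelTable
        With per-sample summed counts, percent methylation, and the
        per-gene mean percent over non-missing samples.
    """
    genes = validate_gene_table(genes)
    samples = list(cpgs)
    meth = pd.DataFrame(index=genes.index, columns=samples, dtype=np.int64)
    cov = pd.DataFrame(index=genes.index, columns=samples, dtype=np.int64)
    for sample_id, table in cpgs.items():
        m, c = _sum_counts_in_intervals(table, genes)
        meth[sample_id] = m
        cov[sample_id] = c
    meth = meth.astype(np.int64)
    cov = cov.astype(np.int64)
    covf = cov.to_numpy().astype(float)
    methf = meth.to_numpy().astype(float)
    eligible = covf >= max(min_gene_cov, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(eligible, 100.0 * methf / np.where(covf > 0, covf, 1), np.nan)
    pct = pd.DataFrame(pct, index=genes.index, columns=samples)
    return MethLevelTable(meth=meth, cov=cov, pct=pct)


# promoter quantification shares the interval-pooling contract exactly
def promoter_percent_methylation(
    cpgs: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    min_cov: int = 10,
) -> MethLevelTable:
    """Percent methylation over promoter windows (same rules as gene bodies)."""
    return gene_percent_methylation(cpgs, windows, min_gene_cov=min_cov)


def log2_with_zero_rule(values: pd.Series) -> pd.Series:
    """log2-transform percent values, first replacing zeros.

    Every exact zero is assigned the smallest non-zero value present in
    ``values`` (one substitution constant per dataset), then log2 is
    applied. Missing values stay missing. All-zero input is an error
    because the substitution value would be undefined.
    """
    vals = values.astype(float)
    finite = vals.dropna()
    nonzero = finite[finite > 0]
    if len(finite) and nonzero.empty:
        raise GbmError("log2_with_zero_rule: all values are zero")
    if (finite < 0).any():
        raise GbmError("log2_with_zero_rule: negative percent value")
    filled = vals.where(vals != 0, other=nonzero.min() if len(nonzero) else np.nan)
    out = np.log2(filled)
    out.name = f"log2_{values.name}" if values.name else "log2_value"
    return out


def promoter_windows(
    genes: pd.DataFrame,
    width: int = 1000,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware windows immediately upstream of each gene's 5' end.

    A ``+`` strand gene [s, e] gets [s - width, s - 1]; a ``-`` strand
    gene gets [e + 1, e + width]. Windows are clipped to [1, contig
    length] (clipping at the right edge only when ``contig_lengths`` is
    provided); genes whose window is empty after clipping are dropped
    with a warning. Window rows reuse the gene-table schema and index.
    """
    if width < 1:
        raise GbmError(f"promoter width must be >= 1, got {width}")
    genes = validate_gene_table(genes)
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["start"] - width, genes["end"] + 1)
    end = np.where(plus, genes["start"] - 1, genes["end"] + width)
    start = np.maximum(start, 1)
    if contig_lengths is not None:
        limits = genes["chrom"].map(contig_lengths)
        if limits.isna().any():
            missing = genes.loc[limits.isna(), "chrom"].iloc[0]
            raise GbmError(f"no contig length provided for {missing!r}")
        end = np.minimum(end, limits.to_numpy())
    windows = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": start,
            "end": end,
            "strand": genes["strand"],
        },
        index=genes.index,
    )
    empty = windows["start"] > windows["end"]
    if empty.any():
        logger.warning(
            "dropping %d promoter window(s) empty after clipping (e.g. %r)",
            int(empty.sum()),
            windows.index[empty][0],
        )
        windows = windows[~empty]
    windows["length"] = windows["end"] - windows["start"] + 1
    return windows


def rpkm(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase of gene length per million mapped reads.

    ``rpkm[g, s] = counts[g, s] / (length_kb(g) * libsize(s) / 1e6)``
    where libsize is the column sum of ``counts``.
    """
    counts = validate_count_matrix(counts)
    missing = counts.index.difference(genes.index)
    if len(missing):
        raise GbmError(f"no gene model for {missing[0]!r} (and {len(missing)-1} more)")
    lengths = genes.loc[counts.index, "length"].to_numpy(dtype=float)
    if (lengths < 1).any():
        raise GbmError("gene length must be >= 1 for RPKM")
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    if (libsize <= 0).any():
        bad = counts.columns[libsize <= 0][0]
        raise GbmError(f"zero library size in sample {bad!r}")
    scale = (lengths[:, None] / 1000.0) * (libsize[None, :] / 1e6)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / scale,
        index=counts.index,
        columns=counts.columns,
    )


def mbd_score(
    counts: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    genes: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.Series:
    """MBD-score: mean log2 captured/unbound RPKM ratio over library pairs.

    Parameters
    ----------
    counts
        Count matrix containing both fractions' columns.
    pairs
        (captured_sample, unbound_sample) column pairs.
    pseudocount
        Reads added to every cell before RPKM so the ratio stays finite;
        the default of one read keeps the score symmetric under swapping
        the fractions.
    """
    if not pairs:
        raise GbmError("mbd_score requires at least one captured/unbound pair")
    flat = [s for pair in pairs for s in pair]
    missing = [s for s in flat if s not in counts.columns]
    if missing:
        raise GbmError(f"MBD sample(s) missing from counts: {missing}")
    if len(flat) != len(set(flat)):
        raise GbmError("a sample appears in more than one MBD pair")
    pseudo = counts[flat] + pseudocount
    # RPKM on pseudocounted counts; library sizes recomputed after the shift
    lengths = genes.loc[counts.index, "length"].to_numpy(dtype=float)
    lib = pseudo.sum(axis=0).to_numpy(dtype=float)
    rp = pseudo.to_numpy(dtype=float) / (
        (lengths[:, None] / 1000.0) * (lib[None, :] / 1e6)
    )
    rp = pd.DataFrame(rp, index=counts.index, columns=flat)
    scores = [
        np.log2(rp[cap].to_numpy()) - np.log2(rp[unb].to_numpy())
        for cap, unb in pairs
    ]
    out = pd.Series(np.mean(scores, axis=0), index=counts.index, name="mbd_score")
    return out


def pairs_from_sample_sheet(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """Derive (captured, unbound) MBD pairs from a sample sheet's pair_id."""
    mbd = sheet[sheet["assay"] == "mbd"]
    if "pair_id" not in mbd.columns:
        raise GbmError("MBD sample sheet lacks a pair_id column")
    pairs = []
    for pair_id, grp in mbd.groupby("pair_id"):
        cap = grp.index[grp["fraction"] == "captured"]
        unb = grp.index[grp["fraction"] == "unbound"]
        if len(cap) != 1 or len(unb) != 1:
            raise GbmError(
                f"MBD pair {pair_id!r} must have exactly one captured and "
                f"one unbound sample"
            )
        pairs.append((cap[0], unb[0]))
    return pairs


def estimate_genomic_coverage(
    mean_dedup_reads: float,
    combined_pair_length: float,
    genome_length: float,
) -> float:
    """Fold genomic coverage from deduplicated read-pair counts.

    coverage = mean_dedup_reads * combined_pair_length / genome_length
    """
    if genome_length <= 0:
        raise GbmError("genome length must be positive")
    if mean_dedup_reads <= 0 or combined_pair_length <= 0:
        raise GbmError("read count and read length must be positive")
    return mean_dedup_reads * combined_pair_length / genome_length
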