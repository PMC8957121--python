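"""Readers and writers for the file dialects the pipeline touches.

Every reader validates strictly and returns the in-memory pandas schemas
documented in :mod:`gbmseesaw.types`; downstream modules never touch files.

Supported dialects
------------------
* Bismark-style cytosine reports: tab-separated
  ``chrom  pos  strand  count_methylated  count_unmethylated  context
  [trinucleotide]``, 1-based positions. Only CpG-context rows are retained.
* Gene models as GFF3 (1-based inclusive; ``ID=`` attribute) or BED6
  (0-based half-open, converted to 1-based inclusive on load).
* Gene x sample count matrices and generic result tables as TSV with a
  header row; the first column is ``gene_id``.

All output TSVs may carry ``#``-prefixed provenance comment lines, which
every reader here skips.
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    CPG_COLUMNS,
    GENE_COLUMNS,
    GbmError,
    ParseError,
    VALID_ASSAYS,
    VALID_FRACTIONS,
    VALID_STRANDS,
    validate_count_matrix,
    validate_gene_table,
)

logger = logging.getLogger(__name__)

_CPG_CONTEXTS = {"cpg", "cg"}


def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a sorted CpG table.

    Parameters
    ----------
    path
        Tab-separated file with >= 6 columns per non-empty line:
        chrom, 1-based position, strand, methylated count, unmethylated
        count, context (a 7th trinucleotide column is tolerated and
        ignored). Lines starting with ``#`` are skipped.

    Returns
    -------
    DataFrame with columns chrom, pos, strand, meth_count, unmeth_count,
    restricted to CpG-context rows ("CpG"/"CG", case-insensitive) and
    sorted by (chrom, pos).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            if context.lower() not in _CPG_CONTEXTS:
                continue
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer position or count"
                ) from None
            if pos < 1:
                raise ParseError(f"{path}: line {lineno}: position {pos} < 1")
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if strand not in VALID_STRANDS:
                raise ParseError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            rows.append((chrom, pos, strand, meth, unmeth))
    if not rows:
        logger.warning("cytosine report %s contained no CpG records", path)
        return pd.DataFrame(columns=CPG_COLUMNS).astype(
            {"pos": np.int64, "meth_count": np.int64, "unmeth_count": np.int64}
        )
    df = pd.DataFrame(rows, columns=CPG_COLUMNS)
    df = df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return df


def write_cytosine_report(cpgs: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a CpG table back out in the 7-column cytosine-report dialect."""
    out = cpgs.copy()
    out["context"] = "CpG"
    out["trinucleotide"] = "CGN"
    out.to_csv(path, sep="\t", header=False, index=False)


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for item in attr.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(
    path: str | os.PathLike,
    dialect: str = "gff3",
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Read gene models from GFF3 or BED6 into a validated gene table.

    GFF3 rows whose type column matches ``feature_type`` are kept and the
    gene id is taken from the ``ID=`` attribute. BED intervals (0-based,
    half-open) are converted to the internal 1-based inclusive convention;
    a missing BED strand column defaults to ``+`` with a warning.
    """
    if dialect not in {"gff3", "bed"}:
        raise GbmError(f"unknown gene-model dialect {dialect!r}")
    records: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise ParseError(
                        f"{path}: line {lineno}: GFF3 needs 9 columns"
                    )
                if fields[2] != feature_type:
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ParseError(
                        f"{path}: line {lineno}: {feature_type} row lacks ID="
                    )
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from None
                strand = fields[6]
            else:  # bed
                if len(fields) < 4:
                    raise ParseError(
                        f"{path}: line {lineno}: BED needs >= 4 columns"
                    )
                gene_id = fields[3]
                try:
                    start0, end0 = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from None
                start, end = start0 + 1, end0  # half-open -> 1-based inclusive
                if len(fields) >= 6 and fields[5] in VALID_STRANDS:
                    strand = fields[5]
                else:
                    logger.warning(
                        "%s: line %d: missing strand, defaulting to '+'",
                        path, lineno,
                    )
                    strand = "+"
            if strand not in VALID_STRANDS:
                raise ParseError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            if start > end:
                raise ParseError(
                    f"{path}: line {lineno}: gene {gene_id!r} has start > end"
                )
            records.append((gene_id, fields[0], start, end, strand))
    if not records:
        raise ParseError(f"{path}: no {feature_type} records found")
    df = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    df["length"] = df["end"] - df["start"] + 1
    return validate_gene_table(df)


def write_gene_models_bed(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a gene table as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for gene_id, row in genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t"
                f"{gene_id}\t0\t{row['strand']}\n"
            )


def read_count_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample TSV count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: count matrix needs gene_id plus >= 1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric count at gene {bad!r}, sample {col!r}"
            ) from None
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[vals != np.round(vals)][0]
            raise ParseError(
                f"{path}: non-integer count at gene {bad!r}, sample {col!r}"
            )
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ParseError(
                f"{path}: negative count at gene {bad!r}, sample {col!r}"
            )
        out[col] = vals.astype(np.int64)
    return validate_count_matrix(out, name=str(path))


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV indexed by sample_id.

    Required columns: sample_id, condition, assay, fraction, is_control.
    Optional: pair_id (MBD captured/unbound pairing), path (per-sample
    cytosine report location for WGBS samples).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "assay", "fraction", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    df = df.set_index("sample_id")
    bad_assay = set(df["assay"]) - VALID_ASSAYS
    if bad_assay:
        raise ParseError(f"{path}: unknown assay value(s) {sorted(bad_assay)}")
    bad_frac = set(df["fraction"]) - VALID_FRACTIONS
    if bad_frac:
        raise ParseError(f"{path}: unknown fraction value(s) {sorted(bad_frac)}")
    df["is_control"] = df["is_control"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if df["is_control"].isna().any():
        raise ParseError(f"{path}: is_control must be true/false")
    return df


def write_table(
    rows: pd.DataFrame,
    path: str | os.PathLike,
    comments: Iterable[str] = (),
    index: bool = True,
) -> None:
    """Write any tabular result as TSV with a header.

    Floats are rendered with 9 significant digits so tables round-trip
    through the matching readers to better than 1e-9 relative error; NaN
    is rendered as ``NA``. ``comments`` become ``#``-prefixed provenance
    lines above the header.
    """
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        rows.to_csv(
            fh,
            sep="\t",
            index=index,
            na_rep="NA",
            float_format="%.9g",
            quoting=csv.QUOTE_NONE,
        )


def read_table(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], index_col=index_col
    )
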