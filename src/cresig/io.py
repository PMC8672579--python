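"""Readers and writers for the on-disk formats, plus the annotation types.

Formats handled:

* BED3+ and ENCODE narrowPeak (10-column) peak files -> :class:`IntervalSet`
* two-column ``chrom.sizes`` TSV -> :class:`ChromSizes`
* TSS annotation TSV (``gene_id  symbol  chrom  strand  tss``) -> :class:`GeneModel` list
* expression TSV (``gene_id`` + one column per replicate, FPKM) -> :class:`ExpressionTable`

All coordinate columns are validated on read; malformed lines raise
:class:`ParseError` naming the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

BED_DIALECTS = ("bed3", "narrowPeak")


class ParseError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class GeneModel:
    """A TSS-anchored gene record.

    ``tss`` is a single 0-based position; strand determines which side
    of it is upstream.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: chrom must be non-empty")


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp; lengths must be positive."""

    def __init__(self, mapping: Mapping[str, int] = ()):
        super().__init__(mapping)
        for chrom, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be > 0, got {length}")


class ExpressionTable:
    """Per-gene FPKM values across replicates of one tissue.

    Wraps a DataFrame indexed by ``gene_id`` with one column per
    replicate; ``fpkm_avg`` is always the arithmetic mean across the
    replicate columns.
    """

    def __init__(self, replicates: pd.DataFrame):
        if replicates.empty:
            raise ValueError("expression table is empty")
        if replicates.index.has_duplicates:
            dups = replicates.index[replicates.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression table: {dups[:5]}")
        if (replicates < 0).any().any():
            raise ValueError("FPKM values must be >= 0")
        self.replicates = replicates.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.replicates.index)

    @property
    def fpkm_avg(self) -> pd.Series:
        return self.replicates.mean(axis=1).rename("fpkm_avg")

    def __len__(self) -> int:
        return len(self.replicates)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.replicates.index

    def to_frame(self) -> pd.DataFrame:
        out = self.replicates.copy()
        out["fpkm_avg"] = self.fpkm_avg
        return out


# -- BED -------------------------------------------------------------------


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(path: str | Path, dialect: str = "bed3") -> IntervalSet:
    """Read a BED3+ or narrowPeak file into an :class:`IntervalSet`.

    Only the first three columns are interpreted; extra columns are
    ignored.  Comment, ``track`` and ``browser`` lines are skipped.
    """
    if dialect not in BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}; expected one of {BED_DIALECTS}")
    min_cols = 10 if dialect == "narrowPeak" else 3
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for {dialect}, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates: {exc}") from None
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals)


def write_bed(path: str | Path, intervals: IntervalSet | Iterable[GenomicInterval]) -> None:
    """Write intervals as BED3, sorted by (chrom, start)."""
    if not isinstance(intervals, IntervalSet):
        intervals = IntervalSet(intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# -- tables ----------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if fields[0] in sizes:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = length
    try:
        return ChromSizes(sizes)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


TSS_COLUMNS = ("gene_id", "symbol", "chrom", "strand", "tss")


def read_tss_table(path: str | Path) -> list[GeneModel]:
    """TSS annotation TSV with header ``gene_id symbol chrom strand tss``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups[:5]}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        try:
            genes.append(
                GeneModel(
                    gene_id=row.gene_id,
                    symbol=row.symbol,
                    chrom=row.chrom,
                    strand=row.strand,
                    tss=int(row.tss),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return genes


def write_tss_table(path: str | Path, genes: Iterable[GeneModel]) -> None:
    pd.DataFrame(
        [(g.gene_id, g.symbol, g.chrom, g.strand, g.tss) for g in genes],
        columns=list(TSS_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionTable:
    """Expression TSV: ``gene_id`` column plus one numeric column per
    replicate.  A pre-computed ``fpkm_avg`` column, if present, is
    dropped and recomputed from the replicates.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing 'gene_id' column")
    df = df.set_index("gene_id")
    df = df.drop(columns=[c for c in df.columns if c == "fpkm_avg"])
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no replicate columns")
    try:
        return ExpressionTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_expression(path: str | Path, table: ExpressionTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="gene_id")
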