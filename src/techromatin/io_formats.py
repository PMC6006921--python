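"""Readers, writers and domain containers for every on-disk format the pipeline touches.

Formats
-------
* chrom.sizes           two-column whitespace-delimited text (name, length)
* TE annotation         RepeatMasker ``.out`` or a BED6+ dialect
                        (chrom start end family class strand [age])
* segmentation          BED4 dense chromHMM track, state mnemonic in column 4
* gene models           BED12, exon structure from blockStarts/blockSizes
* expression matrix     TSV, first column gene_id, header row of tissue ids

Internally every coordinate is 0-based half-open (BED convention);
RepeatMasker's 1-based inclusive coordinates are converted on read.
Strand is stored but never used by overlap computations. Files ending in
``.gz`` are read and written gzip-compressed transparently.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "SVA", "other")

#: columns of the DataFrame backing a :class:`TECatalog`
TE_COLUMNS = ["chrom", "start", "end", "family", "te_class", "strand", "age_class"]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a format or coordinate invariant."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# genome table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome names and lengths (bp), as in a ``chrom.sizes`` file."""

    lengths: Mapping[str, int]

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise ValidationError(f"non-positive length for {chrom}: {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Raise unless 0 <= start < end <= chromosome length."""
        if chrom not in self.lengths:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValidationError(
                f"interval {chrom}:{start}-{end} outside chromosome of "
                f"length {self.lengths[chrom]}"
            )


def read_chrom_sizes(path) -> GenomeTable:
    """Parse a two-column ``chrom.sizes`` table."""
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{i}: expected 2 columns, got {len(fields)}")
            chrom, raw = fields
            try:
                length = int(raw)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: length {raw!r} is not an integer") from exc
            if chrom in lengths:
                raise ValidationError(f"{path}:{i}: duplicate chromosome {chrom!r}")
            if length <= 0:
                raise ValidationError(f"{path}:{i}: non-positive length {length} for {chrom!r}")
            lengths[chrom] = length
    return GenomeTable(lengths)


def write_chrom_sizes(table: GenomeTable, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, length in table.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# TE catalog
# ---------------------------------------------------------------------------


def map_te_class(class_string: str) -> str:
    """Map a RepeatMasker class/family string onto the five major classes.

    ``"SINE/Alu"`` -> SINE, ``"LTR/ERV1"`` -> LTR, ``"Retroposon/SVA"`` -> SVA.
    Anything unrecognised maps to "other" with a logged warning.
    """
    head = class_string.split("/", 1)[0].strip()
    if "SVA" in class_string:
        return "SVA"
    if head in ("DNA", "LINE", "SINE", "LTR", "SVA"):
        return head
    logger.warning("unknown TE class string %r mapped to 'other'", class_string)
    return "other"


class TECatalog:
    """A set of annotated TE copies backed by a DataFrame.

    Columns: chrom, start, end, family, te_class, strand, age_class.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeTable | None = None):
        missing = [c for c in TE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"TE catalog missing columns {missing}")
        df = df.loc[:, TE_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValidationError("TE catalog contains empty or negative intervals")
        if (df["family"] == "").any():
            raise ValidationError("TE catalog contains empty family names")
        bad = ~df["te_class"].isin(TE_CLASSES)
        if bad.any():
            raise ValidationError(f"unknown te_class values: {sorted(df.loc[bad, 'te_class'].unique())}")
        if genome is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                genome.check_interval(chrom, int(sub["start"].min()), int(sub["end"].max()))
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def families(self) -> list[str]:
        return sorted(self.df["family"].unique())

    def with_df(self, df: pd.DataFrame) -> "TECatalog":
        return TECatalog(df, self.genome)


def read_te_annotation(
    path,
    dialect: str,
    age_map: Mapping[str, str] | None = None,
    genome: GenomeTable | None = None,
) -> TECatalog:
    """Read a TE annotation as a :class:`TECatalog`.

    ``dialect`` is ``"repeatmasker_out"`` (standard ``.out`` with three header
    lines, 1-based inclusive coordinates) or ``"bed6plus"``
    (chrom start end family class strand [age]). The age class is taken from
    the optional seventh BED column when present, else looked up by family in
    ``age_map``, else "unknown".
    """
    age_map = age_map or {}
    rows = []
    if dialect == "repeatmasker_out":
        with _open_text(path) as fh:
            for i, line in enumerate(fh, start=1):
                if i <= 3 or not line.strip():
                    continue
                f = line.split()
                if len(f) < 11:
                    raise ParseError(f"{path}:{i}: expected >=11 fields, got {len(f)}")
                try:
                    begin, end = int(f[5]), int(f[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: bad coordinates {f[5]!r}/{f[6]!r}") from exc
                strand = "-" if f[8] in ("C", "-") else "+"
                family = f[9]
                rows.append(
                    (f[4], begin - 1, end, family, map_te_class(f[10]), strand,
                     age_map.get(family, "unknown"))
                )
    elif dialect == "bed6plus":
        with _open_text(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise ParseError(f"{path}:{i}: expected >=6 columns, got {len(f)}")
                family = f[3]
                age = f[6] if len(f) > 6 and f[6] else age_map.get(family, "unknown")
                klass = f[4] if f[4] in TE_CLASSES else map_te_class(f[4])
                rows.append((f[0], int(f[1]), int(f[2]), family, klass, f[5], age))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=TE_COLUMNS)
    return TECatalog(df, genome)


def write_te_bed(catalog: TECatalog, path) -> None:
    """Write a catalog in the BED6+ dialect (7 columns, age class last)."""
    with _open_text(path, "wt") as fh:
        for row in catalog.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.family}\t"
                f"{row.te_class}\t{row.strand}\t{row.age_class}\n"
            )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationRecord:
    chrom: str
    start: int
    end: int
    state_label: str


class Segmentation:
    """A dense chromatin-state track: sorted, non-overlapping labelled segments."""

    def __init__(self, df: pd.DataFrame, genome: GenomeTable | None = None):
        df = df.loc[:, ["chrom", "start", "end", "state"]].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
            raise ValidationError("segmentation contains empty or negative intervals")
        if (df["state"] == "").any():
            raise ValidationError("segmentation contains empty state labels")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValidationError(f"overlapping segments on {chrom}")
            if genome is not None:
                genome.check_interval(chrom, int(sub["start"].iloc[0]), int(sub["end"].max()))
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[SegmentationRecord]:
        for r in self.df.itertuples(index=False):
            yield SegmentationRecord(r.chrom, int(r.start), int(r.end), r.state)

    def __getitem__(self, i: int) -> SegmentationRecord:
        r = self.df.iloc[i]
        return SegmentationRecord(r["chrom"], int(r["start"]), int(r["end"]), r["state"])


def read_segmentation(
    path,
    genome: GenomeTable | None = None,
    merge_abutting_same_state: bool = False,
) -> Segmentation:
    """Read a BED4 dense segmentation; extra BED columns are ignored.

    When ``merge_abutting_same_state`` is true, consecutive records on one
    chromosome with identical state and abutting coordinates are coalesced.
    """
    rows = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{i}: BED4 required, got {len(f)} columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    seg = Segmentation(df, genome)
    if merge_abutting_same_state and len(seg):
        d = seg.df
        same = (
            (d["chrom"].values[1:] == d["chrom"].values[:-1])
            & (d["state"].values[1:] == d["state"].values[:-1])
            & (d["start"].values[1:] == d["end"].values[:-1])
        )
        new_block = np.concatenate(([True], ~same))
        block = np.cumsum(new_block) - 1
        merged = d.groupby(block).agg(
            chrom=("chrom", "first"), start=("start", "first"),
            end=("end", "last"), state=("state", "first"),
        )
        seg = Segmentation(merged, genome)
    return seg


def write_segmentation(seg: Segmentation, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in seg.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene: interval, strand, TSS and exon blocks (absolute coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.gene_id}: bad interval {self.start}-{self.end}")
        prev_end = self.start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s < self.start or e > self.end or s >= e:
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} outside gene bounds")
            if s < prev_end:
                raise ValidationError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def gene_length(self) -> int:
        return self.end - self.start

    @property
    def exonic_bp(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))


class GeneCatalog:
    """An indexed collection of gene models."""

    def __init__(self, genes: Sequence[GeneModel], genome: GenomeTable | None = None):
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids in catalog")
        if genome is not None:
            for g in genes:
                genome.check_interval(g.chrom, g.start, g.end)
        self.genes = list(genes)
        self.genome = genome
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def read_gene_models(path, genome: GenomeTable | None = None) -> GeneCatalog:
    """Read gene models from BED12 (blockStarts/blockSizes define exons)."""
    genes = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{i}: BED12 required, got {len(f)} columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets) or len(sizes) != int(f[9]):
                raise ParseError(f"{path}:{i}: blockCount does not match block lists")
            ex_s = tuple(start + o for o in offsets)
            ex_e = tuple(start + o + s for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, start, end, strand, ex_s, ex_e))
    return GeneCatalog(genes, genome)


def write_gene_models(catalog: GeneCatalog, path) -> None:
    with _open_text(path, "wt") as fh:
        for g in catalog.genes:
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - g.start) for s in g.exon_starts)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exon_starts)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Gene x tissue matrix of mean TPM values (dense, non-negative)."""

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if df.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 tissues")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing cells")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative values")
        self.df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and tissue ids as header."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with _open_text(path, "wt") as fh:
        matrix.df.to_csv(fh, sep="\t", float_format="%.12g", lineterminator="\n")
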