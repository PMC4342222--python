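"""Pileup tables and library-level plumbing.

The atomic input of the whole analysis is a per-transcript pileup: for one
sequencing library, the number of A/C/G/T reads observed at every covered
position of every cDNA model.  Positions are 1-based transcript coordinates.
This module provides the readers/writers for that format, replicate pooling,
read-start deduplication, an importer for ``samtools mpileup`` text output,
and library-size normalization of count matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError, PileupFormatError, UsageError

BASES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ("gene_id", "pos", "A", "C", "G", "T")


@dataclass
class PileupTable:
    """Per-gene, per-position base counts for one sequencing library.

    ``data`` holds columns gene_id, pos, A, C, G, T, depth with
    ``depth == A + C + G + T`` and unique (gene_id, pos) pairs.
    """

    library_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if "depth" not in self.data.columns:
            self.data["depth"] = sum(self.data[b] for b in BASES)
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise PileupFormatError(f"pileup table missing columns {missing}")
        counts = df[list(BASES)].to_numpy()
        if (counts < 0).any() or (df["pos"].to_numpy() < 1).any():
            raise PileupFormatError("negative counts or non-positive positions")
        if not np.array_equal(counts.sum(axis=1), df["depth"].to_numpy()):
            raise PileupFormatError("depth does not equal the sum of base counts")
        dup = df.duplicated(subset=["gene_id", "pos"])
        if dup.any():
            first = df.loc[dup, ["gene_id", "pos"]].iloc[0]
            raise PileupFormatError(
                f"duplicate (gene_id, pos): ({first['gene_id']}, {first['pos']})"
            )

    def __len__(self) -> int:
        return len(self.data)


def read_pileup(path, library_id: str | None = None) -> PileupTable:
    """Read a pileup TSV (``gene_id pos A C G T``, header required).

    Malformed rows raise :class:`PileupFormatError` naming the offending line
    number (the header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != list(PILEUP_COLUMNS):
        raise PileupFormatError(
            f"{path}: expected header {list(PILEUP_COLUMNS)}, found {list(df.columns)}"
        )
    numeric = {}
    for col in ("pos", *BASES):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise PileupFormatError(f"{path}: malformed value in column {col!r} at line {line}")
        numeric[col] = vals.astype(np.int64)
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str), **numeric})
    if library_id is None:
        library_id = str(path)
    return PileupTable(library_id=library_id, data=out)


def write_pileup(table: PileupTable, path) -> None:
    """Write the canonical 6-column pileup TSV (depth is derived, not stored)."""
    table.data[list(PILEUP_COLUMNS)].to_csv(path, sep="\t", index=False)


def pool_replicates(tables: list[PileupTable], library_id: str | None = None) -> PileupTable:
    """Element-wise sum of base counts across biological replicates.

    Pooling increases sequence depth before SNP discovery; the operation is
    associative and commutative and the union of gene/position sets is kept.
    """
    if not tables:
        raise UsageError("pool_replicates requires at least one table")
    frames = [t.data[list(PILEUP_COLUMNS)] for t in tables]
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["gene_id", "pos"], as_index=False)[list(BASES)]
        .sum()
        .sort_values(["gene_id", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    if library_id is None:
        library_id = "+".join(t.library_id for t in tables)
    return PileupTable(library_id=library_id, data=pooled)


# ---------------------------------------------------------------------------
# read-level deduplication


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read: the unit read-start deduplication operates on."""

    gene_id: str
    start: int
    strand: str
    observed_bases: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.start < 1:
            raise UsageError("read start must be >= 1")
        if self.strand not in ("+", "-"):
            raise UsageError("strand must be '+' or '-'")


def dedup_by_start(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Keep at most one read per (gene_id, strand, start), first wins.

    Removing same-start reads prevents PCR duplicates from inflating SNP
    coverage.  The key is strand-aware so legitimate opposite-strand reads
    sharing a coordinate are both retained; order is stable and the operation
    is idempotent.
    """
    seen: set[tuple[str, str, int]] = set()
    kept: list[ReadRecord] = []
    for read in reads:
        key = (read.gene_id, read.strand, read.start)
        if key not in seen:
            seen.add(key)
            kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# count-matrix normalization


@dataclass
class CountMatrix:
    """Gene x library read counts with per-library size factors."""

    counts: pd.DataFrame  # genes as rows, libraries as columns
    size_factors: pd.Series | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise UsageError("size factors not computed; call normalize_to_smallest first")
        return self.counts / self.size_factors


def normalize_to_smallest(matrix: CountMatrix, method: str = "smallest") -> CountMatrix:
    """Compute size factors so normalized counts are comparable across libraries.

    ``method="smallest"`` (default) scales every library by total / smallest
    total, so the smallest library is unchanged and ``min(size_factors) == 1``.
    ``method="median-ratios"`` is the DESeq-style median-of-ratios alternative
    (size factor = median over all-positive genes of count / geometric mean).
    """
    counts = matrix.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise NormalizationError(f"zero-total libraries: {bad}")
    if method == "smallest":
        factors = totals / totals.min()
    elif method == "median-ratios":
        positive = counts[(counts > 0).all(axis=1)]
        if positive.empty:
            raise NormalizationError("median-ratios: no gene has positive counts in all libraries")
        log_geo_mean = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geo_mean, axis=0)
        factors = np.exp(ratios.median(axis=0))
    else:
        raise UsageError(f"unknown normalization method {method!r}")
    return CountMatrix(counts=counts, size_factors=factors.astype(float))


# ---------------------------------------------------------------------------
# samtools mpileup importer (optional convenience; the canonical format is the
# 6-column TSV above)

_INDEL_RE = re.compile(r"[+-](\d+)")


def _count_mpileup_bases(bases: str, ref: str) -> dict[str, int]:
    counts = dict.fromkeys(BASES, 0)
    ref = ref.upper()
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":  # start-of-read marker followed by mapping quality
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":  # indel: skip the run
            m = _INDEL_RE.match(bases, i)
            if m:
                i = m.end() + int(m.group(1))
                continue
            i += 1
            continue
        if ch in ".," and ref in counts:
            counts[ref] += 1
        elif ch.upper() in counts:
            counts[ch.upper()] += 1
        i += 1
    return counts


def read_mpileup(path, library_id: str | None = None) -> PileupTable:
    """Import samtools mpileup text output into a :class:`PileupTable`.

    Only the substitution evidence is kept: indels, read start/end markers and
    N/* symbols are skipped, matching the cDNA-alignment scope of the pipeline.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise PileupFormatError(f"{path}: short mpileup line {lineno}")
            gene, pos, ref, _depth, bases = fields[:5]
            counts = _count_mpileup_bases(bases, ref)
            rows.append({"gene_id": gene, "pos": int(pos), **counts})
    df = pd.DataFrame(rows, columns=list(PILEUP_COLUMNS))
    if library_id is None:
        library_id = str(path)
    return PileupTable(library_id=library_id, data=df)
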