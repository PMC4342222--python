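"""Parent-diagnostic SNP discovery from parental RNA-seq pileups.

A diagnostic SNP is a transcript position where one parent's reads deviate
from the cDNA reference base nearly unanimously: at least ``min_fraction``
(default 95%) of reads carry the same non-reference base at a coverage of at
least ``min_coverage`` (default 5) reads.  The stringent purity rule exists to
reject heterozygous sites of the outcrossing parent, whose two alleles appear
in roughly equal proportions.  Positions where both parents carry the *same*
SNP base, or where the reference-matched parent itself deviates from the
reference, are uninformative about parentage and are removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnnotationError, UsageError
from .pileup import BASES, PileupTable

SNP_COLUMNS = ("gene_id", "pos", "parent", "snp_base", "percent", "coverage")


def _empty_snp_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "parent": pd.Series(dtype=object),
            "snp_base": pd.Series(dtype=object),
            "percent": pd.Series(dtype=float),
            "coverage": pd.Series(dtype=np.int64),
        }
    )


def call_parental_snps(
    pileup: PileupTable,
    reference_bases: pd.DataFrame,
    parent: str,
    min_coverage: int = 5,
    min_fraction: float = 0.95,
) -> pd.DataFrame:
    """Call high-probability SNPs of one parent against the cDNA reference.

    A position is retained iff ``depth >= min_coverage`` and the most frequent
    non-reference base accounts for at least ``min_fraction`` of the depth
    (closed thresholds).  Ties between two non-reference bases at exactly
    equal counts are rejected as ambiguous.  ``reference_bases`` must provide
    a ``ref_base`` for every pileup position considered; missing annotations
    raise :class:`AnnotationError`.

    Returns a diagnostic SNP table with columns
    ``gene_id pos parent snp_base percent coverage``.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise UsageError("min_fraction must lie in (0, 1]")
    if min_coverage < 1:
        raise UsageError("min_coverage must be >= 1")
    df = pileup.data.merge(
        reference_bases[["gene_id", "pos", "ref_base"]], on=["gene_id", "pos"], how="left"
    )
    missing = df["ref_base"].isna()
    if missing.any():
        examples = df.loc[missing, ["gene_id", "pos"]].head(5).to_records(index=False)
        raise AnnotationError(
            f"{int(missing.sum())} pileup positions lack a reference base, e.g. {list(examples)}"
        )
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    ref_idx = pd.Categorical(df["ref_base"], categories=list(BASES)).codes
    nonref = counts.copy()
    nonref[np.arange(len(df)), ref_idx] = -1  # mask the reference base out
    order = np.argsort(nonref, axis=1)
    best_idx = order[:, -1]
    best = nonref[np.arange(len(df)), best_idx]
    second = nonref[np.arange(len(df)), order[:, -2]]
    depth = df["depth"].to_numpy(dtype=np.int64)
    keep = (
        (depth >= min_coverage)
        & (best > 0)
        & (best > second)  # reject exact non-reference ties
        & (best >= min_fraction * depth)
    )
    out = pd.DataFrame(
        {
            "gene_id": df.loc[keep, "gene_id"].to_numpy(),
            "pos": df.loc[keep, "pos"].to_numpy(),
            "parent": parent,
            "snp_base": np.asarray(list(BASES), dtype=object)[best_idx[keep]],
            "percent": 100.0 * best[keep] / depth[keep],
            "coverage": depth[keep],
        }
    )
    return out.reset_index(drop=True) if len(out) else _empty_snp_table()


def subtract_shared(
    snps_parent1: pd.DataFrame, snps_parent2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove positions carrying the same SNP base in both parents' tables.

    Positions shared by coordinate but with *different* SNP bases remain
    informative and are kept in both tables.
    """
    key1 = set(zip(snps_parent1["gene_id"], snps_parent1["pos"], snps_parent1["snp_base"]))
    key2 = set(zip(snps_parent2["gene_id"], snps_parent2["pos"], snps_parent2["snp_base"]))
    shared = key1 & key2

    def _drop(table: pd.DataFrame) -> pd.DataFrame:
        if not shared or table.empty:
            return table.reset_index(drop=True)
        mask = [
            (g, p, b) in shared
            for g, p, b in zip(table["gene_id"], table["pos"], table["snp_base"])
        ]
        return table.loc[~np.asarray(mask)].reset_index(drop=True)

    return _drop(snps_parent1), _drop(snps_parent2)


def remove_reference_parent_snps(
    diagnostic: pd.DataFrame, reference_parent_snps: pd.DataFrame
) -> pd.DataFrame:
    """Drop diagnostic positions where the reference-matched parent deviates
    from the reference (its reads there cannot be assigned by the reference
    base)."""
    if reference_parent_snps.empty or diagnostic.empty:
        return diagnostic.reset_index(drop=True)
    blocked = set(zip(reference_parent_snps["gene_id"], reference_parent_snps["pos"]))
    mask = [(g, p) in blocked for g, p in zip(diagnostic["gene_id"], diagnostic["pos"])]
    return diagnostic.loc[~np.asarray(mask)].reset_index(drop=True)


def summarize_genes(snps: pd.DataFrame) -> pd.DataFrame:
    """Per-gene SNP summary: count, mean percent SNP and mean coverage.

    The mean percent SNP is the sum of per-position percentages divided by the
    number of SNP positions; mean coverage the analogous mean of per-position
    read counts.  Genes without any SNP do not appear.
    """
    if snps.empty:
        return pd.DataFrame(
            {
                "gene_id": pd.Series(dtype=object),
                "n_snps": pd.Series(dtype=np.int64),
                "mean_percent_snp": pd.Series(dtype=float),
                "mean_coverage": pd.Series(dtype=float),
            }
        )
    grouped = snps.groupby("gene_id", sort=True)
    out = pd.DataFrame(
        {
            "n_snps": grouped.size(),
            "mean_percent_snp": grouped["percent"].mean(),
            "mean_coverage": grouped["coverage"].mean(),
        }
    ).reset_index()
    return out


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps[list(SNP_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "parent": str, "snp_base": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: SNP table missing columns {missing}")
    return df
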