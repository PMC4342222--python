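"""Allelic quantification of hybrid transcriptomes at diagnostic SNPs.

Hybrid reads at a parent-diagnostic position are assigned to the diagnostic
parent if they carry that parent's SNP base, and to the other parental lineage
if they carry the reference base; reads with any third base are excluded from
both counts and from the informative depth.  Per gene, the paternal allelic
fraction P_p is the unweighted mean over informative positions of the
per-position paternal percentage, C is the mean informative depth, and the
approximate parental read counts are

    N_m = C * P_m / 100        N_p = C * P_p / 100

with P_m = 100 - P_p.  Before ratio tests a pseudocount of one read per
parental class keeps every cell positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, UsageError
from .pileup import BASES, PileupTable

PROFILE_COLUMNS = ("gene_id", "cross_id", "n_positions", "P_m", "P_p", "C", "N_m", "N_p")


@dataclass(frozen=True)
class AllelicProfile:
    """Per-gene maternal/paternal allelic fractions and estimated read counts."""

    gene_id: str
    cross_id: str
    n_positions: int
    P_m: float  # maternal allelic fraction, %
    P_p: float  # paternal allelic fraction, %
    C: float  # mean informative coverage, reads
    N_m: float
    N_p: float


def genotype_positions(
    hybrid: PileupTable,
    diagnostic: pd.DataFrame,
    reference_bases: pd.DataFrame,
    min_coverage: int = 5,
    diagnostic_parent: str | None = None,
) -> pd.DataFrame:
    """Count maternal/paternal reads at every informative diagnostic position.

    ``diagnostic`` is a post-subtraction diagnostic SNP table whose ``parent``
    column names the parent the SNP base belongs to (``diagnostic_parent``
    overrides it).  Diagnostic positions absent from the hybrid pileup are
    silently uninformative; a diagnostic SNP base equal to the reference base
    raises :class:`IntegrityError`.  Positions with informative depth below
    ``min_coverage`` are dropped.

    Returns columns ``gene_id pos maternal_count paternal_count
    informative_depth``.
    """
    if diagnostic.empty:
        return pd.DataFrame(
            {
                "gene_id": pd.Series(dtype=object),
                "pos": pd.Series(dtype=np.int64),
                "maternal_count": pd.Series(dtype=np.int64),
                "paternal_count": pd.Series(dtype=np.int64),
                "informative_depth": pd.Series(dtype=np.int64),
            }
        )
    diag = diagnostic.copy()
    if diagnostic_parent is not None:
        diag["parent"] = diagnostic_parent
    bad_parent = ~diag["parent"].isin(["maternal", "paternal"])
    if bad_parent.any():
        raise UsageError("diagnostic parent must be 'maternal' or 'paternal'")
    df = diag.merge(
        reference_bases[["gene_id", "pos", "ref_base"]], on=["gene_id", "pos"], how="left"
    )
    if df["ref_base"].isna().any():
        raise IntegrityError("diagnostic positions missing from the reference base map")
    if (df["snp_base"] == df["ref_base"]).any():
        raise IntegrityError("diagnostic SNP base equals the reference base")
    df = df.merge(hybrid.data, on=["gene_id", "pos"], how="inner")
    if df.empty:
        return genotype_positions(hybrid, diagnostic.iloc[:0], reference_bases)
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    idx = np.arange(len(df))
    snp_idx = pd.Categorical(df["snp_base"], categories=list(BASES)).codes
    ref_idx = pd.Categorical(df["ref_base"], categories=list(BASES)).codes
    snp_count = counts[idx, snp_idx]
    ref_count = counts[idx, ref_idx]
    informative = snp_count + ref_count
    is_paternal_snp = (df["parent"] == "paternal").to_numpy()
    paternal = np.where(is_paternal_snp, snp_count, ref_count)
    maternal = np.where(is_paternal_snp, ref_count, snp_count)
    keep = informative >= min_coverage
    out = pd.DataFrame(
        {
            "gene_id": df.loc[keep, "gene_id"].to_numpy(),
            "pos": df.loc[keep, "pos"].to_numpy(),
            "maternal_count": maternal[keep],
            "paternal_count": paternal[keep],
            "informative_depth": informative[keep],
        }
    )
    return out.sort_values(["gene_id", "pos"], kind="mergesort").reset_index(drop=True)


def _profiles_from_positions(positions: pd.DataFrame, cross_id: str, weighted: bool) -> pd.DataFrame:
    pos = positions.copy()
    pos["pat_pct"] = 100.0 * pos["paternal_count"] / pos["informative_depth"]
    grouped = pos.groupby("gene_id", sort=True)
    if weighted:
        P_p = 100.0 * grouped["paternal_count"].sum() / grouped["informative_depth"].sum()
    else:
        P_p = grouped["pat_pct"].mean()
    C = grouped["informative_depth"].mean()
    out = pd.DataFrame(
        {
            "cross_id": cross_id,
            "n_positions": grouped.size(),
            "P_p": P_p,
            "C": C,
        }
    )
    out["P_m"] = 100.0 - out["P_p"]
    out["N_m"] = out["C"] * out["P_m"] / 100.0
    out["N_p"] = out["C"] * out["P_p"] / 100.0
    return out.reset_index()[list(PROFILE_COLUMNS)]


def profile_genes(positions: pd.DataFrame, cross_id: str, weighted: bool = False) -> pd.DataFrame:
    """Aggregate per-position counts into per-gene allelic profiles.

    Default aggregation is the unweighted mean of per-position fractions (the
    "mean percent SNP" convention); ``weighted=True`` pools reads across
    positions instead, for sensitivity analysis.  Genes with zero informative
    positions are simply absent.
    """
    if positions.empty:
        return pd.DataFrame(columns=list(PROFILE_COLUMNS))
    return _profiles_from_positions(positions, cross_id, weighted)


def profile_gene(positions: pd.DataFrame, gene_id: str, cross_id: str) -> AllelicProfile:
    """Profile a single gene; raises :class:`UsageError` without informative positions."""
    sub = positions[positions["gene_id"] == gene_id]
    if sub.empty:
        raise UsageError(f"no informative positions for gene {gene_id!r}")
    row = _profiles_from_positions(sub, cross_id, weighted=False).iloc[0]
    return AllelicProfile(
        gene_id=gene_id,
        cross_id=cross_id,
        n_positions=int(row["n_positions"]),
        P_m=float(row["P_m"]),
        P_p=float(row["P_p"]),
        C=float(row["C"]),
        N_m=float(row["N_m"]),
        N_p=float(row["N_p"]),
    )


def apply_pseudocounts(N_m, N_p, mode: str = "per-allele"):
    """Test-ready counts with pseudocounts.

    ``per-allele`` (default) adds one read to each parental count, which is
    symmetric and guarantees positive cells in the chi-square.  ``coverage``
    is the literal reading — one read added to the coverage, split according
    to the observed fractions — which does *not* remove zero cells and is
    provided for comparison only.
    """
    N_m = np.asarray(N_m, dtype=float)
    N_p = np.asarray(N_p, dtype=float)
    if mode == "per-allele":
        n_m, n_p = N_m + 1.0, N_p + 1.0
    elif mode == "coverage":
        C = N_m + N_p
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(C > 0, N_m / C, 0.5)
        n_m, n_p = (C + 1.0) * share, (C + 1.0) * (1.0 - share)
    else:
        raise UsageError(f"unknown pseudocount mode {mode!r}")
    if n_m.ndim == 0:
        return float(n_m), float(n_p)
    return n_m, n_p


def estimate_mapping_bias(profiles: pd.DataFrame, reference_parent: str = "maternal") -> float:
    """Mean reference-parent allelic fraction across genes of a known 50:50 mix.

    A QC diagnostic (not a correction): on an even mix the value estimates the
    observed reference fraction the mapping-bias model would produce.
    Requires at least 10 genes.
    """
    if len(profiles) < 10:
        raise UsageError("estimate_mapping_bias requires profiles for at least 10 genes")
    col = "P_m" if reference_parent == "maternal" else "P_p"
    if reference_parent not in ("maternal", "paternal"):
        raise UsageError("reference_parent must be 'maternal' or 'paternal'")
    return float(profiles[col].mean() / 100.0)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles[list(PROFILE_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cross_id": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: profile table missing columns {missing}")
    return df
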