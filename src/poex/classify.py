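"""MEG/PEG classification, cross comparisons and bias-distribution analyses.

A gene is called maternal (MEG) when its maternal allelic fraction exceeds
66% — the point above which expression is more maternal than the 2m:1p
endosperm genome dose explains — and the goodness-of-fit chi-square against
the 2:1 null is significant after Benjamini-Hochberg correction.  It is
called paternal (PEG) when the paternal fraction exceeds 50% with a
significant departure from the 1:1 null.  Everything else is biparental.
Both within-cross goodness-of-fit tests and the 2x2 between-cross chi-square
are exposed so either gating convention is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import LowCoverageError, UsageError
from .quantify import apply_pseudocounts

CLASSES = ("maternal", "biparental", "paternal")
CALL_COLUMNS = ("gene_id", "cross_id", "class", "P_m", "P_p", "C", "chi2", "p", "padj")


# ---------------------------------------------------------------------------
# chi-square kernels


def chisq_goodness_of_fit(n_m, n_p, null_maternal_share: float):
    """Pearson goodness-of-fit of (n_m, n_p) against an expected maternal share.

    One degree of freedom; counts must be positive (apply pseudocounts first).
    Accepts scalars or arrays.
    """
    s = float(null_maternal_share)
    if not 0.0 < s < 1.0:
        raise UsageError("null_maternal_share must lie in (0, 1)")
    n_m = np.asarray(n_m, dtype=float)
    n_p = np.asarray(n_p, dtype=float)
    T = n_m + n_p
    if np.any(T <= 0):
        raise UsageError("total count must be positive")
    e_m, e_p = T * s, T * (1.0 - s)
    chi2 = (n_m - e_m) ** 2 / e_m + (n_p - e_p) ** 2 / e_p
    p = stats.chi2.sf(chi2, df=1)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def chisq_between_crosses(n_m_a, n_p_a, n_m_b, n_p_b):
    """Pearson 2x2 chi-square (rows = crosses, columns = maternal/paternal).

    No continuity correction, one degree of freedom.  Accepts scalars or
    arrays (vectorised over genes).
    """
    a, b = np.asarray(n_m_a, float), np.asarray(n_p_a, float)
    c, d = np.asarray(n_m_b, float), np.asarray(n_p_b, float)
    N = a + b + c + d
    if np.any(N <= 0):
        raise UsageError("2x2 table total must be positive")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if np.any(row1 <= 0) or np.any(row2 <= 0) or np.any(col1 <= 0) or np.any(col2 <= 0):
        raise UsageError("2x2 margins must be positive (apply pseudocounts)")
    chi2 = N * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = stats.chi2.sf(chi2, df=1)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification


def classify_genes(
    profiles: pd.DataFrame,
    meg_threshold: float = 66.0,
    peg_threshold: float = 50.0,
    alpha: float = 0.05,
    meg_null_maternal_share: float = 2.0 / 3.0,
    peg_null_maternal_share: float = 0.5,
    pseudocount_mode: str = "per-allele",
) -> pd.DataFrame:
    """Classify every profiled gene as maternal / biparental / paternal.

    The significance gate is the within-cross goodness-of-fit against the
    class's own null ratio (2:1 for the maternal call, 1:1 for the paternal
    call), BH-adjusted over all profiled genes per family.  Thresholds are
    strict (P_m must *exceed* ``meg_threshold``).  The output carries both
    test families plus canonical ``chi2/p/padj`` columns taken from the test
    that gated (or would gate) the call.
    """
    if profiles.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    n_m, n_p = apply_pseudocounts(
        profiles["N_m"].to_numpy(), profiles["N_p"].to_numpy(), mode=pseudocount_mode
    )
    chi2_meg, p_meg = chisq_goodness_of_fit(n_m, n_p, meg_null_maternal_share)
    chi2_peg, p_peg = chisq_goodness_of_fit(n_m, n_p, peg_null_maternal_share)
    chi2_meg, p_meg = np.atleast_1d(chi2_meg), np.atleast_1d(p_meg)
    chi2_peg, p_peg = np.atleast_1d(chi2_peg), np.atleast_1d(p_peg)
    padj_meg = bh_adjust(p_meg)
    padj_peg = bh_adjust(p_peg)

    P_m = profiles["P_m"].to_numpy(dtype=float)
    P_p = profiles["P_p"].to_numpy(dtype=float)
    maternal = (P_m > meg_threshold) & (padj_meg < alpha)
    paternal = (P_p > peg_threshold) & (padj_peg < alpha) & ~maternal
    cls = np.where(maternal, "maternal", np.where(paternal, "paternal", "biparental"))

    use_meg = P_m > meg_threshold
    calls = pd.DataFrame(
        {
            "gene_id": profiles["gene_id"].to_numpy(),
            "cross_id": profiles["cross_id"].to_numpy(),
            "class": cls,
            "P_m": P_m,
            "P_p": P_p,
            "C": profiles["C"].to_numpy(dtype=float),
            "chi2": np.where(use_meg, chi2_meg, chi2_peg),
            "p": np.where(use_meg, p_meg, p_peg),
            "padj": np.where(use_meg, padj_meg, padj_peg),
            "chi2_meg": chi2_meg,
            "p_meg": p_meg,
            "padj_meg": padj_meg,
            "chi2_peg": chi2_peg,
            "p_peg": p_peg,
            "padj_peg": padj_peg,
        }
    )
    return calls


def summarize_cross(calls: pd.DataFrame) -> pd.DataFrame:
    """Class counts and shares per cross (the headline summary table layout)."""
    if calls.empty:
        return pd.DataFrame(columns=["cross_id", "class", "n_genes", "percent"])
    rows = []
    for cross_id, sub in calls.groupby("cross_id", sort=True):
        total = len(sub)
        for cls in CLASSES:
            n = int((sub["class"] == cls).sum())
            rows.append(
                {
                    "cross_id": cross_id,
                    "class": cls,
                    "n_genes": n,
                    "percent": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows)


def common_gene_filter(profiles_by_cross: dict, min_mean_reads: float = 5.0) -> set[str]:
    """Genes whose mean coverage is at least ``min_mean_reads`` in every cross."""
    if len(profiles_by_cross) < 2:
        raise UsageError("common_gene_filter requires at least two crosses")
    common: set[str] | None = None
    for profiles in profiles_by_cross.values():
        kept = set(profiles.loc[profiles["C"] >= min_mean_reads, "gene_id"])
        common = kept if common is None else common & kept
    return common or set()


# ---------------------------------------------------------------------------
# distribution comparisons across crosses


def compare_bias_distributions(fractions_a, fractions_b):
    """Paired Wilcoxon signed-rank test of per-gene paternal fractions.

    Zero-difference pairs are dropped (signed-rank convention); if every pair
    is tied the p-value is reported as 1 with a warning.  Returns
    ``(statistic, p, mean_a, mean_b)``.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.shape != b.shape or a.size < 10:
        raise UsageError("compare_bias_distributions requires >= 10 paired values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if np.all(a == b):
        warnings.warn("all paired differences are zero; p reported as 1", stacklevel=2)
        return 0.0, 1.0, mean_a, mean_b
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue), mean_a, mean_b


def bias_correlation(fractions_a, fractions_b):
    """OLS simple regression of cross B's paternal fractions on cross A's.

    Returns ``(r_squared, slope, p)`` where p is the slope p-value.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise UsageError("bias_correlation requires >= 3 paired values")
    if np.ptp(a) == 0:
        raise UsageError("zero variance in the predictor; fit undefined")
    res = stats.linregress(a, b)
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# literature annotation and set comparisons

HYBRID_STATUSES = ("confirmed", "reverted_to_maternal", "de_novo_PEG", "not_informative")


def annotate_with_literature(
    hybrid_calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    literature: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate hybrid-cross calls against known imprinted genes.

    Rules: a literature PEG that is paternal in the hybrid is ``confirmed``; a
    literature PEG that is maternal in the hybrid is ``reverted_to_maternal``;
    a paternal hybrid call with no literature status (and not paternal in the
    control cross) is a ``de_novo_PEG``; genes without SNP coverage in the
    hybrid are ``not_informative``.  ``literature`` needs columns ``gene_id``
    and ``status`` (known_PEG / known_MEG / none); duplicates are rejected.
    """
    if literature["gene_id"].duplicated().any():
        dupes = literature.loc[literature["gene_id"].duplicated(), "gene_id"].tolist()
        raise UsageError(f"duplicate literature entries: {dupes[:5]}")
    valid = {"known_PEG", "known_MEG", "none"}
    bad = set(literature["status"].unique()) - valid
    if bad:
        raise UsageError(f"unknown literature statuses: {sorted(bad)}")

    hybrid_class = hybrid_calls.set_index("gene_id")["class"]
    control_class = control_calls.set_index("gene_id")["class"] if len(control_calls) else pd.Series(dtype=object)
    genes = sorted(set(literature["gene_id"]) | set(hybrid_class.index))
    lit_status = literature.set_index("gene_id")["status"]

    rows = []
    for gene in genes:
        lit = lit_status.get(gene, "none")
        hyb = hybrid_class.get(gene)
        ctrl = control_class.get(gene)
        if hyb is None:
            status = "not_informative"
        elif lit == "known_PEG" and hyb == "paternal":
            status = "confirmed"
        elif lit == "known_PEG" and hyb == "maternal":
            status = "reverted_to_maternal"
        elif lit == "none" and hyb == "paternal" and ctrl != "paternal":
            status = "de_novo_PEG"
        else:
            status = "not_informative"
        rows.append(
            {
                "gene_id": gene,
                "literature_status": lit,
                "hybrid_class": hyb if hyb is not None else "no_coverage",
                "control_class": ctrl if ctrl is not None else "no_coverage",
                "hybrid_status": status,
            }
        )
    return pd.DataFrame(rows)


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def downsampled_chisq(profile_a, profile_b):
    """2x2 chi-square after rescaling both profiles to the lower coverage.

    Each profile's (N_m, N_p) is rescaled deterministically (half-up rounding,
    totals preserved exactly) so both sum to ``min(C_a, C_b)``; the 2x2 test
    then compares allelic composition free of the coverage imbalance.
    Profiles may be :class:`~poex.quantify.AllelicProfile` objects or mappings
    with ``N_m``/``N_p``/``C``.
    """

    def _counts(p):
        if hasattr(p, "N_m"):
            return float(p.N_m), float(p.N_p), float(p.C)
        return float(p["N_m"]), float(p["N_p"]), float(p["C"])

    nm_a, np_a, c_a = _counts(profile_a)
    nm_b, np_b, c_b = _counts(profile_b)
    if c_a <= 0 or c_b <= 0:
        raise UsageError("both coverages must be positive")
    target = min(c_a, c_b)
    if target < 5:
        raise LowCoverageError(f"minimum coverage {target} < 5; refusing downsampled test")

    def _rescale(nm, c):
        m = _round_half_up(nm * target / c)
        return float(m), float(_round_half_up(target) - m)

    a_m, a_p = _rescale(nm_a, c_a)
    b_m, b_p = _rescale(nm_b, c_b)
    return chisq_between_crosses(a_m, a_p, b_m, b_p)


@dataclass
class CallSetComparison:
    shared: dict
    unique_a: dict
    unique_b: dict

    def counts(self) -> pd.DataFrame:
        rows = []
        for cls in ("maternal", "paternal"):
            rows.append(
                {
                    "class": cls,
                    "shared": len(self.shared[cls]),
                    "unique_a": len(self.unique_a[cls]),
                    "unique_b": len(self.unique_b[cls]),
                }
            )
        return pd.DataFrame(rows)


def compare_call_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> CallSetComparison:
    """Venn-style overlap of MEG and PEG gene sets between two call tables."""
    shared, unique_a, unique_b = {}, {}, {}
    for cls in ("maternal", "paternal"):
        set_a = set(calls_a.loc[calls_a["class"] == cls, "gene_id"]) if len(calls_a) else set()
        set_b = set(calls_b.loc[calls_b["class"] == cls, "gene_id"]) if len(calls_b) else set()
        shared[cls] = sorted(set_a & set_b)
        unique_a[cls] = sorted(set_a - set_b)
        unique_b[cls] = sorted(set_b - set_a)
    return CallSetComparison(shared=shared, unique_a=unique_a, unique_b=unique_b)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
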