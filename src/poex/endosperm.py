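"""Endosperm-specificity scoring from a seed-compartment expression matrix.

For each gene, take the maximum expression over endosperm compartments and
the maximum over non-endosperm compartments (seed coat, suspensor, embryo) at
the preglobular/globular stages, and score

    log_ratio = log10((max_endo - floor) / (max_nonendo - floor))

where ``floor`` (default 2.3) is the expression level that can be taken as
zero on the source scale; each parenthesised term is clamped below at a small
epsilon so genes sitting on the floor yield finite, capped scores.  Low
expressors are removed by ``log_sum = log10(max_endo + max_nonendo) >= 1.8``,
and endosperm-specific genes are the upper Tukey outliers of the remaining
log-ratio distribution (above Q3 + 1.5 IQR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

SCORE_COLUMNS = (
    "gene_id",
    "max_endo",
    "max_nonendo",
    "log_ratio",
    "log_sum",
    "passed_expression_filter",
    "is_endosperm_specific",
)


@dataclass
class TissueExpressionMatrix:
    """Gene x seed-compartment expression values on the source (linear) scale.

    ``compartment_map`` tags every column ``endosperm`` or ``non_endosperm``;
    values must sit at or above ``floor``.
    """

    values: pd.DataFrame
    compartment_map: dict
    floor: float = 2.3

    def __post_init__(self):
        tags = set(self.compartment_map.values())
        if not tags <= {"endosperm", "non_endosperm"}:
            raise UsageError(f"compartment tags must be endosperm/non_endosperm, got {sorted(tags)}")
        missing = [c for c in self.values.columns if c not in self.compartment_map]
        if missing:
            raise UsageError(f"columns without a compartment tag: {missing}")
        if "endosperm" not in tags or "non_endosperm" not in tags:
            raise UsageError("need at least one endosperm and one non-endosperm compartment")
        if (self.values.to_numpy() < self.floor - 1e-12).any():
            raise DataError(f"expression values below the floor {self.floor}")

    def columns_tagged(self, tag: str) -> list[str]:
        return [c for c in self.values.columns if self.compartment_map[c] == tag]


def endosperm_score(
    matrix: TissueExpressionMatrix, epsilon: float = 0.01, log_base: float = 10.0
) -> pd.DataFrame:
    """Per-gene maxima, floored log-ratio and log-sum (no filtering applied)."""
    if epsilon <= 0:
        raise UsageError("epsilon must be positive")
    endo_cols = matrix.columns_tagged("endosperm")
    non_cols = matrix.columns_tagged("non_endosperm")
    max_endo = matrix.values[endo_cols].max(axis=1)
    max_nonendo = matrix.values[non_cols].max(axis=1)
    num = np.maximum(max_endo - matrix.floor, epsilon)
    den = np.maximum(max_nonendo - matrix.floor, epsilon)
    log = np.log(log_base)
    scores = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "max_endo": max_endo.to_numpy(),
            "max_nonendo": max_nonendo.to_numpy(),
            "log_ratio": (np.log(num) - np.log(den)).to_numpy() / log,
            "log_sum": np.log((max_endo + max_nonendo).to_numpy()) / log,
        }
    )
    return scores.reset_index(drop=True)


def expression_filter(scores: pd.DataFrame, min_log_sum: float = 1.8) -> pd.DataFrame:
    """Flag well-expressed genes (``log_sum >= min_log_sum``).

    Genes failing the filter stay in the table with
    ``passed_expression_filter = False`` but are excluded from outlier
    analysis downstream.
    """
    out = scores.copy()
    out["passed_expression_filter"] = out["log_sum"] >= min_log_sum
    return out


def tukey_outliers(values, method: str = "linear") -> np.ndarray:
    """Upper Tukey-fence outlier flags: ``v > Q3 + 1.5 * (Q3 - Q1)``.

    Quartiles use linear interpolation between order statistics by default;
    ``method="hinges"`` uses Tukey hinges (medians of the halves) instead.
    Requires at least 4 values; flags are invariant to input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise UsageError("tukey_outliers requires at least 4 values")
    if method == "linear":
        q1, q3 = np.percentile(v, [25, 75])
    elif method == "hinges":
        s = np.sort(v)
        n = s.size
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half :]))
    else:
        raise UsageError(f"unknown quartile method {method!r}")
    fence = q3 + 1.5 * (q3 - q1)
    return v > fence


def endosperm_specific_set(
    matrix: TissueExpressionMatrix,
    min_log_sum: float = 1.8,
    epsilon: float = 0.01,
    quartile_method: str = "linear",
) -> tuple[set[str], pd.DataFrame]:
    """Score -> expression filter -> Tukey outliers on the log ratio.

    Returns the endosperm-specific gene set together with the full score table
    (flags included for every gene).
    """
    scores = expression_filter(endosperm_score(matrix, epsilon=epsilon), min_log_sum=min_log_sum)
    scores["is_endosperm_specific"] = False
    passed = scores["passed_expression_filter"].to_numpy()
    if passed.sum() >= 4:
        flags = tukey_outliers(scores.loc[passed, "log_ratio"].to_numpy(), method=quartile_method)
        scores.loc[passed, "is_endosperm_specific"] = flags
    specific = set(scores.loc[scores["is_endosperm_specific"], "gene_id"])
    return specific, scores[list(SCORE_COLUMNS)]


def read_tissue_matrix(matrix_path, compartment_map: dict, floor: float = 2.3) -> TissueExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return TissueExpressionMatrix(values=values, compartment_map=compartment_map, floor=floor)


def write_tissue_matrix(matrix: TissueExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g")
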