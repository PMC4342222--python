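"""Classification statistics: chi-square kernels, BH, calls, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poex.classify import (
    annotate_with_literature,
    bh_adjust,
    bias_correlation,
    chisq_between_crosses,
    chisq_goodness_of_fit,
    classify_genes,
    common_gene_filter,
    compare_bias_distributions,
    compare_call_sets,
    downsampled_chisq,
    summarize_cross,
)
from poex.errors import LowCoverageError, UsageError


def _profiles(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "P_p", "C"])
    df["cross_id"] = "c"
    df["n_positions"] = 1
    df["P_m"] = 100.0 - df["P_p"]
    df["N_m"] = df["C"] * df["P_m"] / 100.0
    df["N_p"] = df["C"] * df["P_p"] / 100.0
    return df


class TestGoodnessOfFit:
    def test_hand_computed_example(self):
        chi2, p = chisq_goodness_of_fit(35, 1, 0.5)
        assert chi2 == pytest.approx(32.111, abs=1e-3)
        assert p == pytest.approx(1.46e-8, rel=0.02)

    def test_exact_null_fit(self):
        chi2, p = chisq_goodness_of_fit(20, 10, 2 / 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_symmetric_counts_at_even_null(self):
        chi2, _ = chisq_goodness_of_fit(17.3, 17.3, 0.5)
        assert chi2 == 0.0

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(300):
            n_m, n_p = rng.integers(1, 500, 2)
            s = rng.uniform(0.05, 0.95)
            chi2, p = chisq_goodness_of_fit(n_m, n_p, s)
            T = n_m + n_p
            oracle = stats.chisquare([n_m, n_p], f_exp=[T * s, T * (1 - s)])
            assert chi2 == pytest.approx(oracle.statistic, abs=1e-9)
            assert p == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(UsageError):
            chisq_goodness_of_fit(0, 0, 0.5)
        with pytest.raises(UsageError):
            chisq_goodness_of_fit(1, 1, 1.0)


class TestBetweenCrosses:
    def test_identical_profiles_null(self):
        chi2, p = chisq_between_crosses(50, 50, 50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_frozen_oracle_example(self):
        # (90,10) vs (50,50), Pearson without continuity correction
        chi2, p = chisq_between_crosses(90, 10, 50, 50)
        oracle = stats.chi2_contingency([[90, 10], [50, 50]], correction=False)
        assert chi2 == pytest.approx(38.095, abs=1e-3)
        assert chi2 == pytest.approx(oracle.statistic, abs=1e-9)
        assert p == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_row_swap_symmetry(self):
        a = chisq_between_crosses(30, 70, 70, 30)
        b = chisq_between_crosses(70, 30, 30, 70)
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(300):
            table = rng.integers(1, 200, 4)
            chi2, p = chisq_between_crosses(*table)
            oracle = stats.chi2_contingency(table.reshape(2, 2), correction=False)
            assert chi2 == pytest.approx(oracle.statistic, abs=1e-9)
            assert p == pytest.approx(oracle.pvalue, abs=1e-9)


def _bh_textbook(p):
    """Step-up BH from the definition, as an independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBhAdjust:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_pvalue(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_pointwise_at_least_input(self, rng):
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_matches_textbook_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 100))
            assert bh_adjust(p) == pytest.approx(_bh_textbook(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            bh_adjust([0.5, 1.5])


class TestClassifyGenes:
    def test_published_style_worked_examples(self):
        """P_p=95.6 at C=407 -> paternal; P_p=54.2 at C=128 -> biparental."""
        calls = classify_genes(_profiles([("pheres1_like", 95.6, 407.0), ("hdg3_like", 54.2, 128.0)]))
        by_gene = calls.set_index("gene_id")["class"]
        assert by_gene["pheres1_like"] == "paternal"
        assert by_gene["hdg3_like"] == "biparental"

    def test_meg_threshold_is_strict(self):
        calls = classify_genes(_profiles([("g1", 34.0, 10000.0)]))  # P_m = 66.0 exactly
        assert calls.iloc[0]["class"] == "biparental"

    def test_every_gene_gets_one_class(self, rng):
        rows = [(f"g{i}", float(rng.uniform(0, 100)), float(rng.uniform(5, 300))) for i in range(150)]
        calls = classify_genes(_profiles(rows))
        assert len(calls) == 150
        assert calls["class"].isin(["maternal", "biparental", "paternal"]).all()

    def test_padj_never_below_p(self):
        calls = classify_genes(_profiles([(f"g{i}", 50.0 + i, 100.0) for i in range(30)]))
        assert (calls["padj"] >= calls["p"] - 1e-15).all()


class TestSummaries:
    def test_share_counting(self):
        calls = pd.DataFrame(
            {
                "cross_id": "c",
                "gene_id": list("abcd"),
                "class": ["maternal", "maternal", "paternal", "biparental"],
            }
        )
        out = summarize_cross(calls).set_index("class")
        assert out.loc["maternal", "percent"] == pytest.approx(50.0)
        assert out.loc["paternal", "percent"] == pytest.approx(25.0)

    def test_empty_input(self):
        assert summarize_cross(pd.DataFrame(columns=["cross_id", "class"])).empty

    def test_common_gene_filter_boundary(self):
        profs = {
            "a": _profiles([("g1", 50.0, 5.0), ("g2", 50.0, 4.9)]),
            "b": _profiles([("g1", 50.0, 5.0), ("g2", 50.0, 100.0)]),
        }
        assert common_gene_filter(profs, min_mean_reads=5) == {"g1"}
        assert common_gene_filter(profs, min_mean_reads=0) == {"g1", "g2"}


class TestDistributionComparisons:
    def test_identical_vectors_p_one(self):
        a = np.linspace(0, 50, 20)
        with pytest.warns(UserWarning):
            _, p, _, _ = compare_bias_distributions(a, a)
        assert p == 1.0

    def test_constant_shift_detected(self, rng):
        a = rng.uniform(0, 50, 100)
        _, p, mean_a, mean_b = compare_bias_distributions(a, a + 3.0)
        assert p < 0.001 and mean_b - mean_a == pytest.approx(3.0)

    def test_swap_preserves_p(self, rng):
        a, b = rng.uniform(0, 50, 30), rng.uniform(0, 50, 30)
        _, p1, _, _ = compare_bias_distributions(a, b)
        _, p2, _, _ = compare_bias_distributions(b, a)
        assert p1 == pytest.approx(p2)

    def test_identity_regression(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        r2, slope, _ = bias_correlation(a, a)
        assert r2 == pytest.approx(1.0) and slope == pytest.approx(1.0)

    def test_negated_regression(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        r2, slope, _ = bias_correlation(a, -a)
        assert r2 == pytest.approx(1.0) and slope == pytest.approx(-1.0)

    def test_independent_vectors_near_zero_r2(self, rng):
        a, b = rng.uniform(size=1000), rng.uniform(size=1000)
        r2, _, _ = bias_correlation(a, b)
        assert r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(UsageError):
            bias_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLiteratureAnnotation:
    LIT = pd.DataFrame({"gene_id": ["known1", "known2"], "status": ["known_PEG", "known_PEG"]})

    def _calls(self, mapping, cross="hybrid"):
        return pd.DataFrame(
            {"gene_id": list(mapping), "cross_id": cross, "class": list(mapping.values())}
        )

    def test_reverted_to_maternal(self):
        ann = annotate_with_literature(
            self._calls({"known1": "maternal"}), self._calls({"known1": "paternal"}), self.LIT
        )
        row = ann.set_index("gene_id").loc["known1"]
        assert row["hybrid_status"] == "reverted_to_maternal"

    def test_confirmed_peg(self):
        ann = annotate_with_literature(
            self._calls({"known1": "paternal"}), self._calls({}), self.LIT
        )
        assert ann.set_index("gene_id").loc["known1", "hybrid_status"] == "confirmed"

    def test_de_novo_peg(self):
        ann = annotate_with_literature(
            self._calls({"novel": "paternal"}), self._calls({"novel": "biparental"}), self.LIT
        )
        assert ann.set_index("gene_id").loc["novel", "hybrid_status"] == "de_novo_PEG"

    def test_no_coverage_not_informative(self):
        ann = annotate_with_literature(self._calls({}), self._calls({}), self.LIT)
        assert (ann["hybrid_status"] == "not_informative").all()

    def test_duplicate_literature_rejected(self):
        dup = pd.concat([self.LIT, self.LIT.iloc[:1]])
        with pytest.raises(UsageError):
            annotate_with_literature(self._calls({}), self._calls({}), dup)


class TestDownsampledChisq:
    def test_identical_fractions_null(self):
        a = {"N_m": 60.0, "N_p": 40.0, "C": 100.0}
        b = {"N_m": 12.0, "N_p": 8.0, "C": 20.0}
        chi2, p = downsampled_chisq(a, b)
        assert chi2 == pytest.approx(0.0)

    def test_frozen_oracle_example(self):
        # (90 maternal of 100) vs (12 of 20): rescaled to (18,2) vs (12,8)
        a = {"N_m": 90.0, "N_p": 10.0, "C": 100.0}
        b = {"N_m": 12.0, "N_p": 8.0, "C": 20.0}
        chi2, p = downsampled_chisq(a, b)
        oracle = stats.chi2_contingency([[18, 2], [12, 8]], correction=False)
        assert chi2 == pytest.approx(oracle.statistic, abs=1e-9)
        assert chi2 == pytest.approx(4.8, abs=1e-9)

    def test_rescaling_preserves_fraction_within_rounding(self, rng):
        for _ in range(50):
            c_a, c_b = rng.integers(6, 400, 2)
            f = rng.uniform()
            a = {"N_m": c_a * f, "N_p": c_a * (1 - f), "C": float(c_a)}
            b = {"N_m": c_b * 0.5, "N_p": c_b * 0.5, "C": float(c_b)}
            target = min(c_a, c_b)
            from poex.classify import _round_half_up

            scaled = _round_half_up(a["N_m"] * target / c_a)
            assert abs(100 * scaled / target - 100 * f) <= 100 / (2 * target) + 1e-9

    def test_low_coverage_refused(self):
        a = {"N_m": 3.0, "N_p": 1.0, "C": 4.0}
        b = {"N_m": 50.0, "N_p": 50.0, "C": 100.0}
        with pytest.raises(LowCoverageError):
            downsampled_chisq(a, b)


class TestCompareCallSets:
    def _calls(self, pegs, megs=()):
        genes = list(pegs) + list(megs)
        classes = ["paternal"] * len(pegs) + ["maternal"] * len(megs)
        return pd.DataFrame({"gene_id": genes, "cross_id": "c", "class": classes})

    def test_identical_sets(self):
        a = self._calls(["g1"], ["g2"])
        out = compare_call_sets(a, a)
        assert out.unique_a == {"maternal": [], "paternal": []}

    def test_disjoint_sets(self):
        out = compare_call_sets(self._calls(["a"]), self._calls(["b"]))
        assert out.shared["paternal"] == []
        assert out.unique_a["paternal"] == ["a"] and out.unique_b["paternal"] == ["b"]
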