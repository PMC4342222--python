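"""Synthetic-data generator: determinism, planted structure, mixture arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poex.errors import UsageError
from poex.quantify import genotype_positions, profile_genes
from poex.simulate import (
    ENDOSPERM_ONLY,
    EVEN_MIX,
    NO_BIAS,
    BiasModel,
    GenomeModel,
    ImprintingSpec,
    SeedMixtureModel,
    SyntheticGenome,
    simulate_cross,
    simulate_lcm_matrix,
    simulate_parents,
)


def _biparental_spec(genome):
    return ImprintingSpec(
        classes=pd.Series("biparental", index=pd.Index(genome.gene_ids, name="gene_id"))
    )


class TestGenomeModel:
    def test_degenerate_model_rejected(self):
        with pytest.raises(UsageError):
            GenomeModel(n_genes=0)
        with pytest.raises(UsageError):
            GenomeModel(divergence_rate=1.5)

    def test_zero_divergence_empty_truth(self):
        genome = SyntheticGenome(GenomeModel(n_genes=10, gene_length=50, divergence_rate=0.0, seed=1))
        assert len(genome.truth_snps()) == 0

    def test_planted_snps_match_binomial_expectation(self):
        model = GenomeModel(n_genes=150, gene_length=1000, divergence_rate=0.05, seed=2)
        truth = SyntheticGenome(model).truth_snps()
        per_gene = truth.groupby("gene_id").size()
        # mean ~ Binomial(1000, 0.05) expectation 50, SE of the mean ~ 6.9/sqrt(150)
        assert abs(per_gene.reindex([f"g{i+1:05d}" for i in range(150)], fill_value=0).mean() - 50) < 2.0

    def test_shared_reference_seed_shares_reference(self):
        a = SyntheticGenome(GenomeModel(n_genes=5, gene_length=30, seed=1, reference_seed=9))
        b = SyntheticGenome(GenomeModel(n_genes=5, gene_length=30, seed=2, reference_seed=9))
        assert np.array_equal(a.ref, b.ref)
        assert not np.array_equal(a.div_mask, b.div_mask)


class TestDeterminism:
    def test_parents_bit_reproducible(self):
        model = GenomeModel(n_genes=15, gene_length=100, heterozygosity_rate=0.01, seed=3)
        a = simulate_parents(model)
        b = simulate_parents(model)
        pd.testing.assert_frame_equal(a.maternal.data, b.maternal.data)
        pd.testing.assert_frame_equal(a.paternal.data, b.paternal.data)
        pd.testing.assert_frame_equal(a.truth_snps, b.truth_snps)

    def test_cross_bit_reproducible(self):
        genome = SyntheticGenome(GenomeModel(n_genes=15, gene_length=100, seed=4))
        spec = _biparental_spec(genome)
        a = simulate_cross(genome, spec, seed=5)
        b = simulate_cross(genome, spec, seed=5)
        pd.testing.assert_frame_equal(a.pileup.data, b.pileup.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_lcm_bit_reproducible(self):
        a, ta = simulate_lcm_matrix(n_genes=50, n_specific=5, seed=6)
        b, tb = simulate_lcm_matrix(n_genes=50, n_specific=5, seed=6)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert ta == tb


class TestBiasModel:
    def test_even_parameter_is_identity(self):
        assert BiasModel(0.5).distort(0.37) == pytest.approx(0.37)
        assert BiasModel(0.5).loss_probability == 0.0

    def test_target_reached_at_even_mix(self):
        assert BiasModel(0.60).distort(0.5) == pytest.approx(0.60)

    def test_below_half_favours_nonreference(self):
        assert BiasModel(0.40).distort(0.5) == pytest.approx(0.40)

    def test_bounds_rejected(self):
        with pytest.raises(UsageError):
            BiasModel(0.0)


class TestSeedMixture:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(UsageError):
            SeedMixtureModel(f_maternal_tissue=0.5, f_endosperm=0.5, f_embryo=0.5)

    def test_expected_fraction_closed_form(self):
        """f_mat=0.5, f_endo=0.5, biparental, no bias -> 0.5 + 0.5*(2/3) = 0.8333."""
        genome = SyntheticGenome(GenomeModel(n_genes=30, gene_length=60, seed=7))
        mix = SeedMixtureModel(f_maternal_tissue=0.5, f_endosperm=0.5, f_embryo=0.0)
        result = simulate_cross(genome, _biparental_spec(genome), mix=mix, seed=8)
        assert np.allclose(result.truth["true_maternal_fraction"], 5.0 / 6.0)
        assert np.allclose(result.truth["expected_maternal_fraction"], 5.0 / 6.0)

    def test_all_endosperm_meg_fully_maternal(self):
        genome = SyntheticGenome(GenomeModel(n_genes=10, gene_length=60, seed=9))
        spec = ImprintingSpec(classes=pd.Series("MEG", index=pd.Index(genome.gene_ids)))
        result = simulate_cross(genome, spec, mix=ENDOSPERM_ONLY, seed=10)
        assert np.allclose(result.truth["true_maternal_fraction"], 1.0)


class TestImprintingSpec:
    def test_class_fractions_realised(self):
        spec = ImprintingSpec.random(
            [f"g{i}" for i in range(200)], meg_fraction=0.10, peg_fraction=0.05,
            reverted_fraction=0.05, seed=11,
        )
        counts = spec.classes.value_counts()
        assert counts["MEG"] == 20 and counts["PEG"] == 10 and counts["reverted_PEG"] == 10

    def test_reverted_dose_depends_on_design(self):
        spec = ImprintingSpec(classes=pd.Series(["reverted_PEG"], index=["g1"]), peg_maternal_dose=0.1)
        assert spec.endosperm_dose("control").iloc[0] == pytest.approx(0.1)
        assert spec.endosperm_dose("hybrid").iloc[0] == pytest.approx(1.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(UsageError):
            ImprintingSpec(classes=pd.Series(["martian"], index=["g1"]))


class TestSamplingBehaviour:
    def _observed_fractions(self, genome, depth_mean, seed, bias=NO_BIAS):
        spec = _biparental_spec(genome)
        result = simulate_cross(genome, spec, mix=EVEN_MIX, bias=bias, depth_mean=depth_mean, seed=seed)
        diag = genome.truth_snps()
        positions = genotype_positions(result.pileup, diag, genome.reference_bases())
        profiles = profile_genes(positions, cross_id="x")
        return result.truth.set_index("gene_id"), profiles

    def test_high_depth_converges_to_truth(self):
        # binomial sampling sd at 8000 reads is ~0.006, so an absolute error
        # under 0.02 (>3 sd) should hold for at least 99% of genes
        genome = SyntheticGenome(GenomeModel(n_genes=200, gene_length=80, seed=12))
        truth, profiles = self._observed_fractions(genome, depth_mean=8000, seed=13)
        observed = profiles.set_index("gene_id")["P_m"] / 100.0
        expected = truth.loc[observed.index, "expected_maternal_fraction"]
        err = (observed - expected).abs()
        assert (err < 0.02).mean() >= 0.99
        # and the errors themselves shrink roughly with 1/sqrt(depth)
        assert err.median() < 0.01

    def test_neutral_bias_leaves_fractions_unchanged(self):
        genome = SyntheticGenome(GenomeModel(n_genes=300, gene_length=80, seed=14))
        _, unbiased = self._observed_fractions(genome, depth_mean=50, seed=15)
        _, neutral = self._observed_fractions(genome, depth_mean=50, seed=16, bias=BiasModel(0.5))
        ks = stats.ks_2samp(unbiased["P_m"], neutral["P_m"])
        assert ks.pvalue > 0.01


class TestLcmMatrix:
    def test_values_respect_floor(self):
        matrix, _ = simulate_lcm_matrix(n_genes=100, n_specific=5, seed=17)
        assert (matrix.values.to_numpy() >= 2.3).all()

    def test_n_specific_bound(self):
        with pytest.raises(UsageError):
            simulate_lcm_matrix(n_genes=10, n_specific=11)

    def test_no_planted_genes_gives_empty_truth(self):
        _, truth = simulate_lcm_matrix(n_genes=50, n_specific=0, seed=18)
        assert truth == []
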