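"""Genotypic-effect models: covariates, locus values, epistasis, effect
generation and phenotype simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polybreed import (
    TraitModel,
    additive_covariate,
    dominance_covariate,
    dosage_matrix,
    epistatic_pair_values,
    functional_variance,
    generate_effects,
    locus_values,
    make_fixture,
    simulate_phenotypes,
    total_genetic_value,
)
from polybreed.genome import GeneticMap, GenomePopulation, LociPanel

from _oracles import oracle_components, oracle_total_g, random_instance


class TestCovariates:
    @given(st.sampled_from([2, 4, 6, 8]), st.data())
    @settings(max_examples=60, deadline=None)
    def test_additive_antisymmetry_and_range(self, ploidy, data):
        t = data.draw(st.integers(0, ploidy))
        v = additive_covariate(t, ploidy)
        assert -1.0 <= v <= 1.0
        assert additive_covariate(ploidy - t, ploidy) == pytest.approx(-v)

    @given(st.sampled_from([2, 4, 6, 8]), st.data())
    @settings(max_examples=60, deadline=None)
    def test_dominance_symmetry_and_range(self, ploidy, data):
        t = data.draw(st.integers(0, ploidy))
        v = dominance_covariate(t, ploidy)
        assert 0.0 <= v <= 1.0
        assert dominance_covariate(ploidy - t, ploidy) == pytest.approx(v)
        assert dominance_covariate(ploidy // 2, ploidy) == 1.0
        assert dominance_covariate(0, ploidy) == 0.0

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError):
            additive_covariate(3, 2)
        with pytest.raises(ValueError):
            dominance_covariate(-1, 4)


class TestLocusValues:
    """Bi-allelic reduction: the symbolic one-locus value table."""

    def test_diploid_rows_reduce_to_substitution_coding(self):
        rng = np.random.default_rng(0)
        a1, a2, d1, d2 = rng.normal(size=4)
        rows = {
            (2, 0): (-(a2 - a1), 0.0),
            (1, 1): (0.0, d1 + d2),
            (0, 2): (+(a2 - a1), 0.0),
        }
        for (t1, t2), (exp_a, exp_d) in rows.items():
            a, d = locus_values([t1, t2], [a1, a2], [d1, d2], ploidy=2)
            assert a == pytest.approx(exp_a)
            assert d == pytest.approx(exp_d)

    def test_tetraploid_rows(self):
        rng = np.random.default_rng(1)
        a1, a2, d1, d2 = rng.normal(size=4)
        rows = {
            (4, 0): (-(a2 - a1), 0.0),
            (3, 1): (-0.5 * (a2 - a1), 0.75 * (d1 + d2)),
            (2, 2): (0.0, d1 + d2),
            (1, 3): (0.5 * (a2 - a1), 0.75 * (d1 + d2)),
            (0, 4): (+(a2 - a1), 0.0),
        }
        for (t1, t2), (exp_a, exp_d) in rows.items():
            a, d = locus_values([t1, t2], [a1, a2], [d1, d2], ploidy=4)
            assert a == pytest.approx(exp_a)
            assert d == pytest.approx(exp_d)

    def test_non_carried_allele_still_contributes(self):
        # tri-allelic diploid: allele 3 absent, its covariate is -1
        a, _ = locus_values([1, 1, 0], [0.5, -0.5, 9.9], [0, 0, 0], ploidy=2)
        assert a == pytest.approx(-9.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            locus_values([1, 1], [1.0, 2.0, 3.0], [0.0, 0.0], ploidy=2)


class TestEpistaticValues:
    def test_diploid_epistatic_values_match_loop_oracle(self):
        """Every diploid two-locus genotype against the explicit double sum."""
        rng = np.random.default_rng(2)
        aa, ad, da, dd = rng.normal(size=(4, 4))
        from _oracles import cov_a, cov_d

        for tk in range(3):
            for tl in range(3):
                dk, dl = [tk, 2 - tk], [tl, 2 - tl]
                got = epistatic_pair_values(dk, dl, aa, ad, da, dd, ploidy=2)
                exp_aa = exp_addd = exp_dd = 0.0
                for bl in range(2):
                    for bk in range(2):
                        i = bl * 2 + bk
                        exp_aa += cov_a(dl[bl], 2) * cov_a(dk[bk], 2) * aa[i]
                        exp_addd += cov_d(dl[bl], 2) * cov_a(dk[bk], 2) * ad[i]
                        exp_addd += cov_a(dl[bl], 2) * cov_d(dk[bk], 2) * da[i]
                        exp_dd += cov_d(dl[bl], 2) * cov_d(dk[bk], 2) * dd[i]
                assert got == pytest.approx((exp_aa, exp_addd, exp_dd))

    def test_heterozygous_locus_kills_aa_regardless_of_partner(self):
        rng = np.random.default_rng(3)
        aa = rng.normal(size=4)
        for tl in range(3):
            got, _, _ = epistatic_pair_values([1, 1], [tl, 2 - tl], aa, np.zeros(4), np.zeros(4), np.zeros(4), 2)
            assert got == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            epistatic_pair_values([1, 1], [1, 1], np.zeros(3), np.zeros(4), np.zeros(4), np.zeros(4), 2)


class TestTotalGeneticValue:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n_b = int(rng.integers(2, 5))
            ploidy = int(rng.choice([2, 4, 6]))
            n_qtl = int(rng.integers(1, 6))
            n_ep = int(rng.integers(0, min(2, n_qtl // 2) + 1))
            dosage, effects = random_instance(rng, n_b, ploidy, n_qtl, n_ep)
            gv = total_genetic_value(dosage, effects, ploidy)
            expected = oracle_total_g(dosage, effects, ploidy)
            assert np.allclose(gv.g, expected, rtol=0, atol=1e-12 * max(1, np.abs(expected).max()))

    def test_all_zero_effects_give_zero(self):
        rng = np.random.default_rng(5)
        dosage, effects = random_instance(rng, 2, 2, 4, 2)
        for name in ("a", "d", "aa", "ad", "da", "dd"):
            getattr(effects, name)[:] = 0.0
        effects.a_offset[:] = 0.0
        effects.nonadd_offset = 0.0
        gv = total_genetic_value(dosage, effects, 2)
        assert np.all(gv.g == 0.0)

    def test_additive_only_reduces_to_sum_of_locus_values(self):
        rng = np.random.default_rng(6)
        dosage, effects = random_instance(rng, 3, 4, 4, 0)
        for name in ("d",):
            getattr(effects, name)[:] = 0.0
        effects.nonadd_offset = 0.0
        gv = total_genetic_value(dosage, effects, 4)
        comp = oracle_components(dosage, effects, 4)
        assert np.allclose(gv.g, comp["a"] - effects.a_offset.sum())


class TestGenerateEffects:
    def test_rescaling_hits_targets_and_centering_is_exact(self, bi_short_genome):
        founders, panel, _cfg = bi_short_genome
        trait = TraitModel(
            sigma_a2=1.0, sigma_d2=0.25, sigma_aa2=0.25, sigma_ad2=0.25, sigma_dd2=0.25, sigma_e2=2.0
        )
        effects = generate_effects(founders, panel, trait, n_ep=panel.n_qtl // 2, rng=7)
        for comp, target in (("additive", 1.0), ("dominance", 0.25), ("aa", 0.25), ("ad", 0.25), ("dd", 0.25)):
            assert functional_variance(comp, effects, founders, panel) == pytest.approx(target, abs=1e-9)
        # per-locus founder means of centered additive values are exactly zero
        dos = dosage_matrix(founders, panel.qtl, n_alleles=effects.n_b)
        ta = (dos - founders.ploidy / 2) * (2 / founders.ploidy)
        per_locus = np.einsum("njb,bj->nj", ta, effects.a) - effects.a_offset
        assert np.abs(per_locus.mean(axis=0)).max() < 1e-10
        gv = total_genetic_value(dos, effects, founders.ploidy)
        assert abs(gv.g.mean()) < 1e-10
        # pairing: every QTL in exactly one pair when n_ep = n_qtl / 2
        assert len(np.unique(effects.pairs)) == 2 * effects.n_ep == panel.n_qtl

    def test_dominance_effects_track_additive_effects(self, bi_short_genome):
        # d* = delta * a with E[delta] = 0.19 > 0: dominance effects correlate
        # positively with the additive effects they derive from
        founders, panel, _cfg = bi_short_genome
        trait = TraitModel(sigma_a2=1.0, sigma_d2=0.25, sigma_e2=2.0)
        effects = generate_effects(founders, panel, trait, rng=8)
        corr = np.corrcoef(effects.a.ravel(), effects.d.ravel())[0, 1]
        assert corr > 0.2

    def test_clonal_founders_with_positive_variance_raise(self):
        pop, panel = make_fixture("worked_tables")["diploid"]
        clones = pop.subset(np.array([0, 0, 0, 0]))
        with pytest.raises(ValueError, match="rescale"):
            generate_effects(clones, panel, TraitModel(sigma_a2=1.0), rng=9)

    def test_additive_only_trait_zeroes_other_components(self, tiny_diploid_fixture):
        pop, panel, _ = tiny_diploid_fixture
        trait = TraitModel(sigma_a2=1.0, sigma_d2=0.0, sigma_aa2=0.0, sigma_ad2=0.0, sigma_dd2=0.0)
        effects = generate_effects(pop, panel, trait, n_ep=1, rng=10)
        for name in ("d", "aa", "ad", "da", "dd"):
            assert np.all(getattr(effects, name) == 0.0)


@pytest.fixture()
def tiny_diploid_fixture():
    return make_fixture("tiny_diploid")


class TestFunctionalVariance:
    def _one_locus_panel_pop(self, haps):
        gmap = GeneticMap(np.array([10.0]), np.array([0]), np.array([5.0]), np.array([2]), np.array([True]))
        n = haps.shape[0]
        pop = GenomePopulation(gmap, 2, [haps], np.arange(n), np.full((n, 2), -1), np.zeros(n, int))
        f0 = (haps == 0).mean()
        panel = LociPanel(np.array([0]), np.array([2]), np.array([], dtype=int), np.array([[f0, 1 - f0]]),
                          np.array([]), 2)
        return pop, panel

    def test_single_locus_methods_agree_exactly(self):
        rng = np.random.default_rng(11)
        haps = rng.integers(0, 2, size=(20, 2, 1)).astype(np.uint8)
        pop, panel = self._one_locus_panel_pop(haps)
        effects = generate_effects(pop, panel, TraitModel(sigma_a2=1.0), rng=12)
        v_ind = functional_variance("additive", effects, pop, panel, "by_individual")
        v_loc = functional_variance("additive", effects, pop, panel, "by_locus")
        assert v_ind == pytest.approx(v_loc)

    def test_perfect_positive_ld_inflates_individual_variance(self):
        # two loci with identical haplotype patterns and equal effects
        gmap = GeneticMap(np.array([10.0]), np.array([0, 0]), np.array([2.0, 8.0]),
                          np.array([2, 2]), np.array([True, True]))
        rng = np.random.default_rng(13)
        col = rng.integers(0, 2, size=(30, 2, 1)).astype(np.uint8)
        haps = np.concatenate([col, col], axis=2)
        pop = GenomePopulation(gmap, 2, [haps], np.arange(30), np.full((30, 2), -1), np.zeros(30, int))
        f0 = (col == 0).mean()
        panel = LociPanel(np.array([0, 1]), np.array([2, 2]), np.array([], dtype=int),
                          np.array([[f0, 1 - f0], [f0, 1 - f0]]), np.array([]), 2)
        effects = generate_effects(pop, panel, TraitModel(sigma_a2=1.0), rng=14)
        effects.a[:, 1] = effects.a[:, 0]  # equal effects on perfectly correlated loci
        effects.a_offset[1] = effects.a_offset[0]
        v_ind = functional_variance("additive", effects, pop, panel, "by_individual")
        v_loc = functional_variance("additive", effects, pop, panel, "by_locus")
        assert v_ind > v_loc

    def test_unknown_method_rejected(self, tiny_diploid_fixture):
        pop, panel, effects = tiny_diploid_fixture
        with pytest.raises(ValueError, match="method"):
            functional_variance("additive", effects, pop, panel, "by_continent")


class TestPhenotypes:
    def test_no_noise_is_exact(self):
        g = np.arange(5.0)
        y = simulate_phenotypes(g, mu=2.0, sigma_e2=0.0, rng=15)
        assert np.allclose(y, g + 2.0)

    def test_residual_variance_matches_target(self):
        rng = np.random.default_rng(16)
        g = rng.normal(size=20_000)
        y = simulate_phenotypes(g, mu=0.0, sigma_e2=2.0, rng=17)
        assert np.var(y - g) == pytest.approx(2.0, rel=0.05)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(np.zeros(3), 0.0, -1.0, rng=18)
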