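"""Founder-genome simulation, meiosis and panel selection."""

import numpy as np
import pytest

from polybreed import (
    GeneticMap,
    GenomePopulation,
    dosage_matrix,
    marker_dosage,
    random_genetic_map,
    select_loci,
    simulate_historical_population,
)
from polybreed.genome import _gamete_batch
from polybreed.pipeline import potato_chromosome_lengths


def single_chrom_map(positions, length=100.0, n_alleles=2, qtl=False):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return GeneticMap(
        chrom_lengths=np.array([length]),
        chrom=np.zeros(n, dtype=int),
        pos=positions,
        n_alleles=np.full(n, n_alleles),
        is_qtl_candidate=np.full(n, qtl),
    )


class TestGeneticMap:
    def test_rejects_unsorted_loci(self):
        with pytest.raises(ValueError, match="sorted"):
            single_chrom_map([50.0, 10.0])

    def test_rejects_positions_beyond_chromosome(self):
        with pytest.raises(ValueError, match="beyond"):
            single_chrom_map([120.0])

    def test_potato_map_total_length(self):
        lengths = potato_chromosome_lengths()
        assert len(lengths) == 12
        assert np.isclose(lengths.sum(), 888.6)


class TestHistoricalPopulation:
    def test_no_drift_keeps_exactly_equal_frequencies(self):
        gmap = random_genetic_map([100.0, 80.0], 60, 40, qtl_alleles=4, rng=0)
        pop = simulate_historical_population(gmap, Ne=50, n_generations=0, ploidy=2, rng=1)
        freqs = pop.allele_freqs()
        bi = gmap.n_alleles == 2
        assert np.allclose(freqs[bi, :2], 0.5)
        assert np.allclose(freqs[~bi], 0.25)

    def test_heterozygosity_decays_at_wright_fisher_rate(self):
        # E[H_t] = H_0 (1 - 1/(2 Ne))^t for diploids, checked over many loci
        ne, t = 100, 200
        gmap = random_genetic_map(potato_chromosome_lengths(), 3000, 0, rng=2)
        pop = simulate_historical_population(gmap, Ne=ne, n_generations=t, ploidy=2, rng=3)
        freqs = pop.allele_freqs()
        het = (1.0 - (freqs**2).sum(axis=1)).mean()
        expected = 0.5 * (1.0 - 1.0 / (2 * ne)) ** t
        assert abs(het - expected) < 0.02

    def test_tiny_population_fixes_almost_all_loci(self):
        gmap = random_genetic_map([100.0], 500, 0, rng=4)
        pop = simulate_historical_population(gmap, Ne=2, n_generations=200, ploidy=2, rng=5)
        freqs = pop.allele_freqs()
        fixed = (freqs.max(axis=1) == 1.0).mean()
        assert fixed >= 0.99

    def test_allele_counts_only_shrink_and_dosages_conserve(self):
        gmap = random_genetic_map([50.0], 100, 100, qtl_alleles=4, rng=6)
        pop = simulate_historical_population(gmap, Ne=30, n_generations=50, ploidy=4, rng=7)
        freqs = pop.allele_freqs()
        assert np.allclose(freqs.sum(axis=1), 1.0)
        dos = dosage_matrix(pop, np.arange(gmap.n_loci), n_alleles=4)
        assert (dos.sum(axis=2) == 4).all()

    def test_rejects_odd_ploidy_and_tiny_ne(self):
        gmap = random_genetic_map([50.0], 10, 0, rng=8)
        with pytest.raises(ValueError, match="ploidy"):
            simulate_historical_population(gmap, Ne=10, n_generations=1, ploidy=3, rng=9)
        with pytest.raises(ValueError, match="Ne"):
            simulate_historical_population(gmap, Ne=1, n_generations=1, ploidy=2, rng=9)
        with pytest.raises(ValueError, match="bottleneck"):
            simulate_historical_population(gmap, Ne=10, n_generations=1, ploidy=2, bottleneck=(1, 1, 1), rng=9)


class TestMeiosis:
    def test_zero_length_chromosome_copies_a_parental_homolog(self):
        # ploidy 2, two distinct homologs, 0 cM: gamete is one of them, ~1/2 each
        hap = np.array([[[0, 0, 0], [1, 1, 1]]], dtype=np.uint8)
        pos = np.array([0.0, 0.0, 0.0])
        gam = _gamete_batch(hap, np.zeros(2000, dtype=int), pos, 0.0, np.random.default_rng(0))
        assert gam.shape == (2000, 1, 3)
        whole = gam[:, 0, :]
        assert set(map(tuple, whole)) <= {(0, 0, 0), (1, 1, 1)}
        frac = (whole[:, 0] == 0).mean()
        assert 0.45 < frac < 0.55

    def test_mean_crossovers_match_poisson_map_length(self):
        # 100 cM chromosome -> ~1 crossover per gamete; count source switches
        m = 51
        pos = np.linspace(0, 100, m)
        hap = np.zeros((1, 2, m), dtype=np.uint8)
        hap[0, 1] = 1
        gam = _gamete_batch(hap, np.zeros(10_000, dtype=int), pos, 100.0, np.random.default_rng(1))
        switches = (np.diff(gam[:, 0, :], axis=1) != 0).sum(axis=1)
        assert abs(switches.mean() - 1.0) < 0.05

    @pytest.mark.parametrize("d_cm", [10.0, 50.0, 100.0])
    def test_recombination_fraction_follows_haldane(self, d_cm):
        pos = np.array([0.0, d_cm])
        hap = np.array([[[0, 0], [1, 1]]], dtype=np.uint8)
        gam = _gamete_batch(hap, np.zeros(20_000, dtype=int), pos, d_cm, np.random.default_rng(2))
        rec = (gam[:, 0, 0] != gam[:, 0, 1]).mean()
        expected = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
        assert abs(rec - expected) < 0.012

    def test_tetraploid_bivalent_pairing_excludes_double_reduction(self):
        # one locus, four private alleles: a gamete carries two *different*
        # parental homologs; every unordered pair eventually appears
        hap = np.arange(4, dtype=np.uint8).reshape(1, 4, 1)
        gam = _gamete_batch(hap, np.zeros(3000, dtype=int), np.array([5.0]), 10.0, np.random.default_rng(3))
        assert gam.shape == (3000, 2, 1)
        pairs = {tuple(sorted(g[:, 0])) for g in gam}
        assert all(a != b for a, b in pairs)  # no duplicated homolog: no double reduction
        assert len(pairs) == 6  # all unordered pairs occur under random pairing

    def test_empty_chromosome_rejected(self):
        hap = np.zeros((1, 2, 0), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            _gamete_batch(hap, np.zeros(1, dtype=int), np.array([]), 50.0, np.random.default_rng(0))


class TestDosageMatrix:
    def test_worked_dosage_rows(self):
        from polybreed import make_fixture

        tables = make_fixture("worked_tables")
        pop2, panel2 = tables["diploid"]
        dos = dosage_matrix(pop2, panel2.qtl)
        assert dos[:, 0, :].tolist() == [[2, 0], [1, 1], [0, 2]]
        pop4, panel4 = tables["tetraploid"]
        dos4 = dosage_matrix(pop4, panel4.qtl)
        assert dos4[:, 0, :].tolist() == [[4, 0], [3, 1], [2, 2], [1, 3], [0, 4]]
        assert (dos4.sum(axis=2) == 4).all()

    def test_unknown_locus_rejected(self):
        from polybreed import make_fixture

        pop, panel, _ = make_fixture("tiny_diploid")
        with pytest.raises(ValueError, match="unknown locus"):
            dosage_matrix(pop, np.array([99]))


@pytest.fixture(scope="module")
def drifted_pop():
    gmap = random_genetic_map([200.0, 150.0], 800, 800, qtl_alleles=4, rng=10)
    return simulate_historical_population(gmap, Ne=80, n_generations=40, ploidy=2, rng=11)


class TestSelectLoci:
    def test_marker_and_qtl_constraints_hold(self, drifted_pop):
        panel = select_loci(drifted_pop, 60, 100, 0.05, [(2, 0.5), (4, 0.5)], rng=12)
        freqs = drifted_pop.allele_freqs()
        assert ((freqs[panel.markers, :2] >= 0.05).all(axis=1)).all()
        assert len(np.intersect1d(panel.qtl, panel.markers)) == 0
        counts = np.bincount(panel.qtl_seg_alleles, minlength=5)
        assert counts[2] == 30 and counts[4] == 30
        for locus, c in zip(panel.qtl, panel.qtl_seg_alleles):
            assert (freqs[locus] >= 0.05).sum() == c
        assert panel.n_b == 4

    def test_profile_rounding_matches_proportions(self, drifted_pop):
        panel = select_loci(drifted_pop, 10, 5, 0.05, [(2, 0.2), (4, 0.8)], rng=13)
        counts = np.bincount(panel.qtl_seg_alleles, minlength=5)
        assert counts[2] == 2 and counts[4] == 8

    def test_fixed_population_raises_named_error(self):
        gmap = random_genetic_map([50.0], 30, 30, rng=14)
        pop = simulate_historical_population(gmap, Ne=20, n_generations=0, ploidy=2, rng=15)
        for h in pop.haplotypes:
            h[:] = 0  # clone everyone: nothing segregates
        with pytest.raises(ValueError, match="marker"):
            select_loci(pop, 5, 5, 0.05, [(2, 1.0)], rng=16)


class TestLinkageDisequilibrium:
    def test_ld_decays_with_map_distance(self, bi_short_genome):
        founders, panel, _cfg = bi_short_genome
        dos = marker_dosage(founders, panel).astype(float)
        pos = founders.gmap.pos[panel.markers]
        chrom = founders.gmap.chrom[panel.markers]
        rng = np.random.default_rng(17)
        near, far = [], []
        idx = rng.choice(len(pos), size=800, replace=False)
        for j in idx:
            same = np.flatnonzero((chrom == chrom[j]))
            dist = np.abs(pos[same] - pos[j])
            for bucket, lo, hi in ((near, 0.01, 1.0), (far, 10.0, 20.0)):
                cand = same[(dist > lo) & (dist < hi)]
                if len(cand):
                    k = cand[rng.integers(len(cand))]
                    r = np.corrcoef(dos[:, j], dos[:, k])[0, 1]
                    bucket.append(r * r)
        assert np.mean(near) > np.mean(far)
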