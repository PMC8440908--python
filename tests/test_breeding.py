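"""Meiosis, crossing, single-seed descent, and parent pairing."""

import numpy as np
import pytest

import soysim as ss
from soysim.breeding import _gamete_batch
from soysim.genome import GeneticMap, Population


def _map_one_chr(length_cm, positions):
    positions = np.asarray(positions, dtype=float)
    return GeneticMap(
        lengths_cm=np.array([length_cm]),
        spans_bp=np.array([1_000_000]),
        site_chrom=np.zeros(len(positions), dtype=np.int32),
        site_pos=positions,
    )


def _diploid(hap0, hap1, gmap, n_copies=1):
    h = np.stack([np.asarray(hap0, dtype=np.uint8), np.asarray(hap1, dtype=np.uint8)])
    return Population(
        haplotypes=np.repeat(h[None], n_copies, axis=0),
        gmap=gmap,
        ids=np.arange(n_copies),
        family=np.zeros(n_copies, dtype=int),
        generation="founder",
    )


class TestMeiosis:
    def test_negligible_length_transmits_intact_haplotype(self):
        gmap = _map_one_chr(1e-9, [0.0, 2e-10, 5e-10])
        rng = np.random.default_rng(1)
        parent = np.stack([np.zeros(3, np.uint8), np.ones(3, np.uint8)])
        for _ in range(20):
            g = ss.meiosis(parent, gmap, rng)
            assert np.array_equal(g, parent[0]) or np.array_equal(g, parent[1])

    def test_mendelian_segregation(self):
        # heterozygous site transmits allele 1 with frequency 1/2
        gmap = _map_one_chr(50.0, [25.0])
        parent = np.array([[[0], [1]]], dtype=np.uint8)
        rng = np.random.default_rng(2)
        gam = _gamete_batch(parent, np.zeros(20_000, dtype=np.int64), gmap, rng)
        assert abs(gam.mean() - 0.5) < 0.015

    @pytest.mark.parametrize("d_cm", [5.0, 20.0, 40.0])
    def test_haldane_recombination_fraction(self, d_cm):
        # no interference + Poisson crossovers -> r = (1 - e^{-2d/100})/2,
        # verified by brute-force gamete counting on opposite-homozygote
        # haplotypes (allele identifies parental origin)
        gmap = _map_one_chr(50.0, [5.0, 5.0 + d_cm])
        parent = np.array([[[0, 0], [1, 1]]], dtype=np.uint8)
        rng = np.random.default_rng(3)
        gam = _gamete_batch(parent, np.zeros(20_000, dtype=np.int64), gmap, rng)
        r_obs = (gam[:, 0] != gam[:, 1]).mean()
        r_exp = (1 - np.exp(-2 * d_cm / 100)) / 2
        assert abs(r_obs - r_exp) < 0.012

    def test_map_mismatch_rejected(self):
        gmap = _map_one_chr(10.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            ss.meiosis(np.zeros((2, 5), dtype=np.uint8), gmap, np.random.default_rng(0))


class TestMakeCrosses:
    def test_inbred_identical_parents_reproduce_themselves(self):
        gmap = _map_one_chr(80.0, np.linspace(1, 79, 30))
        hap = (np.arange(30) % 2).astype(np.uint8)
        pop = _diploid(hap, hap, gmap, n_copies=2)
        plan = ss.CrossPlan(pairs=np.array([[0, 1]]))
        f1 = ss.make_crosses(pop, plan, np.random.default_rng(4))
        assert np.array_equal(f1.haplotypes[0, 0], hap)
        assert np.array_equal(f1.haplotypes[0, 1], hap)

    def test_opposite_homozygotes_give_full_heterozygote(self):
        gmap = _map_one_chr(80.0, np.linspace(1, 79, 30))
        h = np.zeros((2, 2, 30), dtype=np.uint8)
        h[1] = 1  # parent 1 carries all alt alleles
        pop = Population(haplotypes=h, gmap=gmap, ids=np.arange(2),
                         family=np.zeros(2, dtype=int), generation="founder")
        plan = ss.CrossPlan(pairs=np.array([[0, 1]]))
        f1 = ss.make_crosses(pop, plan, np.random.default_rng(5))
        assert np.all(f1.dosage() == 1)

    def test_allele_conservation(self, small_founders):
        # no allele absent from both parents ever appears in offspring
        plan = ss.CrossPlan(pairs=np.array([[0, 1]]))
        f1 = ss.make_crosses(small_founders, plan, np.random.default_rng(6))
        pd_ = small_founders.dosage()[:2]
        both_ref = (pd_[0] == 0) & (pd_[1] == 0)
        both_alt = (pd_[0] == 2) & (pd_[1] == 2)
        off = f1.dosage()[0]
        assert np.all(off[both_ref] == 0)
        assert np.all(off[both_alt] == 2)

    def test_missing_parent_rejected(self, small_founders):
        plan = ss.CrossPlan(pairs=np.array([[0, 99999]]))
        with pytest.raises(ValueError):
            ss.make_crosses(small_founders, plan, np.random.default_rng(7))

    def test_self_pairing_rejected(self):
        with pytest.raises(ValueError):
            ss.CrossPlan(pairs=np.array([[3, 3]]))


class TestSSD:
    @staticmethod
    def _full_het_f1(n_sites=120):
        gmap = _map_one_chr(100.0, np.linspace(0.5, 99.5, n_sites))
        h = np.zeros((1, 2, n_sites), dtype=np.uint8)
        h[0, 1] = 1
        return Population(haplotypes=h, gmap=gmap, ids=np.arange(1),
                          family=np.zeros(1, dtype=int), generation="F1")

    def test_f2_heterozygosity_one_half(self):
        f1 = self._full_het_f1()
        f2 = ss.ssd_advance(f1, 3000, n_selfing_rounds=0, rng=np.random.default_rng(8))
        assert f2.generation == "F2"
        assert abs(f2.mean_heterozygosity() - 0.5) < 0.025

    def test_f4_heterozygosity_one_eighth(self):
        # heterozygosity halves per selfing round: (1/2)^3 at F4
        f1 = self._full_het_f1()
        f4 = ss.ssd_advance(f1, 3000, n_selfing_rounds=2, rng=np.random.default_rng(9))
        assert f4.generation == "F4"
        assert abs(f4.mean_heterozygosity() - 0.125) < 0.015

    def test_family_sizes_exact(self, small_founders):
        plan = ss.pair_parents(small_founders.ids, 4, np.random.default_rng(10))
        f1 = ss.make_crosses(small_founders, plan, np.random.default_rng(11))
        f4 = ss.ssd_advance(f1, 50, rng=np.random.default_rng(12))
        assert f4.n_individuals == 200
        assert np.all(np.bincount(f4.family) == 50)

    def test_invalid_family_size(self, small_founders):
        plan = ss.pair_parents(small_founders.ids, 2, np.random.default_rng(13))
        f1 = ss.make_crosses(small_founders, plan, np.random.default_rng(13))
        with pytest.raises(ValueError):
            ss.ssd_advance(f1, 0, rng=np.random.default_rng(13))


class TestPairParents:
    def test_two_candidates_give_unique_pair(self):
        plan = ss.pair_parents(np.array([7, 9]), 1, np.random.default_rng(14))
        assert sorted(plan.pairs[0].tolist()) == [7, 9]

    def test_no_self_pairings_ever(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            plan = ss.pair_parents(np.arange(5), 30, rng)
            assert np.all(plan.pairs[:, 0] != plan.pairs[:, 1])

    def test_usage_approximately_uniform_with_zeros(self):
        # 375 parents, 300 crosses: usage is multinomial-uniform and some
        # parents go unused in a single plan
        rng = np.random.default_rng(16)
        tally = np.zeros(375)
        unused_seen = False
        n_plans = 200
        for _ in range(n_plans):
            plan = ss.pair_parents(np.arange(375), 300, rng)
            counts = np.bincount(plan.pairs.ravel(), minlength=375)
            tally += counts
            if np.any(counts == 0):
                unused_seen = True
        assert unused_seen
        mean = tally.mean()  # 200 * 600 / 375 = 320
        assert np.all(np.abs(tally - mean) < 6 * np.sqrt(mean))

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            ss.pair_parents(np.array([1]), 1, np.random.default_rng(17))
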