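import numpy as np
import pytest

from paleopair.io import MISSING
from paleopair.jackknife import block_partition
from paleopair.pairstats import (
    EXPECTED_RATIOS,
    conditional_nucleotide_diversity,
    kinship_test,
    mismatch_distance,
)
from paleopair.pseudohaploid import (
    PseudohaploidGenome,
    call_pseudohaploid,
    make_pseudo_twins,
)
from paleopair.simulate import PairSpec, PopSpec, SimulationConfig, simulate_all

from conftest import make_geno, make_panel


def genome(calls):
    return PseudohaploidGenome("g", np.asarray(calls, dtype=np.int8))


def flat_partition(panel, n_blocks=4):
    return block_partition(panel, np.arange(len(panel)), n_blocks=n_blocks)


def run_pair(relatedness, seed, n_snps=20_000, depth=5.0, error=0.001):
    cfg = SimulationConfig(
        n_snps=n_snps,
        pop_specs=(PopSpec("P", 0.01, 2),),
        pair_spec=PairSpec("P", relatedness, mean_depth=depth, error_rate=error),
        seed=seed,
    )
    panel, geno, pu1, pu2, truth = simulate_all(cfg)
    rng = np.random.default_rng(seed + 10_000)
    t1 = make_pseudo_twins(pu1, panel, rng=rng)
    t2 = make_pseudo_twins(pu2, panel, rng=rng)
    s1 = call_pseudohaploid(pu1, panel, rng=rng)
    s2 = call_pseudohaploid(pu2, panel, rng=rng)
    part = block_partition(panel, np.arange(len(panel)), n_blocks=50)
    return kinship_test(t1, t2, s1, s2, part), truth


class TestMismatchDistance:
    def test_identical_zero(self):
        panel = make_panel([("A", "C")] * 8)
        g = genome([0, 1, 0, 1, MISSING, 0, 1, 0])
        res = mismatch_distance(g, g, flat_partition(panel))
        assert res.estimate == 0.0

    def test_complementary_one(self):
        panel = make_panel([("A", "C")] * 8)
        g1 = genome([0, 1, 0, 1, 0, 1, 0, 1])
        g2 = genome([1, 0, 1, 0, 1, 0, 1, 0])
        res = mismatch_distance(g1, g2, flat_partition(panel))
        assert res.estimate == 1.0

    def test_symmetry(self):
        panel = make_panel([("A", "C")] * 12)
        rng = np.random.default_rng(0)
        g1 = genome(rng.integers(0, 2, 12))
        g2 = genome(rng.integers(0, 2, 12))
        part = flat_partition(panel)
        a = mismatch_distance(g1, g2, part)
        b = mismatch_distance(g2, g1, part)
        assert a.estimate == b.estimate
        assert a.se == b.se

    def test_missing_sites_excluded_from_denominator(self):
        panel = make_panel([("A", "C")] * 8)
        g1 = genome([0, MISSING, 0, 0, 0, 0, 0, 0])
        g2 = genome([1, 1, 0, 0, 0, 0, 0, 0])
        res = mismatch_distance(g1, g2, flat_partition(panel))
        assert res.estimate == pytest.approx(1 / 7)
        assert res.n_sites == 7

    def test_no_overlap_raises(self):
        panel = make_panel([("A", "C")] * 4)
        g1 = genome([0, 0, MISSING, MISSING])
        g2 = genome([MISSING, MISSING, 0, 0])
        with pytest.raises(ValueError, match="no sites"):
            mismatch_distance(g1, g2, flat_partition(panel, n_blocks=2))

    def test_unrelated_pair_matches_2pq_oracle(self):
        # distance between unrelated pseudohaploids ~ mean 2p(1-p)
        cfg = SimulationConfig(
            n_snps=20_000,
            pop_specs=(PopSpec("P", 0.0, 2),),
            pair_spec=PairSpec("P", mean_depth=10.0),
            seed=17,
        )
        panel, _, pu1, pu2, truth = simulate_all(cfg)
        rng = np.random.default_rng(3)
        g1 = call_pseudohaploid(pu1, panel, rng=rng)
        g2 = call_pseudohaploid(pu2, panel, rng=rng)
        part = block_partition(panel, np.arange(len(panel)), n_blocks=50)
        res = mismatch_distance(g1, g2, part)
        p = truth.pop_freqs["P"]
        assert res.estimate == pytest.approx(np.mean(2 * p * (1 - p)), abs=0.01)


class TestKinshipTest:
    def test_unrelated_ratio_two(self):
        res, _ = run_pair("unrelated", seed=1)
        assert res.ratio == pytest.approx(2.0, abs=0.1)
        assert res.classification == "unrelated"

    def test_identical_ratio_one(self):
        res, _ = run_pair("identical", seed=2)
        assert res.ratio == pytest.approx(1.0, abs=0.1)
        assert res.classification == "identical"

    def test_parent_offspring_ratio(self):
        res, _ = run_pair("parent_offspring", seed=3)
        assert res.ratio == pytest.approx(1.5, abs=0.1)
        assert res.classification == "first_degree"

    def test_ratio_recovers_two_one_minus_theta(self):
        # property: 2(1-theta) within 2 jackknife SEs for each class
        for rel in ("unrelated", "parent_offspring", "full_sib", "identical"):
            res, truth = run_pair(rel, seed=11)
            expected = 2 * (1 - truth.kinship_theta)
            assert abs(res.ratio - expected) <= max(2 * res.se_ratio, 0.05)

    def test_zero_within_distance_indeterminate(self):
        panel = make_panel([("A", "C")] * 8)
        from paleopair.pseudohaploid import PseudoTwinPair

        pair_i = PseudoTwinPair("i", genome([0] * 8), genome([0] * 8))
        pair_j = PseudoTwinPair("j", genome([1] * 8), genome([1] * 8))
        res = kinship_test(
            pair_i, pair_j, genome([0] * 8), genome([1] * 8), flat_partition(panel)
        )
        assert res.classification == "indeterminate"

    def test_expected_ratio_table(self):
        assert EXPECTED_RATIOS == {
            "identical": 1.0,
            "first_degree": 1.5,
            "unrelated": 2.0,
        }


class TestCnd:
    def cnd_setup(self, pair_drift, seed, n_snps=10_000):
        cfg = SimulationConfig(
            n_snps=n_snps,
            pop_specs=(PopSpec("REF", 0.02, 20), PopSpec("P", pair_drift, 2)),
            pair_spec=PairSpec("P", mean_depth=5.0),
            seed=seed,
        )
        panel, geno, pu1, pu2, _ = simulate_all(cfg)
        rng = np.random.default_rng(seed + 1)
        g1 = call_pseudohaploid(pu1, panel, rng=rng)
        g2 = call_pseudohaploid(pu2, panel, rng=rng)
        part = block_partition(panel, np.arange(len(panel)), n_blocks=20)
        return g1, g2, panel, geno, part

    def test_identical_genomes_zero(self):
        g1, _, panel, geno, part = self.cnd_setup(0.05, seed=4)
        res = conditional_nucleotide_diversity(g1, g1, panel, geno, part)
        assert res.cnd == 0.0

    def test_ascertainment_excludes_transitions(self):
        g1, g2, panel, geno, part = self.cnd_setup(0.05, seed=5)
        res = conditional_nucleotide_diversity(g1, g2, panel, geno, part)
        # masking transitions on top changes nothing: already excluded
        from paleopair.io import MISSING as MISS

        m1 = PseudohaploidGenome(
            g1.individual_id,
            np.where(panel.is_transition, MISS, g1.calls).astype(np.int8),
        )
        m2 = PseudohaploidGenome(
            g2.individual_id,
            np.where(panel.is_transition, MISS, g2.calls).astype(np.int8),
        )
        res_masked = conditional_nucleotide_diversity(m1, m2, panel, geno, part)
        assert res.cnd == res_masked.cnd
        assert res.n_sites == res_masked.n_sites

    def test_permutation_invariance(self):
        g1, g2, panel, geno, part = self.cnd_setup(0.05, seed=6)
        a = conditional_nucleotide_diversity(g1, g2, panel, geno, part)
        b = conditional_nucleotide_diversity(g2, g1, panel, geno, part)
        assert a.cnd == b.cnd

    def test_drift_reduces_diversity(self):
        # higher drift in the pair's population -> lower CND (on average)
        low = np.mean(
            [
                conditional_nucleotide_diversity(
                    *self.cnd_setup(0.01, seed=s)
                ).cnd
                for s in range(5)
            ]
        )
        high = np.mean(
            [
                conditional_nucleotide_diversity(
                    *self.cnd_setup(0.20, seed=s)
                ).cnd
                for s in range(5)
            ]
        )
        assert high < low

    def test_empty_ascertainment_raises(self):
        panel = make_panel([("C", "T")] * 4)  # transitions only
        geno = make_geno(panel, [("a", "R"), ("b", "R")], np.ones((4, 2)))
        part = block_partition(panel, np.arange(4), n_blocks=2)
        g = genome([0, 1, 0, 1])
        with pytest.raises(ValueError, match="empty"):
            conditional_nucleotide_diversity(g, g, panel, geno, part)
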