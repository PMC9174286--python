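import numpy as np
import pytest

from paleopair.fstats import FreqTable, allele_frequencies
from paleopair.jackknife import block_partition
from paleopair.qpadm import f4_system, fit_qpadm, nested_model_search
from paleopair.simulate import AdmixtureSpec, PopSpec, SimulationConfig, simulate_all

from conftest import make_panel


def table(**pops):
    freqs = {k: np.asarray(v, dtype=float) for k, v in pops.items()}
    counts = {k: np.full(len(v), 20, dtype=np.int64) for k, v in pops.items()}
    return FreqTable(freqs=freqs, counts=counts)


def flat_partition(n, n_blocks=10):
    panel = make_panel([("A", "C")] * n)
    return block_partition(panel, np.arange(n), n_blocks=n_blocks)


def random_table(rng, n, labels):
    return table(**{lab: rng.random(n) for lab in labels})


RIGHTS = ["R1", "R2", "R3", "R4", "R5", "R6"]


def informative_config(seed, n_snps=50_000, alpha=(0.6, 0.4), target_n=20):
    """Sources plus rights differentially related to them (drifted copies)."""
    return SimulationConfig(
        n_snps=n_snps,
        pop_specs=(
            PopSpec("S1", 0.05, 20),
            PopSpec("S2", 0.05, 20),
            PopSpec("R1", 0.30, 15),
            PopSpec("R4", 0.10, 15),
            PopSpec("R5", 0.15, 15),
            PopSpec("R6", 0.20, 15),
        ),
        admixture_specs=(
            AdmixtureSpec("R2", ("S1",), (1.0,), drift=0.08, n_individuals=15),
            AdmixtureSpec("R3", ("S2",), (1.0,), drift=0.08, n_individuals=15),
            AdmixtureSpec("T", ("S1", "S2"), alpha, drift=0.01, n_individuals=target_n),
        ),
        seed=seed,
    )


def fit_replicate(seed, **cfg_kw):
    cfg = informative_config(seed, **cfg_kw)
    panel, geno, _, _, truth = simulate_all(cfg)
    freqs = allele_frequencies(geno)
    part = block_partition(panel, np.arange(len(panel)), n_blocks=50)
    return fit_qpadm("T", ["S1", "S2"], RIGHTS, freqs, part), truth, freqs, part


class TestF4System:
    def test_target_equals_source_gives_matching_column(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        ft = table(
            T=p, S1=p, S2=rng.random(100),
            R1=rng.random(100), R2=rng.random(100), R3=rng.random(100),
        )
        sys_ = f4_system("T", ["S1", "S2"], ["R1", "R2", "R3"], ft, flat_partition(100))
        np.testing.assert_allclose(sys_.y(), sys_.x()[:, 0])

    def test_single_source_single_column(self):
        rng = np.random.default_rng(1)
        ft = random_table(rng, 50, ["T", "S1", "R1", "R2", "R3"])
        sys_ = f4_system("T", ["S1"], ["R1", "R2", "R3"], ft, flat_partition(50, 5))
        assert sys_.x().shape == (2, 1)

    def test_exact_mixture_linearity(self):
        # T = 0.5 S1 + 0.5 S2 site-wise -> y = 0.5 X1 + 0.5 X2
        rng = np.random.default_rng(2)
        s1, s2 = rng.random(80), rng.random(80)
        ft = table(
            T=0.5 * s1 + 0.5 * s2, S1=s1, S2=s2,
            R1=rng.random(80), R2=rng.random(80), R3=rng.random(80),
        )
        sys_ = f4_system("T", ["S1", "S2"], ["R1", "R2", "R3"], ft, flat_partition(80, 8))
        np.testing.assert_allclose(
            sys_.y(), 0.5 * sys_.x()[:, 0] + 0.5 * sys_.x()[:, 1], atol=1e-14
        )

    def test_insufficient_rights(self):
        rng = np.random.default_rng(3)
        ft = random_table(rng, 20, ["T", "S1", "S2", "R1", "R2"])
        with pytest.raises(ValueError, match="k\\+1"):
            f4_system("T", ["S1", "S2"], ["R1", "R2"], ft, flat_partition(20, 2))


class TestFitQpadm:
    def test_target_identical_to_source_exact_fit(self):
        rng = np.random.default_rng(4)
        p = rng.random(200)
        ft = table(
            T=p, S1=p,
            R1=rng.random(200), R2=rng.random(200), R3=rng.random(200),
        )
        m = fit_qpadm("T", ["S1"], ["R1", "R2", "R3"], ft, flat_partition(200, 20))
        np.testing.assert_allclose(m.weights, [1.0])
        assert m.p_value == pytest.approx(1.0, abs=1e-9)
        assert m.feasible

    def test_weights_sum_to_one_exactly(self):
        m, _, _, _ = fit_replicate(seed=0, n_snps=10_000)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_negative_weight_flags_infeasible(self):
        # truth alpha=(1, 0): the noisy S2 weight goes negative in some
        # replicates; scan seeds for one and check the flag convention
        # (point-estimate sign only, as in the published flagging where
        # -0.032 +/- 0.020 is infeasible despite the small weight)
        found = False
        for seed in range(10):
            m, _, _, _ = fit_replicate(seed=seed, n_snps=5_000, alpha=(1.0, 0.0))
            assert m.feasible == bool(np.all(m.weights >= 0))
            if np.any(m.weights < 0):
                found = True
                assert not m.feasible
                break
        assert found, "no replicate produced a negative weight"

    def test_parameter_recovery_single_replicate(self):
        m, truth, _, _ = fit_replicate(seed=1)
        alpha = truth.admixture_weights["T"]
        assert m.weights[0] == pytest.approx(alpha["S1"], abs=3 * m.se[0] + 0.01)
        assert m.weights[1] == pytest.approx(alpha["S2"], abs=3 * m.se[1] + 0.01)
        assert m.feasible

    def test_rights_reorder_invariance_beyond_pivot(self):
        m, _, freqs, part = fit_replicate(seed=2, n_snps=10_000)
        shuffled = ["R1", "R4", "R2", "R6", "R3", "R5"]
        m2 = fit_qpadm("T", ["S1", "S2"], shuffled, freqs, part)
        np.testing.assert_allclose(m.weights, m2.weights, atol=1e-8)
        assert m.p_value == pytest.approx(m2.p_value, abs=1e-8)

    def test_dof_accounting(self):
        m, _, _, _ = fit_replicate(seed=3, n_snps=5_000)
        assert m.dof == len(RIGHTS) - 2

    def test_summary_mentions_infeasible(self):
        m, _, _, _ = fit_replicate(seed=0, n_snps=5_000)
        text = m.summary()
        assert "p=" in text
        assert ("infeasible" in text) == (not m.feasible)


class TestNestedSearch:
    def test_enumeration_k2(self):
        _, _, freqs, part = fit_replicate(seed=5, n_snps=5_000)
        models = nested_model_search("T", ["S1", "S2"], RIGHTS, freqs, part)
        assert len(models) == 3
        assert [len(m.sources) for m in models] == [1, 1, 2]

    def test_single_source_truth_accepts_nested(self):
        # truth uses only S1: the {S1} nested model should fit
        cfg = informative_config(6, n_snps=50_000, alpha=(1.0, 0.0))
        panel, geno, _, _, _ = simulate_all(cfg)
        freqs = allele_frequencies(geno)
        part = block_partition(panel, np.arange(len(panel)), n_blocks=50)
        models = nested_model_search("T", ["S1", "S2"], RIGHTS, freqs, part)
        only_s1 = next(m for m in models if m.sources == ("S1",))
        assert only_s1.p_value > 0.05
        assert only_s1.feasible

    def test_omitting_major_source_rejected(self):
        # dropping a 40% source must blow up the fit
        cfg = informative_config(7, n_snps=50_000)
        panel, geno, _, _, _ = simulate_all(cfg)
        freqs = allele_frequencies(geno)
        part = block_partition(panel, np.arange(len(panel)), n_blocks=50)
        models = nested_model_search("T", ["S1", "S2"], RIGHTS, freqs, part)
        only_s1 = next(m for m in models if m.sources == ("S1",))
        assert only_s1.p_value < 0.05

    def test_needs_two_sources(self):
        _, _, freqs, part = fit_replicate(seed=8, n_snps=5_000)
        with pytest.raises(ValueError, match="at least 2"):
            nested_model_search("T", ["S1"], RIGHTS, freqs, part)
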