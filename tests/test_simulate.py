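import numpy as np
import pytest

from icnet.prep import AbundanceTable
from icnet.simulate import (
    ObservationConfig,
    SimulationConfig,
    SyntheticTruth,
    UnstableParameterization,
    coupled_logistic_network,
    observe_reads,
    simulate_community,
)
from tests.conftest import make_ricker_truth


def make_config(**kw):
    defaults = dict(
        n_species=2,
        n_steps=60,
        interaction_matrix=np.array([[0.8, 0.0], [0.0, 0.9]]),
        growth_rates=np.array([0.8, 0.9]),
        process_noise_sd=0.0,
        temperature_sensitivity=np.zeros(2),
        seed=1,
        initial_abundance=np.array([0.5, 0.6]),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateCommunity:
    def test_uncoupled_species_follow_1d_ricker_map(self):
        """With a diagonal A each species is an independent 1-D Ricker map
        x(t+1) = x exp(r - a x), and the Jacobian diagonal equals the
        closed form (1 - a x) exp(r - a x)."""
        a, r, x0 = 0.8, 0.8, 0.5
        truth = simulate_community(make_config())
        x = truth.abundances.values[0, :, 0]
        expected = [x0]
        for _ in range(59):
            expected.append(expected[-1] * np.exp(r - a * expected[-1]))
        np.testing.assert_allclose(x, expected, rtol=1e-12)
        J = truth.jacobians[0, :, 0, 0]
        closed = (1 - a * x[:-1]) * np.exp(r - a * x[:-1])
        np.testing.assert_allclose(J, closed, rtol=1e-12)

    def test_links_are_offdiagonal_support_of_A(self):
        A = np.array([[0.8, 0.0], [0.4, 0.9]])  # species 0 drives species 1
        truth = simulate_community(make_config(interaction_matrix=A))
        assert truth.links == {(0, 1)}

    def test_same_seed_reproduces_trajectory_bitwise(self):
        t1 = make_ricker_truth(seed=42)
        t2 = make_ricker_truth(seed=42)
        assert np.array_equal(t1.abundances.values, t2.abundances.values)
        assert np.array_equal(t1.jacobians, t2.jacobians)

    def test_analytic_jacobian_matches_finite_differences(self):
        """Random states: analytic J agrees with central differences of
        the update map to relative error < 1e-6."""
        rng = np.random.default_rng(0)
        A = np.array([[0.9, 0.3, -0.1], [0.2, 0.8, 0.1], [0.0, -0.2, 1.0]])
        r = np.array([1.0, 1.1, 0.9])
        from icnet.simulate import _ricker_jacobian

        f = lambda z: z * np.exp(r - A @ z)
        for _ in range(50):
            x = rng.uniform(0.2, 2.0, 3)
            J = _ricker_jacobian(x, r, A, 0.0, np.zeros(3))
            Jfd = np.empty((3, 3))
            eps = 1e-6
            for j in range(3):
                dx = np.zeros(3)
                dx[j] = eps
                Jfd[:, j] = (f(x + dx) - f(x - dx)) / (2 * eps)
            assert np.abs(J - Jfd).max() / np.abs(J).max() < 1e-6

    def test_extinct_species_stay_extinct(self):
        cfg = make_config(
            growth_rates=np.array([-5.0, 0.9]), process_noise_sd=0.0
        )
        truth = simulate_community(cfg)
        x = truth.abundances.values[0, :, 0]
        first_zero = np.argmax(x == 0)
        assert x[first_zero:].max() == 0.0

    def test_divergence_raises_named_step(self):
        cfg = make_config(
            interaction_matrix=np.zeros((2, 2)),
            growth_rates=np.array([10.0, 10.0]),
        )
        with pytest.raises(UnstableParameterization, match="step"):
            simulate_community(cfg)

    def test_trajectories_finite(self, ricker_truth):
        assert np.isfinite(ricker_truth.abundances.values).all()

    @pytest.mark.parametrize("bad", [
        dict(n_species=1),
        dict(n_steps=10),
        dict(process_noise_sd=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            make_config(**{k: v for k, v in bad.items()},
                        **({"interaction_matrix": np.array([[0.5]]),
                            "growth_rates": np.array([0.5]),
                            "temperature_sensitivity": np.zeros(1),
                            "initial_abundance": np.array([0.5])}
                           if bad.get("n_species") == 1 else {}))

    def test_negative_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            make_config(interaction_matrix=np.array([[-0.5, 0], [0, 0.9]]))


class TestObserveReads:
    def test_full_design_yields_1220_sample_rows(self):
        """5 plots x 122 days x 2 filter types = 1220 sequencing samples."""
        cfg = SimulationConfig(
            n_species=3,
            n_steps=122,
            n_plots=5,
            interaction_matrix=np.diag([0.8, 0.9, 1.0]),
            growth_rates=np.array([0.8, 0.9, 1.0]),
            process_noise_sd=0.05,
            temperature_sensitivity=np.zeros(3),
            seed=2,
        )
        truth = simulate_community(cfg)
        _, _, meta = observe_reads(truth, cfg.observation, seed=2)
        assert len(meta) == 1220

    def test_standard_reads_proportional_in_noise_free_limit(self):
        """Standards {10,100,1000} with slope 2 and no noise give reads
        exactly {20,200,2000}."""
        truth = make_ricker_truth(n_steps=50, noise_sd=0.0)
        obs = ObservationConfig(
            standards=[("s1", 10.0), ("s2", 100.0), ("s3", 1000.0)],
            efficiency_slope=2.0,
            efficiency_cv_across_samples=0.0,
            sampling="expected",
            n_filter_types=1,
        )
        _, std_reads, _ = observe_reads(truth, obs, seed=0)
        np.testing.assert_allclose(std_reads.iloc[:, 0], [20, 200, 2000])

    def test_taxon_reads_proportional_to_copies_per_sample(self):
        truth = make_ricker_truth(n_steps=50, noise_sd=0.0)
        obs = ObservationConfig(
            efficiency_cv_across_samples=0.5, sampling="expected",
            n_filter_types=1,
        )
        reads, _, meta = observe_reads(truth, obs, seed=3)
        copies = truth.abundances.values[:, :, 0]
        ratios = reads.values / copies
        # slope varies by sample but is shared within each sample
        np.testing.assert_allclose(ratios[0], ratios[1], rtol=1e-12)

    def test_multinomial_reads_are_counts_summing_to_depth(self):
        truth = make_ricker_truth(n_steps=50, noise_sd=0.0)
        obs = ObservationConfig(read_depth_mean=5000, n_filter_types=2)
        reads, std_reads, meta = observe_reads(truth, obs, seed=4)
        total = reads.values.sum(axis=0) + std_reads.values.sum(axis=0)
        assert (reads.values >= 0).all()
        assert reads.values.dtype.kind in "iu" or np.allclose(
            reads.values, np.round(reads.values)
        )
        np.testing.assert_array_equal(total, meta["depth"].values)

    def test_same_seed_reproduces_read_tables(self):
        truth = make_ricker_truth(n_steps=50)
        obs = ObservationConfig(read_depth_mean=2000)
        r1, s1, m1 = observe_reads(truth, obs, seed=9)
        r2, s2, m2 = observe_reads(truth, obs, seed=9)
        assert r1.equals(r2) and s1.equals(s2) and m1.equals(m2)

    def test_too_few_standard_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            ObservationConfig(standards=[("a", 10.0), ("b", 10.0)])


class TestCoupledLogisticNetwork:
    def test_network_returns_table_with_known_support(self):
        C = np.zeros((3, 3))
        C[1, 0] = 0.3  # species 0 drives species 1
        table = coupled_logistic_network(C, n_steps=200, seed=0)
        assert isinstance(table, AbundanceTable)
        assert table.values.shape == (3, 200, 1)
        assert np.isfinite(table.values).all()
        assert (table.values > 0).all()
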