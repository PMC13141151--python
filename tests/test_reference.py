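"""Reference solvers: network derivation, exact SSA, tau-leaping,
Haseltine-Rawlings, ODE."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp, poisson

import odehybrid as oh
from odehybrid.model import OdeModel
from odehybrid.zoo import build_birth_death_chain


class TestNetworkFromDecomposition:
    def test_benchmark_channels(self, benchmark_model, benchmark_network):
        net = benchmark_network
        assert net.n_channels == 2 * benchmark_model.n_species
        x = np.array([2.0, 7.0])
        # interleaved (birth, death) per species: (5, d1*M, k2*M, d2*P)
        np.testing.assert_allclose(net.propensities(x, 0.0), [5.0, 2.0, 100.0, 0.7])
        stoich = net.stoich_matrix()
        np.testing.assert_array_equal(stoich,
                                      [[1, 0], [-1, 0], [0, 1], [0, -1]])

    def test_zero_drift_network_is_silent(self):
        m = OdeModel(species=["a", "b"], parameters={},
                     drift=lambda x, t: np.zeros(2), initial_state=[3.0, 4.0])
        net = oh.network_from_decomposition(m)
        assert np.all(net.propensities(np.array([3.0, 4.0]), 0.0) == 0.0)
        traj = oh.ssa_direct(net, 10.0, seed=0)
        assert np.all(traj.states == [3.0, 4.0])


class TestSsaDirect:
    def test_immigration_death_stationary_poisson(self, immigration_death_model):
        net = oh.network_from_decomposition(immigration_death_model)
        grid = oh.uniform_grid(5050.0, 1.0)
        traj = oh.ssa_direct(net, 5050.0, seed=2024, t_grid=grid)
        x = traj.states[grid >= 50.0, 0]
        assert x.mean() == pytest.approx(5.0, abs=0.3)
        assert x.var() == pytest.approx(5.0, rel=0.15)
        assert np.mean(x == 0) == pytest.approx(np.exp(-5.0), abs=0.006)

    def test_stationary_histogram_passes_chi_square_vs_poisson(
            self, immigration_death_model):
        net = oh.network_from_decomposition(immigration_death_model)
        grid = oh.uniform_grid(5050.0, 1.0)
        traj = oh.ssa_direct(net, 5050.0, seed=77, t_grid=grid)
        x = traj.states[grid >= 50.0, 0].astype(int)
        # bin counts 0..11 with a pooled tail; expected from Poisson(5)
        edges = np.arange(13)
        obs = np.array([np.sum(x == v) for v in edges[:-1]] + [np.sum(x >= 12)])
        pmf = poisson.pmf(edges[:-1], 5.0)
        exp = np.append(pmf, 1.0 - pmf.sum()) * len(x)
        assert chisquare(obs, exp).pvalue > 0.01

    def test_pure_death_ensemble_mean(self):
        model = OdeModel(species=["x"], parameters={}, drift=lambda x, t: -x,
                         initial_state=[10.0])
        net = oh.network_from_decomposition(model)
        grid = np.array([0.0, np.log(2.0)])
        finals = [oh.ssa_direct(net, float(np.log(2.0)) + 1e-9, seed=s,
                                t_grid=grid).states[-1, 0]
                  for s in range(1000)]
        # binomial thinning: mean n0 e^{-t} = 5, var = 10*0.5*0.5 = 2.5
        se = np.sqrt(2.5 / 1000)
        assert abs(np.mean(finals) - 5.0) < 3 * se

    def test_reproducible_and_seed_sensitive(self, benchmark_network):
        t1 = oh.ssa_direct(benchmark_network, 20.0, seed=5)
        t2 = oh.ssa_direct(benchmark_network, 20.0, seed=5)
        t3 = oh.ssa_direct(benchmark_network, 20.0, seed=6)
        np.testing.assert_array_equal(t1.states, t2.states)
        assert not np.array_equal(t1.states, t3.states)


class TestTauLeap:
    def test_pure_immigration_is_exact(self):
        """Constant propensity: total count at T is exactly Poisson(k*T),
        independent of the leap size."""
        model = OdeModel(species=["x"], parameters={},
                         drift=lambda x, t: np.full(1, 5.0), initial_state=[0.0])
        net = oh.network_from_decomposition(model)
        grid = np.array([0.0, 10.0])
        finals = np.array([oh.tau_leap(net, 10.0, 10.0, seed=s,
                                       t_grid=grid).states[-1, 0]
                           for s in range(300)])
        assert finals.mean() == pytest.approx(50.0, abs=3 * np.sqrt(50.0 / 300))
        assert finals.var() == pytest.approx(50.0, rel=0.25)

    def test_negativity_triggers_halving_not_negative_counts(self):
        model = OdeModel(species=["x"], parameters={},
                         drift=lambda x, t: -10.0 * x, initial_state=[3.0])
        net = oh.network_from_decomposition(model)
        traj = oh.tau_leap(net, 1.0, 5.0, seed=4, t_grid=oh.uniform_grid(5.0, 0.5))
        assert traj.states.min() >= 0.0

    def test_stationary_mean_bias_shrinks_with_tau(self, benchmark_network):
        biases = []
        for tau, seed in ((0.5, 10), (0.1, 11), (0.01, 12)):
            traj = oh.tau_leap(benchmark_network, tau, 1000.0, seed=seed)
            s = oh.stationary_stats(traj, 50.0)
            biases.append(abs(s.mean[0] - 5.0))
        # convergence within Monte-Carlo noise (~0.1 on the mean of M)
        assert biases[2] <= biases[0] + 0.3

    def test_reproducible_given_seed(self, benchmark_network):
        a = oh.tau_leap(benchmark_network, 0.1, 20.0, seed=8)
        b = oh.tau_leap(benchmark_network, 0.1, 20.0, seed=8)
        np.testing.assert_array_equal(a.states, b.states)


class TestHrHybrid:
    def test_all_fast_equals_ode(self, benchmark_network, benchmark_model):
        part = oh.ChannelPartition(slow=[], fast=[0, 1, 2, 3])
        grid = oh.uniform_grid(100.0, 1.0)
        hr = oh.hr_hybrid(benchmark_network, part, 100.0, seed=1,
                          rtol=1e-8, atol=1e-10, t_grid=grid)
        ode = oh.ode_solve(benchmark_model, 100.0, rtol=1e-8, atol=1e-10,
                           t_grid=grid)
        assert np.abs(hr.states - ode.states).max() < 1e-4 * np.abs(ode.states).max()

    def test_all_slow_matches_ssa_in_distribution(self, immigration_death_model):
        """Integrated-hazard jump times are exact, so the all-slow HR run and
        the direct SSA agree in stationary distribution (two-sample KS)."""
        net = oh.network_from_decomposition(immigration_death_model)
        grid = oh.uniform_grid(4050.0, 2.0)
        ssa = oh.ssa_direct(net, 4050.0, seed=11, t_grid=grid)
        hr = oh.hr_hybrid(net, oh.ChannelPartition(slow=[0, 1], fast=[]),
                          4050.0, seed=33, t_grid=grid)
        a = ssa.states[grid >= 50.0, 0]
        b = hr.states[grid >= 50.0, 0]
        assert ks_2samp(a, b).statistic < 0.05

    def test_invalid_partition_rejected(self, benchmark_network):
        with pytest.raises(ValueError, match="partition"):
            oh.hr_hybrid(benchmark_network, oh.ChannelPartition(slow=[0], fast=[0]),
                         10.0, seed=0)

    def test_partition_from_species_labels(self, benchmark_network):
        part = oh.ChannelPartition.from_species_labels(
            benchmark_network, {"M": 1, "P": 0})
        assert part.slow == [0, 1]   # mRNA birth and death channels
        assert part.fast == [2, 3]   # protein channels

    def test_reproducible_given_seed(self, benchmark_network):
        part = oh.ChannelPartition.from_species_labels(
            benchmark_network, {"M": 1, "P": 0})
        a = oh.hr_hybrid(benchmark_network, part, 30.0, seed=21)
        b = oh.hr_hybrid(benchmark_network, part, 30.0, seed=21)
        np.testing.assert_array_equal(a.states, b.states)


class TestOdeSolve:
    def test_linear_decay_closed_form(self):
        m = OdeModel(species=["x"], parameters={}, drift=lambda x, t: -2.0 * x,
                     initial_state=[7.0])
        traj = oh.ode_solve(m, 2.0, rtol=1e-10, atol=1e-12,
                            t_grid=np.linspace(0.0, 2.0, 21))
        np.testing.assert_allclose(traj.states[:, 0],
                                   7.0 * np.exp(-2.0 * traj.times), rtol=1e-6)

    def test_network_rate_equation(self, benchmark_network):
        traj = oh.ode_solve(benchmark_network, 200.0, t_grid=oh.uniform_grid(200.0, 1.0))
        np.testing.assert_allclose(traj.states[-1], [5.0, 2500.0], rtol=1e-3)

    def test_zero_drift_constant(self):
        m = OdeModel(species=["x"], parameters={}, drift=lambda x, t: np.zeros(1),
                     initial_state=[4.0])
        traj = oh.ode_solve(m, 5.0)
        assert np.all(traj.states == 4.0)


class TestHybridVsSsaStochasticLimit:
    def test_all_stochastic_hybrid_matches_ssa_distribution(
            self, immigration_death_model):
        net = oh.network_from_decomposition(immigration_death_model)
        grid = oh.uniform_grid(4050.0, 2.0)
        ssa = oh.ssa_direct(net, 4050.0, seed=11, t_grid=grid)
        system = oh.build_hybrid_system(immigration_death_model, {"X1": 1}, dt=0.1)
        hyb = oh.simulate_hybrid(system, 4050.0, seed=22, t_grid=grid)
        a = ssa.states[grid >= 50.0, 0]
        b = hyb.states[grid >= 50.0, 0]
        assert ks_2samp(a, b).statistic < 0.05
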