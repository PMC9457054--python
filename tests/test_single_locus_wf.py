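"""Exact single-locus Wright-Fisher engine: matrices, propagation,
stationarity, experiments and the accumulation bound."""

import numpy as np
import pytest
from scipy import stats

from evoinfo import (
    WFModel,
    absorption_probability,
    accumulation_experiment,
    fixation_experiment,
    genotype_marginal,
    information_levels,
    kimura_fixation_probability,
    maintenance_scan,
    propagate,
    state_costs,
    stationary_distribution,
    transition_matrix,
)


class TestTransitionMatrix:
    def test_pure_drift_rows_are_binomial(self):
        model = WFModel(N=10, mu=0.0, s=0.0)
        M = transition_matrix(model)
        for i in range(11):
            np.testing.assert_allclose(
                M[i], stats.binom.pmf(np.arange(11), 10, i / 10), atol=1e-14)
        # boundaries absorbing
        assert M[0, 0] == 1.0 and M[10, 10] == 1.0

    @pytest.mark.parametrize("N,mu,s", [(5, 0.01, 0.1), (40, 0.005, 0.05),
                                        (100, 1e-4, 0.2)])
    def test_rows_stochastic(self, N, mu, s):
        for selected in (True, False):
            M = transition_matrix(WFModel(N=N, mu=mu, s=s), selected=selected)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_selection_then_sampling_hand_value(self):
        """N=2, mu=0, w_A=2: from one copy, p_sel = 2/3 and the next-count
        distribution is Binomial(2, 2/3)."""
        M = transition_matrix(WFModel(N=2, mu=0.0, s=1.0))
        np.testing.assert_allclose(M[1], [1 / 9, 4 / 9, 4 / 9], atol=1e-14)

    def test_neutral_flag_ignores_fitness_rule(self):
        model = WFModel(N=10, mu=0.01, fitness_rule=lambda x: (1.0, 5.0))
        np.testing.assert_allclose(
            transition_matrix(model, selected=False),
            transition_matrix(WFModel(N=10, mu=0.01, s=0.0), selected=True),
            atol=1e-14)


class TestPropagation:
    def test_neutral_selection_coincides(self):
        model = WFModel(N=20, mu=0.01, s=0.0)
        init = np.zeros(21)
        init[3] = 1.0
        psi, phi = propagate(model, init, 50)
        np.testing.assert_allclose(psi, phi, atol=1e-14)
        D_X, D_G = information_levels(psi[-1], phi[-1], 20)
        assert D_X == pytest.approx(0.0, abs=1e-12)

    def test_absorption_mass_matches_linear_solve(self):
        """Long propagation without mutation concentrates mass on {0, N} with
        the fixation share given by the absorption linear solve."""
        model = WFModel(N=30, mu=0.0, s=0.05)
        init = np.zeros(31)
        init[1] = 1.0
        psi, _ = propagate(model, init, 3000)
        final = psi[-1]
        assert final[1:-1].sum() < 1e-10
        assert final[-1] == pytest.approx(
            absorption_probability(model, 1), abs=1e-8)

    def test_propagate_matches_monte_carlo(self):
        """Seeded Monte-Carlo of the same chain reproduces the propagated
        marginal within binomial sampling error."""
        N, mu, s, T, reps = 40, 0.005, 0.05, 20, 100_000
        model = WFModel(N=N, mu=mu, s=s)
        init = np.zeros(N + 1)
        init[N // 2] = 1.0
        psi, _ = propagate(model, init, T)
        rng = np.random.default_rng(12345)
        counts = np.full(reps, N // 2)
        for _ in range(T):
            x = counts / N
            p_sel = x * (1 + s) / (x * (1 + s) + (1 - x))
            p = p_sel * (1 - mu) + (1 - p_sel) * mu
            counts = rng.binomial(N, p)
        hist = np.bincount(counts, minlength=N + 1) / reps
        # each bin within ~4.5 SDs of its binomial sampling error
        sd = np.sqrt(np.maximum(psi[T] * (1 - psi[T]) / reps, 1e-12))
        assert np.all(np.abs(hist - psi[T]) < 4.5 * sd + 5e-5)


class TestStationary:
    def test_neutral_symmetry(self):
        v = stationary_distribution(WFModel(N=30, mu=0.002, s=0.0),
                                    selected=False)
        np.testing.assert_allclose(v, v[::-1], atol=1e-10)

    def test_fixed_point_property(self):
        model = WFModel(N=25, mu=0.01, s=0.08)
        M = transition_matrix(model)
        v = stationary_distribution(model)
        np.testing.assert_allclose(v @ M, v, atol=1e-10)

    def test_direct_and_power_methods_agree(self):
        model = WFModel(N=40, mu=0.005, s=0.05)
        direct = stationary_distribution(model, method="direct")
        power = stationary_distribution(model, method="power")
        np.testing.assert_allclose(direct, power, atol=1e-10)

    def test_neutral_zero_information(self):
        model = WFModel(N=100, mu=0.001, s=0.0)
        psi = stationary_distribution(model, selected=True)
        phi = stationary_distribution(model, selected=False)
        D_X, D_G = information_levels(psi, phi, 100)
        assert D_X == pytest.approx(0.0, abs=1e-10)

    def test_mu_zero_raises(self):
        with pytest.raises(ValueError, match="absorption"):
            stationary_distribution(WFModel(N=10, mu=0.0, s=0.1))


class TestGenotypeMarginal:
    def test_point_masses_and_symmetry(self):
        N = 12
        fixed = np.zeros(N + 1)
        fixed[N] = 1.0
        assert genotype_marginal(fixed, N).prob("A") == pytest.approx(1.0)
        uniform = np.full(N + 1, 1 / (N + 1))
        assert genotype_marginal(uniform, N).prob("A") == pytest.approx(0.5)
        neutral = stationary_distribution(WFModel(N=N, mu=0.01, s=0.0),
                                          selected=False)
        assert genotype_marginal(neutral, N).prob("A") == pytest.approx(
            0.5, abs=1e-10)

    def test_point_mass_vs_neutral_stationary_levels(self):
        """psi concentrated at fixation: D_X = -log2 phi(N), D_G follows from
        the genotype marginals directly."""
        from evoinfo import PairedEnsemble, kl_divergence

        N = 20
        model = WFModel(N=N, mu=0.01, s=0.0)
        phi = stationary_distribution(model, selected=False)
        psi = np.zeros(N + 1)
        psi[N] = 1.0
        D_X, D_G = information_levels(psi, phi, N)
        assert D_X == pytest.approx(-np.log2(phi[N]), abs=1e-12)
        pair = PairedEnsemble(genotype_marginal(psi, N),
                              genotype_marginal(phi, N))
        assert D_G == pytest.approx(kl_divergence(pair), abs=1e-12)


class TestFixationExperiment:
    def test_neutral_case(self):
        run = fixation_experiment(N=30, s=0.0)
        assert run.extras["psi_fix"] == pytest.approx(1 / 30, abs=1e-9)
        assert run.extras["D_X_inf"] == pytest.approx(0.0, abs=1e-9)
        assert run.extras["total_cost"] == 0.0

    def test_fixation_probability_matches_linear_solve(self):
        run = fixation_experiment(N=100, s=0.01)
        assert run.extras["psi_fix"] == pytest.approx(
            run.extras["psi_fix_exact"], abs=1e-8)

    @pytest.mark.parametrize("Ns", [1.0, 2.0, 3.0])
    def test_fixation_probability_near_diffusion_value(self, Ns):
        N = 100
        run = fixation_experiment(N=N, s=Ns / N)
        assert run.extras["psi_fix"] == pytest.approx(
            kimura_fixation_probability(N, Ns / N), rel=0.02)

    def test_cumulative_cost_bounds_final_information(self):
        run = fixation_experiment(N=100, s=0.02)
        assert run.extras["total_cost"] >= run.extras["D_X_inf"] / 100

    def test_series_invariants(self):
        run = fixation_experiment(N=50, s=0.04)
        assert np.all(np.diff(run.cost_cum) >= -1e-15)
        assert np.all(run.D_X >= run.D_G - 1e-9)
        assert run.max_bound_violation() <= 1e-9


class TestAccumulationExperiment:
    def test_neutral_all_zero(self):
        model = WFModel(N=30, mu=0.01, s=0.0)
        run = accumulation_experiment(model, 100)
        np.testing.assert_allclose(run.D_X, 0.0, atol=1e-10)
        np.testing.assert_allclose(run.cost_rate, 0.0, atol=1e-12)

    def test_converges_to_independent_stationary_solve(self):
        """After saturation the propagated information matches the directly
        solved stationary distributions."""
        model = WFModel(N=50, mu=0.01, s=0.02)
        run = accumulation_experiment(model, 3000)
        psi = stationary_distribution(model, selected=True)
        phi = stationary_distribution(model, selected=False)
        D_X, D_G = information_levels(psi, phi, 50)
        assert run.D_X[-1] == pytest.approx(D_X, abs=1e-6)
        assert run.D_G[-1] == pytest.approx(D_G, abs=1e-6)

    def test_maintenance_cost_persists_at_stationarity(self):
        """Near stationarity the information increments vanish but the cost
        rate stays positive: maintaining information is not free."""
        model = WFModel(N=50, mu=0.01, s=0.04)
        run = accumulation_experiment(model, 3000)
        assert abs(run.dD_X[-1]) < 1e-8
        assert run.cost_rate[-1] > 1e-4

    def test_requires_mutation(self):
        with pytest.raises(ValueError):
            accumulation_experiment(WFModel(N=10, mu=0.0, s=0.1), 10)


class TestAlleleExchangeSymmetry:
    def test_information_invariant_under_allele_swap(self):
        """Relabelling a <-> A (fitness pair swapped) leaves every
        information quantity unchanged."""
        N, mu, s = 40, 0.005, 0.05
        fwd = WFModel(N=N, mu=mu, s=s)
        swapped = WFModel(N=N, mu=mu, fitness_rule=lambda x: (1.0 + s, 1.0))
        psi_f = stationary_distribution(fwd)
        psi_s = stationary_distribution(swapped)
        phi = stationary_distribution(fwd, selected=False)
        np.testing.assert_allclose(psi_f, psi_s[::-1], atol=1e-10)
        D_f = information_levels(psi_f, phi, N)
        D_s = information_levels(psi_s, phi[::-1], N)
        assert D_f == pytest.approx(D_s, abs=1e-10)
        np.testing.assert_allclose(state_costs(fwd), state_costs(swapped)[::-1],
                                   atol=1e-12)


class TestMaintenanceScan:
    def test_genotype_information_grows_toward_one_bit(self):
        scan = maintenance_scan(100, 1e-4, [0.5, 1, 2, 5, 10, 20])
        assert np.all(np.diff(scan["D_G"]) > 0)
        assert scan["D_G"].iloc[-1] < 1.0
        assert scan["D_G"].iloc[-1] > 0.9

    def test_hierarchy_within_scan(self):
        scan = maintenance_scan(60, 1e-3, [0.5, 2, 8])
        assert np.all(scan["D_X"] >= scan["D_G"] - 1e-10)
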