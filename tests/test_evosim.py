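"""Evolution simulator: DFE sampling, epoch dynamics, rates, determinism."""

import math

import numpy as np
import pytest
from scipy import integrate

from fscodes.evosim import (
    PopulationState,
    SimulationConfig,
    dfe_mean,
    evolutionary_rate,
    phi_for_code,
    run_evolution,
    run_replicate,
    sample_dfe,
    step_epoch,
)
from fscodes.fixtures import strain_state


class TestDFE:
    def test_exponential_case_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_dfe(rng, beta=1.0, lam=2.0, size=100_000)
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_general_case_against_quadrature(self):
        beta, lam = 2.0, 1.0
        norm, _ = integrate.quad(lambda x: math.exp(-((lam * x) ** beta)), 0, np.inf)
        expected, _ = integrate.quad(
            lambda x: x * math.exp(-((lam * x) ** beta)) / norm, 0, np.inf
        )
        assert dfe_mean(beta, lam) == pytest.approx(expected, rel=1e-9)
        rng = np.random.default_rng(1)
        draws = sample_dfe(rng, beta=beta, lam=lam, size=100_000)
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_large_lambda_limit(self):
        rng = np.random.default_rng(2)
        draws = sample_dfe(rng, beta=1.0, lam=1e9, size=1000)
        assert draws.max() < 1e-6

    def test_invalid_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_dfe(rng, beta=0.0, lam=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(dfe_lambda=-1.0)

    def test_ref45_preset_mean_is_two_percent(self):
        cfg = SimulationConfig.ref45()
        assert dfe_mean(cfg.dfe_beta, cfg.dfe_lambda) == pytest.approx(0.02)
        cfg2 = SimulationConfig.ref45(dfe_beta=2.0)
        assert dfe_mean(cfg2.dfe_beta, cfg2.dfe_lambda) == pytest.approx(0.02)


class TestEpochDynamics:
    def test_monoclonal_without_mutation_is_constant(self):
        cfg = SimulationConfig(n_total=1e6, u_b=0.0, duration=50.0)
        traj = run_replicate(1.0, cfg, np.random.default_rng(0))
        assert np.all(traj.mean_fitness == 1.0)
        assert traj.slope() == 0.0

    def test_deterministic_pair_matches_closed_form(self):
        # two analytic strains: size ratio after t generations = e^(df * t)
        cfg = SimulationConfig(u_b=0.0, pruning_enabled=False, n_total=2e6)
        state = strain_state([1e6, 1e6], [1.00, 1.02])
        rng = np.random.default_rng(0)
        for _ in range(100):  # 10 generations
            step_epoch(state, cfg, rng)
        ratio = state.n[1] / state.n[0]
        assert ratio == pytest.approx(math.exp(0.02 * 10.0), rel=1e-10)

    def test_stochastic_strain_at_mean_is_critical(self):
        # p_b = p_d = dt when f_i = <f>: expected net change is zero
        cfg = SimulationConfig(u_b=0.0, pruning_enabled=False)
        deltas = []
        for seed in range(200):
            state = strain_state([100.0], [1.0], stochastic=[True])
            step_epoch(state, cfg, np.random.default_rng(seed))
            n = state.n[0] if len(state.n) else 0.0
            deltas.append(n - 100.0)
        mean = np.mean(deltas)
        se = np.std(deltas) / math.sqrt(len(deltas))
        assert abs(mean) < 3 * max(se, 0.5)

    def test_mutants_only_from_analytic_group(self):
        cfg = SimulationConfig(n_total=200.0, u_b=1.0, seed=0)  # huge mutation rate
        state = strain_state([200.0], [1.0], stochastic=[True])
        rng = np.random.default_rng(0)
        step_epoch(state, cfg, rng, np.array([1.0]))
        # the lone strain stays stochastic (below the forced-analytic size),
        # so no mutants can appear
        assert len(state.n) == 1

    def test_expected_mutant_count_formula(self):
        cfg = SimulationConfig(n_total=1e6, seed=0)
        mu = cfg.n_total * cfg.u_b * 0.5 * cfg.dt
        counts = []
        for seed in range(300):
            state = strain_state([1e6], [1.0])
            step_epoch(state, cfg, np.random.default_rng(seed), np.array([0.5]))
            counts.append(len(state.n) - 1)
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - mu) < 4 * max(se, 0.05)

    def test_neutral_effects_leave_fitness_flat(self):
        cfg = SimulationConfig(n_total=1e6, dfe_lambda=1e9, duration=100.0)
        traj = run_replicate(1.0, cfg, np.random.default_rng(5))
        assert abs(traj.mean_fitness[-1] - 1.0) < 1e-6


class TestPruning:
    def test_above_mean_strains_never_pruned(self):
        cfg = SimulationConfig(u_b=0.0, n_total=2e6)
        state = strain_state([1e6, 50.0], [1.0, 1.5], stochastic=[False, True])
        rng = np.random.default_rng(0)
        for _ in range(10):
            step_epoch(state, cfg, rng)
        assert 1.5 in state.f

    def test_large_low_fitness_strain_survives_until_small(self):
        cfg = SimulationConfig(u_b=0.0, n_total=2e6)
        state = strain_state([1e6, 1e6], [0.9, 1.1])
        rng = np.random.default_rng(0)
        step_epoch(state, cfg, rng)
        assert len(state.n) == 2  # still analytic, not pruned
        assert state.pruned == 0

    def test_pruning_bias_positive_and_small(self):
        base = dict(n_total=1e6, duration=150.0, n_replicates=8, seed=11)
        on = evolutionary_rate(
            run_evolution(1.0, SimulationConfig.ref45(pruning_enabled=True, **base))
        )
        off = evolutionary_rate(
            run_evolution(1.0, SimulationConfig.ref45(pruning_enabled=False, **base))
        )
        # paired seeds: pruning inflates mean fitness slightly, never hugely
        assert on.mean >= off.mean * 0.98
        assert on.mean - off.mean < 0.3 * max(off.mean, 1e-12)


class TestRates:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig.ref45(n_total=1e5, duration=50.0, n_replicates=3, seed=9)
        a = run_evolution(0.7, cfg)
        b = run_evolution(0.7, cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.mean_fitness, tb.mean_fitness)

    def test_zero_phi_arrests_evolution(self, red15):
        assert phi_for_code(red15) == 0.0
        cfg = SimulationConfig.ref45(n_total=1e6, duration=100.0, n_replicates=3, seed=1)
        rate = evolutionary_rate(run_evolution(red15, cfg))
        assert rate.mean == 0.0
        assert rate.sd == 0.0

    def test_rate_monotone_in_phi(self):
        cfg = SimulationConfig.ref45(n_total=1e6, duration=300.0, n_replicates=10, seed=21)
        rates = [
            evolutionary_rate(run_evolution(ph, cfg)).mean for ph in (0.0, 0.2, 1.0)
        ]
        assert rates[0] == 0.0
        assert rates[0] < rates[1] < rates[2]

    def test_flat_traces_give_zero_rate(self):
        cfg = SimulationConfig(n_total=1e5, u_b=0.0, duration=20.0, n_replicates=2, seed=0)
        rate = evolutionary_rate(run_evolution(1.0, cfg))
        assert rate == evolutionary_rate(run_evolution(1.0, cfg))
        assert rate.mean == 0.0

    def test_standard_code_fitness_increases(self, standard):
        cfg = SimulationConfig.ref45(n_total=1e6, duration=300.0, n_replicates=4, seed=2)
        trajs = run_evolution(standard, cfg)
        assert evolutionary_rate(trajs).mean > 0
        assert np.mean([t.mean_fitness[-1] for t in trajs]) > 1.0

    def test_wobble_flag_raises_phi_for_red_codes(self, red20):
        assert phi_for_code(red20, wobble=True) > phi_for_code(red20, wobble=False)
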