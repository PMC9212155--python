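import numpy as np
import pytest

from phagehost import (
    ChemostatState,
    InvalidConfigError,
    SimulationParams,
    host_round,
    init_simulation,
    normalize,
    nutrient_update,
    run,
    step,
    virus_round,
)


def make_state(nparams, rng, **overrides):
    state = init_simulation(nparams, rng)
    for key, value in overrides.items():
        setattr(state, key, value)
    return state


class TestInit:
    def test_default_inoculum(self, default_nparams):
        state = init_simulation(default_nparams, np.random.default_rng(0))
        assert state.N_h == 46
        assert state.N_v == 810
        assert np.all(state.host_g_alpha == 0.1)
        assert np.all((state.host_m >= 0.5) & (state.host_m <= 1.0))
        # P_d = P_units - sum(m) with 46 masses in [1/2, 1]
        assert 855.42 - 46 <= state.P_d <= 855.42 - 23
        assert state.time == 0

    def test_no_hosts_leaves_full_nutrient_pool(self):
        n = normalize(SimulationParams(N_h0=0))
        state = init_simulation(n, np.random.default_rng(0))
        assert state.P_d == n.P_units

    def test_seed_reproducibility(self, default_nparams):
        s1 = init_simulation(default_nparams, np.random.default_rng(3))
        s2 = init_simulation(default_nparams, np.random.default_rng(3))
        assert np.array_equal(s1.host_m, s2.host_m)
        assert s1.P_d == s2.P_d

    def test_overfull_inoculum_rejected(self):
        # P_units ~ 6 host-equivalents cannot hold 46 hosts of mass >= 1/2
        n = normalize(SimulationParams(P=0.5))
        with pytest.raises(InvalidConfigError):
            init_simulation(n, np.random.default_rng(0))


class TestNutrientUpdate:
    def test_closed_system_is_inert(self, rng):
        n = normalize(SimulationParams(omega=0.0))
        state = make_state(n, rng, P_d=300.0)
        nutrient_update(state, n)
        assert state.P_d == 300.0

    def test_full_relaxation(self, rng):
        n = normalize(SimulationParams(omega=1.0))
        state = make_state(n, rng, P_d=123.0)
        nutrient_update(state, n)
        assert state.P_d == pytest.approx(state.P_d0)

    def test_partial_relaxation_arithmetic(self, rng):
        n = normalize(SimulationParams())
        state = make_state(n, rng, P_d=300.0)
        state.P_d0 = 800.0
        nutrient_update(state, n)
        assert state.P_d == pytest.approx(400.0)


class TestHostRound:
    def test_no_nutrient_no_growth(self, rng):
        n = normalize(SimulationParams(omega=0.0, delta_h=0.0, eps_h=0.0))
        state = make_state(n, rng, P_d=0.0)
        before = np.sort(state.host_m.copy())
        host_round(state, n, rng)
        assert np.array_equal(np.sort(state.host_m), before)

    def test_division_splits_mass_in_half(self, rng):
        # saturating nutrient: Monod factor -> 1, gain -> mu_h = 0.738;
        # a host of mass 0.9 grows past unity and divides into ~0.819 halves
        p = SimulationParams(N_h0=1, N_v0=0, omega=0.0, delta_h=0.0,
                             eps_h=0.0, pi_h=0.0, P=8.3e7, g_alpha0=1.0)
        n = normalize(p)
        state = make_state(n, rng, host_m=np.array([0.9]))
        host_round(state, n, rng)
        assert state.N_h == 2
        assert np.allclose(state.host_m, 0.819, atol=1e-3)

    def test_no_mutation_keeps_population_monomorphic(self):
        traj = run(SimulationParams(pi_h=0.0, T=10), seed=5)
        # every host gene stays in the single initial histogram bin
        occupied = np.nonzero(traj.hist_g_alpha.sum(axis=0))[0]
        assert occupied.size == 1


class TestVirusRound:
    def test_no_hosts_only_washout_and_decay(self, rng):
        n = normalize(SimulationParams(N_h0=0))
        state = make_state(n, rng)
        before = state.N_v
        virus_round(state, n, rng)
        assert state.N_v <= before
        assert np.all(state.virus_g_nu == 0.1)

    def test_zero_burst_size_conserves_event_arithmetic(self, rng):
        # random kernels make infections frequent; kappa = 0 removes exactly
        # one host and one virus per infection
        p = SimulationParams(kappa=0, omega=0.0, delta_v=0.0,
                             compatibility_mode="random",
                             virulence_mode="random")
        n = normalize(p)
        state = make_state(n, rng)
        nh0, nv0 = state.N_h, state.N_v
        virus_round(state, n, rng)
        assert nh0 - state.N_h == nv0 - state.N_v
        assert nh0 > state.N_h  # some infections did occur

    def test_zero_adsorption_never_infects(self):
        traj = run(SimulationParams(beta=0.0, T=10, omega=0.0), seed=9)
        # virus genes never change (no progeny), abundance only decays
        assert np.all(np.diff(traj.N_v) <= 0)
        occupied = np.nonzero(traj.hist_g_nu.sum(axis=0))[0]
        assert occupied.size == 1


class TestStepAndRun:
    def test_trajectory_length_and_t0(self, default_params):
        traj = run(default_params, seed=1)
        assert len(traj) == default_params.T + 1
        assert traj.N_h[0] == 46 and traj.N_v[0] == 810

    def test_zero_horizon(self, default_params):
        traj = run(default_params.with_(T=0), seed=1)
        assert len(traj) == 1

    def test_bit_identical_given_seed(self, default_params):
        t1 = run(default_params, seed=42)
        t2 = run(default_params, seed=42)
        for name in ("N_h", "N_v", "P_d", "mean_g_alpha", "hist_g_beta"):
            assert np.array_equal(getattr(t1, name), getattr(t2, name),
                                  equal_nan=True), name

    def test_closed_system_conserves_phosphorus(self):
        p = SimulationParams(omega=0.0)
        n = normalize(p)
        traj = run(p, seed=3)
        total = traj.P_d + traj.host_mass
        assert np.allclose(total, n.P_units, rtol=1e-9)

    def test_open_system_phosphorus_ledger(self, default_nparams):
        rng = np.random.default_rng(8)
        state = init_simulation(default_nparams, rng)
        budget0 = state.P_d + state.host_m.sum()
        for _ in range(20):
            step(state, default_nparams, rng)
            budget = (state.P_d + state.host_m.sum()
                      + state.cumulative_outflow - state.cumulative_inflow)
            assert budget == pytest.approx(budget0, rel=1e-9)

    def test_state_bounds_all_steps(self):
        p = SimulationParams(sigma_h=0.3, sigma_v=0.2, T=25)
        n = normalize(p)
        rng = np.random.default_rng(11)
        state = init_simulation(n, rng)
        for _ in range(p.T):
            step(state, n, rng)
            assert np.all(state.host_m > 0) and np.all(state.host_m <= 1.0)
            for genes in (state.host_g_alpha, state.virus_g_nu,
                          state.virus_g_beta):
                assert np.all((genes >= 0.0) & (genes <= 1.0))
            assert state.P_d >= 0.0

    def test_virus_free_hosts_reach_bounded_plateau(self):
        p = SimulationParams(N_v0=0, omega=0.0)
        n = normalize(p)
        traj = run(p, seed=2)
        # every host carries at least mass 1/2, so the nutrient budget caps
        # the population at 2 * P_units individuals
        assert traj.N_h[-1] <= n.P_units / 0.5
        assert traj.N_h[-1] > 1000  # grew to a substantial plateau

    def test_random_kernels_per_pair_infection_probability(self):
        # one virus meeting one host under random compatibility and random
        # virulence succeeds with probability E[U1]*E[U2] = 1/4
        p = SimulationParams(N_h0=1, N_v0=1, omega=0.0, delta_h=0.0,
                             delta_v=0.0, eps_h=0.0, mu_h=0.0, kappa=0,
                             T=1, compatibility_mode="random",
                             virulence_mode="random")
        n_trials = 2000
        infected = sum(run(p, seed=s).N_h[-1] == 0 for s in range(n_trials))
        se = (0.25 * 0.75 / n_trials) ** 0.5
        assert infected / n_trials == pytest.approx(0.25, abs=3 * se)
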