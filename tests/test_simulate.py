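"""Distributional law checks for the direct-method SSA and dataset extraction."""

import numpy as np
import pytest
from scipy import stats as sps

import stochmle as sm
from stochmle.simulate import RunawayError


class TestSSAStep:
    def test_pure_birth_waiting_time_is_exponential(self, pure_birth, rng):
        theta = np.array([2.0])
        state = sm.SystemState(np.array([0]))
        taus = []
        for _ in range(10_000):
            tau, j = sm.ssa_step(pure_birth.network, theta, state, rng)
            assert j == 0
            taus.append(tau)
        taus = np.array(taus)
        se = taus.std() / np.sqrt(taus.size)
        assert abs(taus.mean() - 0.5) < 3 * se

    def test_reaction_choice_follows_propensity_weights(self, birth_death, rng):
        # a = (3, 1) at x=10 with theta=(3, .1): P(birth) = .75
        theta = np.array([3.0, 0.1])
        state = sm.SystemState(np.array([10]))
        draws = np.array(
            [sm.ssa_step(birth_death.network, theta, state, rng)[1] for _ in range(10_000)]
        )
        p = (draws == 0).mean()
        assert abs(p - 0.75) < 3 * np.sqrt(0.75 * 0.25 / draws.size)

    def test_exhausted_system_returns_none(self, rng):
        model = sm.builtin_model("decay_dimer_irreversible")
        state = sm.SystemState(np.array([0, 0]))
        assert sm.ssa_step(model.network, np.ones(3), state, rng) is None


class TestSimulateInterval:
    def test_vanishing_rates_leave_state_untouched(self, birth_death, rng):
        start = sm.SystemState(np.array([5]))
        seg, end = sm.simulate_interval(
            birth_death.network, np.array([1e-12, 1e-12]), start, 0.0, 3.0, rng
        )
        assert seg.n_events == 0
        assert seg.terminal_residual == pytest.approx(3.0)
        assert end.x.tolist() == [5] and end.t == 3.0

    def test_pure_birth_counts_are_poisson(self, pure_birth, rng):
        theta, t = 1.5, 2.0
        counts = []
        for _ in range(10_000):
            seg, end = sm.simulate_interval(
                pure_birth.network, np.array([theta]), sm.SystemState(np.array([0])),
                0.0, t, rng,
            )
            counts.append(end.x[0])
        counts = np.array(counts)
        lam = theta * t
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / counts.size)
        var_se = lam * np.sqrt(2.0 / counts.size)  # approx SE of Poisson variance
        assert abs(counts.var() - lam) < 4 * var_se

    def test_segment_concatenation_is_markov_consistent(self, birth_death, rng):
        """End-state law of [0,2] equals that of [0,1] then [1,2]."""
        theta = np.array([2.0, 0.3])
        n = 10_000
        one_shot, two_step = [], []
        for _ in range(n):
            _, end = sm.simulate_interval(
                birth_death.network, theta, sm.SystemState(np.array([4])), 0.0, 2.0, rng
            )
            one_shot.append(end.x[0])
            _, mid = sm.simulate_interval(
                birth_death.network, theta, sm.SystemState(np.array([4])), 0.0, 1.0, rng
            )
            _, end = sm.simulate_interval(birth_death.network, theta, mid, 1.0, 2.0, rng)
            two_step.append(end.x[0])
        edges = np.arange(0, 16)
        h1, _ = np.histogram(one_shot, bins=edges)
        h2, _ = np.histogram(two_step, bins=edges)
        keep = (h1 + h2) >= 10
        table = np.stack([h1[keep], h2[keep]])
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 1e-3

    def test_runaway_guard(self, pure_birth, rng):
        with pytest.raises(RunawayError):
            sm.simulate_interval(
                pure_birth.network, np.array([100.0]), sm.SystemState(np.array([0])),
                0.0, 10.0, rng, max_events=50,
            )


class TestSimulateTrajectory:
    def test_birth_death_long_run_mean(self, birth_death, rng):
        # time-average of x approaches theta1/theta2; H_death integrates x dt
        theta = np.array([1.0, 0.06])
        traj = sm.simulate_trajectory(
            birth_death.network, theta, np.array([17]), sm.SimulationConfig(10_000.0), rng
        )
        stats = sm.sufficient_statistics(birth_death.network, traj)
        time_avg = stats.integrated_h[1] / traj.horizon
        assert time_avg == pytest.approx(1.0 / 0.06, rel=0.10)

    def test_seeded_runs_are_bit_reproducible(self, birth_death):
        cfg = sm.SimulationConfig(50.0, rng_seed=7)
        a = sm.simulate_trajectory(birth_death.network, birth_death.theta_star, np.array([17]), cfg)
        b = sm.simulate_trajectory(birth_death.network, birth_death.theta_star, np.array([17]), cfg)
        np.testing.assert_array_equal(a.waiting_times, b.waiting_times)
        np.testing.assert_array_equal(a.reaction_indices, b.reaction_indices)
        c = sm.simulate_trajectory(
            birth_death.network, birth_death.theta_star, np.array([17]),
            sm.SimulationConfig(50.0, rng_seed=8),
        )
        assert a.n_events != c.n_events or not np.array_equal(a.waiting_times, c.waiting_times)

    def test_martingale_identity(self, birth_death, rng):
        """E[r_j] = theta_j E[H_j] for every reaction."""
        theta = np.array([1.0, 0.1])
        diffs = []
        for _ in range(1000):
            traj = sm.simulate_trajectory(
                birth_death.network, theta, np.array([5]), sm.SimulationConfig(10.0), rng
            )
            stats = sm.sufficient_statistics(birth_death.network, traj)
            diffs.append(stats.counts - theta * stats.integrated_h)
        diffs = np.array(diffs)
        se = diffs.std(axis=0) / np.sqrt(diffs.shape[0])
        assert (np.abs(diffs.mean(axis=0)) < 3.5 * se + 1e-9).all()

    def test_replay_never_goes_negative(self, decay_dimer, rng):
        traj = sm.simulate_trajectory(
            decay_dimer.network, decay_dimer.theta_star, decay_dimer.x0,
            sm.SimulationConfig(decay_dimer.horizon), rng,
        )
        for x, _tau, _j in traj.replay(decay_dimer.network):
            assert (x >= 0).all()

    def test_pure_birth_terminal_count_poisson_gof(self, pure_birth, rng):
        theta, T = 1.0, 5.0
        counts = np.array(
            [
                sm.simulate_trajectory(
                    pure_birth.network, np.array([theta]), np.array([0]),
                    sm.SimulationConfig(T), rng,
                ).n_events
                for _ in range(10_000)
            ]
        )
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1)
        expected = sps.poisson.pmf(np.arange(kmax + 1), theta * T) * counts.size
        keep = expected >= 5
        observed = np.append(observed[keep], observed[~keep].sum())
        expected = np.append(expected[keep], expected[~keep].sum())
        stat, p = sps.chisquare(observed, expected * observed.sum() / expected.sum())
        assert p > 1e-3


class TestExtractObservations:
    def test_equally_spaced_grid(self, pure_birth, rng):
        traj = sm.simulate_trajectory(
            pure_birth.network, np.array([1.0]), np.array([0]),
            sm.SimulationConfig(1000.0), rng,
        )
        data = sm.extract_observations(pure_birth.network, traj, 30)
        assert data.d == 30
        assert data.times[0] == pytest.approx(1000.0 / 30)
        assert np.allclose(np.diff(data.times), 1000.0 / 30)
        assert data.times[-1] == 1000.0
        assert data.values.shape == (30, 1)

    def test_single_observation_at_horizon(self, pure_birth, rng):
        traj = sm.simulate_trajectory(
            pure_birth.network, np.array([2.0]), np.array([0]), sm.SimulationConfig(10.0), rng
        )
        data = sm.extract_observations(pure_birth.network, traj, 1)
        assert data.d == 1 and data.times[0] == 10.0
        assert data.values[0, 0] == traj.n_events

    def test_counts_match_piecewise_constant_state(self, birth_death, rng):
        traj = sm.simulate_trajectory(
            birth_death.network, birth_death.theta_star, birth_death.x0,
            sm.SimulationConfig(20.0), rng,
        )
        data = sm.extract_observations(birth_death.network, traj, 5)
        for t, row in zip(data.times, data.values):
            np.testing.assert_array_equal(row, traj.state_at(birth_death.network, t))

    def test_species_mask_reproduces_partial_design(self, rng):
        model = sm.builtin_model("autoreg")
        traj = sm.simulate_trajectory(
            model.network, model.theta_star, model.x0, sm.SimulationConfig(5.0), rng
        )
        hidden = np.array(
            [s not in ("DNA", "DNA.P2") for s in model.network.species_names]
        )
        data = sm.extract_observations(model.network, traj, 10, hidden)
        assert data.values.shape == (10, 3)  # mRNA, P, P2 only
        assert data.x0.shape == (5,)  # x0 stays full
        assert not data.fully_observed


class TestBuiltinModels:
    @pytest.mark.parametrize(
        "name,theta,x0,T,d",
        [
            ("birth_death", [1.0, 0.06], [17], 200.0, 40),
            ("decay_dimer_4rxn", [0.2, 0.04, 0.5, 1.0], [1000, 10, 10], 0.1, 5),
            (
                "yeast_polarization",
                [0.38, 0.04, 0.082, 0.12, 0.021, 0.1, 0.005, 13.21],
                [500, 4, 110, 300, 2, 20, 90],
                5.0,
                15,
            ),
        ],
    )
    def test_published_configurations(self, name, theta, x0, T, d):
        model = sm.builtin_model(name)
        np.testing.assert_allclose(model.theta_star, theta)
        np.testing.assert_array_equal(model.x0, x0)
        assert model.horizon == T and model.d == d

    def test_modified_suite_variants(self):
        suite = sm.modified_birth_death_suite()
        assert [m.theta_star[1] for m in suite] == [0.1, 0.5, 1.0, 2.5, 5.0]
        assert [int(m.x0[0]) for m in suite] == [5, 1, 1, 1, 1]
        assert all(m.theta_star[0] == 0.5 and m.horizon == 25.0 and m.d == 25 for m in suite)

    def test_unknown_name_lists_valid_models(self):
        with pytest.raises(KeyError, match="yeast_polarization"):
            sm.builtin_model("brusselator")
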