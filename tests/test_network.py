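"""Mass-action propensity algebra, trajectory statistics and the complete-data MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

import stochmle as sm
from stochmle.network import (
    InvalidTrajectoryError,
    log_likelihood_from_stats,
    pooled_mle,
    shrink_unfired,
)

from conftest import random_toy_trajectory


class TestCombinatorialFactor:
    def test_zeroth_order_is_one(self, pure_birth):
        state = sm.SystemState(np.array([0]))
        assert sm.evaluate_h(pure_birth.network, 0, state) == 1

    def test_unimolecular_counts_molecules(self, birth_death):
        assert sm.evaluate_h(birth_death.network, 1, sm.SystemState(np.array([5]))) == 5

    def test_homo_bimolecular_pairs(self, decay_dimer):
        # 2 S1 -> S2 with x1 = 5: 5*4/2 distinct pairs
        state = sm.SystemState(np.array([5, 0]))
        assert sm.evaluate_h(decay_dimer.network, 1, state) == 10

    def test_hetero_bimolecular_product(self):
        net = sm.ReactionNetwork(
            ["A", "B"],
            [sm.Reaction(np.array([1, 1]), np.array([0, 0]))],
        )
        assert sm.evaluate_h(net, 0, sm.SystemState(np.array([3, 4]))) == 12

    @pytest.mark.parametrize(
        "x,expected", [([0, 0], 0), ([1, 0], 0), ([2, 0], 1)]
    )
    def test_zero_exactly_when_reactants_insufficient(self, decay_dimer, x, expected):
        state = sm.SystemState(np.array(x))
        assert sm.evaluate_h(decay_dimer.network, 1, state) == expected


class TestPropensities:
    def test_birth_death_printed_state(self, birth_death):
        a, a0 = sm.evaluate_propensities(
            birth_death.network, np.array([1.0, 0.06]), sm.SystemState(np.array([17]))
        )
        np.testing.assert_allclose(a, [1.0, 1.02])
        assert a0 == pytest.approx(2.02)

    def test_zero_h_gives_zero_propensity(self, decay_dimer):
        a, a0 = sm.evaluate_propensities(
            decay_dimer.network, np.array([1.0, 1.0, 1.0]), sm.SystemState(np.array([0, 0]))
        )
        assert a0 == 0.0 and (a == 0).all()

    def test_theta_must_be_positive(self, pure_birth):
        with pytest.raises(ValueError):
            sm.evaluate_propensities(
                pure_birth.network, np.array([0.0]), sm.SystemState(np.array([0]))
            )


class TestApplyReaction:
    def test_birth_from_empty(self, birth_death):
        out = sm.apply_reaction(birth_death.network, sm.SystemState(np.array([0])), 0)
        assert out.x.tolist() == [1]

    def test_death_to_empty(self, birth_death):
        out = sm.apply_reaction(birth_death.network, sm.SystemState(np.array([1])), 1)
        assert out.x.tolist() == [0]

    def test_dimerization_stoichiometry(self, decay_dimer):
        out = sm.apply_reaction(decay_dimer.network, sm.SystemState(np.array([4, 0])), 1)
        assert out.x.tolist() == [2, 1]

    def test_forbidden_firing_raises(self, birth_death):
        with pytest.raises(InvalidTrajectoryError):
            sm.apply_reaction(birth_death.network, sm.SystemState(np.array([0])), 1)


class TestReactionValidation:
    def test_order_tags_derived_from_stoichiometry(self, decay_dimer):
        assert [r.order for r in decay_dimer.network.reactions] == [
            "unimolecular",
            "homo-bimolecular",
            "unimolecular",
        ]

    def test_trimolecular_rejected(self):
        with pytest.raises(ValueError, match="molecularity"):
            sm.Reaction(np.array([3]), np.array([0]))
        with pytest.raises(ValueError, match="molecularity"):
            sm.Reaction(np.array([2, 1]), np.array([0, 0]))


class TestSufficientStatistics:
    def test_pure_birth_integrates_to_horizon(self, pure_birth):
        traj = sm.CompleteTrajectory(
            x0=np.array([0]),
            waiting_times=np.array([2.0, 3.0, 4.0]),
            reaction_indices=np.array([0, 0, 0]),
            terminal_residual=1.0,
            horizon=10.0,
        )
        stats = sm.sufficient_statistics(pure_birth.network, traj)
        assert stats.counts.tolist() == [3]
        assert stats.integrated_h[0] == pytest.approx(10.0)

    def test_empty_trajectory(self, birth_death):
        traj = sm.CompleteTrajectory(
            x0=np.array([3]),
            waiting_times=np.array([]),
            reaction_indices=np.array([]),
            terminal_residual=7.0,
            horizon=7.0,
        )
        stats = sm.sufficient_statistics(birth_death.network, traj)
        assert stats.counts.tolist() == [0, 0]
        np.testing.assert_allclose(stats.integrated_h, [7.0, 21.0])  # h_death = x = 3

    def test_hand_integrated_toy(self, birth_death_toy):
        network, traj = birth_death_toy
        stats = sm.sufficient_statistics(network, traj)
        assert stats.counts.tolist() == [1, 1]
        np.testing.assert_allclose(stats.integrated_h, [4.0, 6.0])

    def test_conservation_on_random_trajectories(self, birth_death, rng):
        for _ in range(25):
            theta, traj = random_toy_trajectory(rng, birth_death.network)
            stats = sm.sufficient_statistics(birth_death.network, traj)
            assert stats.counts.sum() == traj.n_events
            total = math.fsum(traj.waiting_times) + traj.terminal_residual
            assert total == pytest.approx(traj.horizon, rel=1e-9)


class TestCompleteLogLikelihood:
    def test_pure_birth_closed_form(self, pure_birth):
        traj = sm.CompleteTrajectory(
            x0=np.array([0]),
            waiting_times=np.array([1.0, 2.5, 0.5]),
            reaction_indices=np.array([0, 0, 0]),
            terminal_residual=6.0,
            horizon=10.0,
        )
        for theta in (0.3, 1.0, 2.0):
            ll = sm.complete_log_likelihood(pure_birth.network, np.array([theta]), traj)
            assert ll == pytest.approx(3 * math.log(theta) - theta * 10.0)

    def test_toy_value_term_by_term(self, birth_death_toy):
        # theta=(1,1): (log1 - 4) + (log1 - 6) + log h_death(x0=2) = -10 + log 2
        network, traj = birth_death_toy
        ll = sm.complete_log_likelihood(network, np.array([1.0, 1.0]), traj)
        assert ll == pytest.approx(-10.0 + math.log(2.0))

    def test_theta_kernel_drops_h_terms(self, birth_death_toy):
        network, traj = birth_death_toy
        full = sm.complete_log_likelihood(network, np.array([1.0, 1.0]), traj)
        kernel = sm.complete_log_likelihood(
            network, np.array([1.0, 1.0]), traj, theta_kernel_only=True
        )
        assert full - kernel == pytest.approx(math.log(2.0))

    def test_firing_from_impossible_state_raises(self, birth_death):
        traj = sm.CompleteTrajectory(
            x0=np.array([0]),
            waiting_times=np.array([1.0]),
            reaction_indices=np.array([1]),  # death with no molecules
            terminal_residual=1.0,
            horizon=2.0,
        )
        with pytest.raises(InvalidTrajectoryError):
            sm.complete_log_likelihood(birth_death.network, np.array([1.0, 1.0]), traj)

    def test_mle_is_likelihood_maximum(self, birth_death_toy):
        network, traj = birth_death_toy
        stats = sm.sufficient_statistics(network, traj)
        theta_hat, _ = sm.complete_data_mle(stats)
        ll_hat = sm.complete_log_likelihood(network, theta_hat, traj)
        for scale in (0.5, 0.9, 1.1, 2.0):
            assert sm.complete_log_likelihood(network, theta_hat * scale, traj) < ll_hat


class TestCompleteDataMLE:
    def test_ratio_of_sufficient_statistics(self):
        stats = sm.SufficientStatistics(np.array([3]), np.array([6.0]))
        theta, fired = sm.complete_data_mle(stats)
        assert theta[0] == pytest.approx(0.5) and fired.all()

    def test_pure_birth_rate_is_events_over_horizon(self, pure_birth, rng):
        traj = sm.simulate_trajectory(
            pure_birth.network, np.array([2.0]), np.array([0]),
            sm.SimulationConfig(50.0), rng,
        )
        stats = sm.sufficient_statistics(pure_birth.network, traj)
        theta, _ = sm.complete_data_mle(stats)
        assert theta[0] == pytest.approx(traj.n_events / 50.0)

    def test_zero_count_flagged_not_estimated(self):
        stats = sm.SufficientStatistics(np.array([0, 2]), np.array([5.0, 4.0]))
        theta, fired = sm.complete_data_mle(stats)
        assert theta[0] == 0.0 and not fired[0] and theta[1] == pytest.approx(0.5)

    def test_zero_h_with_firings_is_invariant_violation(self):
        with pytest.raises(ValueError):
            sm.complete_data_mle(sm.SufficientStatistics(np.array([1]), np.array([0.0])))

    def test_matches_numeric_argmax_per_reaction(self, birth_death, decay_dimer, rng):
        """Closed-form MLE equals a 1-D numeric maximizer of the likelihood
        kernel, reaction by reaction, on 100+ random toy trajectories."""
        checked = 0
        for model in (birth_death, decay_dimer):
            for _ in range(60):
                theta, traj = random_toy_trajectory(rng, model.network)
                stats = sm.sufficient_statistics(model.network, traj)
                theta_hat, fired = sm.complete_data_mle(stats)
                base = np.where(fired, theta_hat, 1.0)
                for j in np.nonzero(fired)[0]:
                    def neg_ll(tj, j=j):
                        th = base.copy()
                        th[j] = tj
                        return -log_likelihood_from_stats(th, stats)

                    res = minimize_scalar(
                        neg_ll,
                        bounds=(1e-9, max(10.0, 10 * theta_hat[j])),
                        method="bounded",
                        options={"xatol": 1e-12},
                    )
                    assert res.x == pytest.approx(theta_hat[j], rel=1e-6)
                    checked += 1
        assert checked >= 100


class TestPooledMLE:
    def test_pooling_is_ratio_of_sums(self):
        theta, fired = pooled_mle(np.array([[2], [4]]), np.array([[4.0], [8.0]]))
        assert theta[0] == pytest.approx(0.5) and fired.all()

    def test_pooled_estimate_is_weighted_mediant(self, birth_death, rng):
        for _ in range(20):
            counts = rng.integers(1, 30, size=(2, 2))
            H = rng.uniform(1.0, 10.0, size=(2, 2))
            pooled, _ = pooled_mle(counts, H)
            per_traj = counts / H
            assert (per_traj.min(axis=0) <= pooled + 1e-12).all()
            assert (pooled <= per_traj.max(axis=0) + 1e-12).all()

    def test_shrink_replaces_unfired_by_tenth(self):
        out = shrink_unfired(
            np.array([0.0, 2.0]), np.array([False, True]), np.array([0.4, 1.0])
        )
        np.testing.assert_allclose(out, [0.04, 2.0])
        floored = shrink_unfired(
            np.array([0.0]), np.array([False]), np.array([1e-10])
        )
        assert floored[0] == pytest.approx(1e-10)


@settings(max_examples=50, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 50), min_size=1, max_size=5),
    h=st.lists(st.floats(0.1, 100.0), min_size=1, max_size=5),
)
def test_kernel_loglik_maximized_at_mle(counts, h):
    """theta_j = r_j / H_j maximizes the likelihood kernel componentwise."""
    m = min(len(counts), len(h))
    stats = sm.SufficientStatistics(np.array(counts[:m]), np.array(h[:m]))
    theta_hat, fired = sm.complete_data_mle(stats)
    if not fired.any():
        return
    theta_hat = np.where(fired, theta_hat, 1.0)
    best = log_likelihood_from_stats(theta_hat, stats)
    for scale in (0.7, 1.3):
        other = theta_hat * np.where(fired, scale, 1.0)
        assert log_likelihood_from_stats(other, stats) <= best + 1e-9
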