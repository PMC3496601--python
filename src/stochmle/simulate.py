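"""Exact trajectory generation with the direct-method SSA.

The direct method alternates an exponential waiting time with rate
``a0(x)`` and a categorical reaction choice with weights ``a_j(x)/a0(x)``.
Simulation over a finite interval discards the firing that would overshoot
the interval end — exact for exponential waiting times by memorylessness —
and records the residual quiet time instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .network import (
    CompleteTrajectory,
    ObservedDataset,
    ReactionNetwork,
    SystemState,
    evaluate_propensities,
    validate_theta,
)

__all__ = [
    "SimulationConfig",
    "RunawayError",
    "ssa_step",
    "simulate_interval",
    "simulate_trajectory",
    "extract_observations",
]

DEFAULT_MAX_EVENTS = 10_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Horizon, seed and runaway guard for a single-trajectory simulation."""

    horizon: float
    rng_seed: int | None = None
    max_events: int = DEFAULT_MAX_EVENTS

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.max_events < 1:
            raise ValueError("max_events must be positive")


class RunawayError(RuntimeError):
    """A simulation exceeded its event cap."""


def ssa_step(
    network: ReactionNetwork,
    theta: np.ndarray,
    state: SystemState,
    rng: np.random.Generator,
) -> tuple[float, int] | None:
    """One direct-method step: ``(tau, j')`` or None when ``a0 = 0``.

    ``a0 = 0`` means no reaction can ever fire again from this state
    (all combinatorial factors vanish), so the system is exhausted.
    """
    a, a0 = evaluate_propensities(network, theta, state)
    if a0 <= 0.0:
        return None
    tau = rng.exponential(1.0 / a0)
    j = int(rng.choice(network.n_reactions, p=a / a0))
    return tau, j


def simulate_interval(
    network: ReactionNetwork,
    theta: np.ndarray,
    state: SystemState,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> tuple[CompleteTrajectory, SystemState]:
    """Simulate ``[t_start, t_end]`` from ``state``.

    Returns the segment (a :class:`CompleteTrajectory` over the interval,
    with ``x0`` the entry state) and the state at ``t_end``.
    """
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    theta = validate_theta(theta, network.n_reactions)
    order, s1, s2, net = network.kernel_tables()
    x = state.x.copy()
    taus, js, n, residual = _kernels.interval_events(
        order, s1, s2, net, theta, x, t_end - t_start, max_events, rng
    )
    if n < 0:
        raise RunawayError(
            f"more than {max_events} firings on [{t_start}, {t_end}]; "
            "raise max_events if this is expected"
        )
    segment = CompleteTrajectory(
        x0=state.x.copy(),
        waiting_times=taus[:n].copy(),
        reaction_indices=js[:n].copy(),
        terminal_residual=residual,
        horizon=t_end - t_start,
    )
    return segment, SystemState(x, t_end)


def simulate_trajectory(
    network: ReactionNetwork,
    theta: np.ndarray,
    x0: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CompleteTrajectory:
    """Complete trajectory over ``[0, T]`` from initial counts ``x0``."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    traj, _end = simulate_interval(
        network,
        theta,
        SystemState(np.asarray(x0, dtype=np.int64), 0.0),
        0.0,
        config.horizon,
        rng,
        config.max_events,
    )
    return traj


def extract_observations(
    network: ReactionNetwork,
    trajectory: CompleteTrajectory,
    d: int,
    observed_mask: np.ndarray | None = None,
) -> ObservedDataset:
    """Subsample a trajectory at ``d`` equally spaced times ``t_i = i T / d``.

    The state "at t_i" is the piecewise-constant state after all firings
    with cumulative time <= t_i (closed on the right).  ``observed_mask``
    restricts the recorded species; ``x0`` is always stored in full.
    """
    if d < 1:
        raise ValueError("need at least one observation time")
    N = trajectory.x0.shape[0]
    mask = (
        np.ones(N, dtype=bool)
        if observed_mask is None
        else np.asarray(observed_mask, dtype=bool)
    )
    T = trajectory.horizon
    times = np.arange(1, d + 1) * (T / d)
    times[-1] = T  # guard against roundoff at the horizon
    states = np.empty((d, N), dtype=np.int64)
    x = trajectory.x0.copy()
    net = network.net_matrix
    elapsed = 0.0
    i = 0
    for tau, j in zip(trajectory.waiting_times, trajectory.reaction_indices):
        elapsed += tau
        while i < d and times[i] < elapsed:
            states[i] = x
            i += 1
        x = x + net[int(j)]
    while i < d:
        states[i] = x
        i += 1
    return ObservedDataset(
        x0=trajectory.x0.copy(),
        times=times,
        observed_mask=mask,
        values=states[:, mask],
    )
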