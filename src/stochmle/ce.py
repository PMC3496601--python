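"""Modified cross-entropy initializer with multilevel splitting.

The cross-entropy (CE) phase turns an arbitrary starting guess into a
plausible rate vector ``theta_CE`` by iterating a simulate-select-split
loop.  Each iteration simulates an ensemble of ``K`` trajectories one
observation interval at a time; after each interval the ensemble is
enriched by resampling (with replacement) the elite fraction whose
cumulative normalized-L1 distance to the data is smallest — multilevel
splitting, with the observed time points as the intermediate milestones.
Per interval and per member, the current estimate is jittered uniformly
on ``[(1-lambda) theta, (1+lambda) theta]`` to inject exploration
variability beyond the system's intrinsic noise.  After the final
interval the elite trajectories' pooled sufficient statistics give the
next estimate; the loop ends when the elite distance threshold
``delta`` reaches zero (every elite trajectory hits every observed
point exactly) or when ``delta`` plateaus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import (
    ObservedDataset,
    ReactionNetwork,
    pooled_mle,
    shrink_unfired,
    validate_theta,
)
from .simulate import RunawayError

__all__ = [
    "CEConfig",
    "CEResult",
    "WeightedEnsemble",
    "CENonConvergenceError",
    "normalized_l1_distance",
    "perturb_parameters",
    "select_and_split",
    "ce_parameter_update",
    "run_ce_phase",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CEConfig:
    """Tuning constants of the CE phase.

    ``ensemble_size`` (K) and ``elite_fraction`` (rho) set the number of
    elite trajectories ceil(rho K) used per update; ``split_fraction``
    (rho') governs interval-level splitting and defaults to rho;
    ``perturbation`` (lambda) is the uniform jitter half-width.  The
    plateau rule stops early when the running-minimum delta improves by
    less than ``plateau_tolerance`` (relative) over ``plateau_window``
    iterations — the remedy for models whose elites cannot reach
    delta = 0 at affordable K.
    """

    ensemble_size: int = 10_000
    elite_fraction: float = 0.001
    split_fraction: float | None = None
    perturbation: float = 0.25
    max_iterations: int = 500
    plateau_window: int = 10
    plateau_tolerance: float = 1e-3
    max_events_per_interval: int = 10_000_000

    def __post_init__(self) -> None:
        if not 0 < self.elite_fraction <= 1:
            raise ValueError("elite_fraction must lie in (0, 1]")
        sf = self.split_fraction
        if sf is not None and not 0 < sf <= 1:
            raise ValueError("split_fraction must lie in (0, 1]")
        if not 0 <= self.perturbation <= 1:
            raise ValueError("perturbation (lambda) must lie in [0, 1]")
        if self.ensemble_size < self.elite_count:
            raise ValueError("ensemble_size must be at least the elite count")

    @property
    def elite_count(self) -> int:
        return max(1, math.ceil(self.elite_fraction * self.ensemble_size))

    @property
    def split_count(self) -> int:
        sf = self.elite_fraction if self.split_fraction is None else self.split_fraction
        return max(1, math.ceil(sf * self.ensemble_size))


@dataclass
class WeightedEnsemble:
    """Ensemble state carried across intervals of one CE iteration.

    Members share ``x0``; each carries its current state, its lineage's
    accumulated sufficient statistics over the intervals simulated so
    far, and its running cumulative distance to the data.  Resampling
    copies whole rows, so a clone inherits its parent's full ancestry.
    """

    states: np.ndarray  # (K, N) int64
    counts: np.ndarray  # (K, M) int64
    integrated_h: np.ndarray  # (K, M)
    h_compensation: np.ndarray  # (K, M) Kahan carry
    distances: np.ndarray  # (K,)

    @classmethod
    def initial(cls, x0: np.ndarray, K: int, M: int) -> "WeightedEnsemble":
        N = x0.shape[0]
        return cls(
            states=np.tile(np.asarray(x0, dtype=np.int64), (K, 1)),
            counts=np.zeros((K, M), dtype=np.int64),
            integrated_h=np.zeros((K, M)),
            h_compensation=np.zeros((K, M)),
            distances=np.zeros(K),
        )

    @property
    def size(self) -> int:
        return int(self.states.shape[0])

    def take(self, idx: np.ndarray) -> "WeightedEnsemble":
        return WeightedEnsemble(
            states=self.states[idx].copy(),
            counts=self.counts[idx].copy(),
            integrated_h=self.integrated_h[idx].copy(),
            h_compensation=self.h_compensation[idx].copy(),
            distances=self.distances[idx].copy(),
        )


class CENonConvergenceError(RuntimeError):
    """CE phase hit max_iterations before delta reached zero or plateaued."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


def normalized_l1_distance(
    simulated: np.ndarray, observed: np.ndarray
) -> float | np.ndarray:
    """Normalized L1 distance: ``sum |sim - obs| / (1 + obs)``.

    Sums over every observed species and time point present in the
    arrays; each absolute deviation is divided by one plus the datum, so
    abundant and rare species weigh comparably.  ``simulated`` may carry
    a leading ensemble axis, in which case one distance per member is
    returned.  Zero exactly when the simulation matches the data at
    every included point.
    """
    simulated = np.asarray(simulated, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    dev = np.abs(simulated - observed) / (1.0 + observed)
    if simulated.ndim > observed.ndim:
        return dev.reshape(simulated.shape[0], -1).sum(axis=1)
    return float(dev.sum())


def perturb_parameters(
    theta_hat: np.ndarray,
    perturbation: float,
    rng: np.random.Generator,
    n_draws: int | None = None,
) -> np.ndarray:
    """Independent uniform jitter on ``[(1-lambda) theta, (1+lambda) theta]``.

    Returns an (M,) draw, or (n_draws, M) when ``n_draws`` is given.
    ``lambda = 0`` is the exact identity.
    """
    if not 0 <= perturbation <= 1:
        raise ValueError("perturbation (lambda) must lie in [0, 1]")
    theta_hat = np.asarray(theta_hat, dtype=np.float64)
    shape = theta_hat.shape if n_draws is None else (n_draws, theta_hat.size)
    u = rng.random(shape)
    return theta_hat * (1.0 - perturbation + 2.0 * perturbation * u)


def select_and_split(
    ensemble: WeightedEnsemble,
    elite_count: int,
    rng: np.random.Generator,
) -> tuple[float, WeightedEnsemble]:
    """Elite threshold and splitting resample of an ensemble.

    ``delta`` is the ``elite_count``-th smallest cumulative distance; every
    member at or below it is elite (ties are all admitted, so the pool may
    exceed ``elite_count``).  Returns ``delta`` and a fresh ensemble of the
    same size drawn uniformly with replacement from the elite pool, each
    copy inheriting its parent's state, ancestry statistics and
    accumulated distance.
    """
    K = ensemble.size
    if K == 0:
        raise ValueError("cannot select from an empty ensemble")
    dist = ensemble.distances
    delta = float(np.partition(dist, elite_count - 1)[elite_count - 1])
    elite_idx = np.nonzero(dist <= delta)[0]
    pick = elite_idx[rng.integers(0, elite_idx.size, size=K)]
    return delta, ensemble.take(pick)


def ce_parameter_update(
    counts: np.ndarray, integrated_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled complete-data MLE over the selected (elite) trajectories.

    The elite-indicator in the CE update is realized by the selection, so
    the update is plain pooling: ``theta_j = sum r_j / sum H_j``.  Raises
    when some pooled ``H_j`` is zero — the reaction was structurally
    impossible on every elite trajectory.
    """
    counts = np.atleast_2d(counts)
    integrated_h = np.atleast_2d(integrated_h)
    if (integrated_h.sum(axis=0) == 0).any():
        raise ValueError(
            "pooled H_j = 0: a reaction is structurally impossible on all "
            "selected trajectories"
        )
    return pooled_mle(counts, integrated_h)


def run_ce_phase(
    network: ReactionNetwork,
    data: ObservedDataset,
    theta_init: np.ndarray | None = None,
    config: CEConfig | None = None,
    rng: np.random.Generator | None = None,
) -> "CEResult":
    """Run the modified CE phase until delta reaches zero or plateaus.

    Per iteration ``m``: for each observation interval, draw fresh
    perturbed rates per member, simulate forward, extend each member's
    cumulative distance with the normalized-L1 deviation at the interval
    end, and (except after the final interval) select-and-split.  The
    elite pool at the final interval feeds the pooled-MLE update.
    """
    config = config or CEConfig()
    rng = rng or np.random.default_rng()
    M = network.n_reactions
    theta = (
        np.ones(M) if theta_init is None else validate_theta(theta_init, M).copy()
    )
    order, s1, s2, net = network.kernel_tables()
    obs_idx = data.observed_indices
    times = np.concatenate([[0.0], data.times])
    K = config.ensemble_size
    trace: list[dict] = []
    deltas: list[float] = []
    total_events = 0

    for m in range(1, config.max_iterations + 1):
        ens = WeightedEnsemble.initial(data.x0, K, M)
        delta = math.inf
        for i in range(data.d):
            thetas = perturb_parameters(theta, config.perturbation, rng, n_draws=K)
            nev = _kernels.ensemble_interval(
                order, s1, s2, net, thetas, ens.states,
                float(times[i + 1] - times[i]),
                config.max_events_per_interval, rng,
                ens.counts, ens.integrated_h, ens.h_compensation,
            )
            if (nev < 0).any():
                raise RunawayError(
                    f"CE iteration {m}: ensemble member exceeded "
                    f"{config.max_events_per_interval} firings on interval "
                    f"[{times[i]}, {times[i + 1]}]"
                )
            total_events += int(nev.sum())
            ens.distances += normalized_l1_distance(
                ens.states[:, obs_idx], data.values[i]
            )
            if i < data.d - 1:
                delta, ens = select_and_split(ens, config.split_count, rng)
        # final interval: elite threshold under rho (no resampling)
        delta = float(
            np.partition(ens.distances, config.elite_count - 1)[config.elite_count - 1]
        )
        elite = ens.distances <= delta
        pooled_r = ens.counts[elite]
        pooled_h = ens.integrated_h[elite]
        theta_new, fired = pooled_mle(pooled_r, pooled_h)
        theta_new = shrink_unfired(theta_new, fired, theta)
        if not fired.all():
            logger.info(
                "CE m=%d: reactions %s never fired among elites; shrinking",
                m, np.nonzero(~fired)[0].tolist(),
            )
        theta = theta_new
        deltas.append(delta)
        trace.append(
            {
                "iteration": m,
                "delta": delta,
                "elite_size": int(elite.sum()),
                "events": total_events,
                **{f"theta_{j + 1}": float(theta[j]) for j in range(M)},
            }
        )
        logger.info("CE m=%d delta=%.6g elites=%d", m, delta, int(elite.sum()))
        if delta == 0.0:
            return CEResult(theta, True, False, trace, total_events)
        # plateau: the best delta achieved has stopped improving.  delta
        # fluctuates stochastically around its floor, so the criterion is
        # the relative improvement of the running minimum over the last
        # `plateau_window` iterations, not iteration-to-iteration change.
        w = config.plateau_window
        if len(deltas) > w:
            best_before = min(deltas[:-w])
            best_recent = min(deltas[-w:])
            if best_recent >= best_before * (1.0 - config.plateau_tolerance):
                logger.info("CE plateau at delta=%.6g after %d iterations", delta, m)
                return CEResult(theta, False, True, trace, total_events)

    raise CENonConvergenceError(
        f"CE phase did not reach delta = 0 within {config.max_iterations} "
        f"iterations (last delta = {deltas[-1]:.6g}). Consider increasing "
        f"ensemble_size to {10 * K} and lowering elite_fraction to "
        f"{config.elite_fraction / 10:g}, or rely on the plateau rule.",
        trace,
    )


@dataclass
class CEResult:
    """Outcome of the CE phase: ``theta_CE`` plus the per-iteration trace."""

    theta: np.ndarray
    converged: bool
    plateaued: bool
    trace: list[dict] = field(repr=False)
    total_events: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def deltas(self) -> np.ndarray:
        return np.array([rec["delta"] for rec in self.trace])

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)
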