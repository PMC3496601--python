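"""Ascent-based Monte Carlo EM refinement of the rate estimates.

Starting from the CE phase's estimate, each iteration draws ``K'``
trajectories that are *consistent* with the data — they pass through
every observed data point exactly — by incremental rejection sampling
between consecutive observation times.  The pooled complete-data MLE of
the consistent ensemble is the EM update.  Monte Carlo noise is managed
in the ascent-based manner: the update is accepted only when a normal
lower confidence bound on the estimated change in conditional
log-likelihood is non-negative, otherwise ``K'`` is enlarged and the
ensemble redrawn; the algorithm stops once an upper confidence bound on
that change stays below a small threshold for a few consecutive
iterations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from . import _kernels
from .network import (
    ObservedDataset,
    ReactionNetwork,
    SufficientStatistics,
    SystemState,
    pooled_mle,
    shrink_unfired,
    validate_theta,
)
from .simulate import RunawayError

__all__ = [
    "MCEMConfig",
    "MCEMResult",
    "ConsistentEnsemble",
    "ConsistentSegment",
    "RareEventError",
    "EventBudgetExceeded",
    "KPrimeCapError",
    "AscentDecision",
    "sample_consistent_segment",
    "draw_consistent_ensemble",
    "mcem_parameter_update",
    "ascent_control_update",
    "run_mcem",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCEMConfig:
    """Ascent-based MCEM control constants.

    ``alpha`` gates update acceptance (lower confidence bound), ``gamma``
    gates stopping (upper confidence bound), ``k`` sets the sample-size
    growth increment ``K' <- K' + ceil(K'/k)``.  ``beta`` is accepted for
    compatibility with the power-based sample-size rule but is unused by
    default.  Stopping requires the upper bound on the conditional
    log-likelihood change to fall below ``stop_tolerance`` for
    ``stop_consecutive`` consecutive iterations (set to 1 for expensive
    models).
    """

    k_prime_init: int = 10
    alpha: float = 0.25
    beta: float = 0.25
    k: int = 3
    gamma: float = 0.25
    stop_tolerance: float = 0.005
    stop_consecutive: int = 3
    max_iterations: int = 2000
    max_segment_retries: int = 1_000_000
    max_events_per_segment: int = 10_000_000
    max_k_prime: int = 100_000

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_prime_init < 1:
            raise ValueError("k_prime_init must be >= 1")


class RareEventError(RuntimeError):
    """Consistent-segment sampling exhausted its retry budget.

    Signals that the current rates make the data a rare event; the caller
    may re-enter the CE phase or raise the retry budget.
    """

    def __init__(self, message: str, acceptance_rate: float):
        super().__init__(message)
        self.acceptance_rate = acceptance_rate


class EventBudgetExceeded(RuntimeError):
    """A budgeted run spent its allotted simulated-event count."""

    def __init__(self, message: str, events: int):
        super().__init__(message)
        self.events = events


class KPrimeCapError(RuntimeError):
    """Sample-size growth exceeded the hard cap on K'."""


@dataclass
class ConsistentSegment:
    """One accepted inter-observation segment plus sampling diagnostics."""

    end_state: np.ndarray
    stats: SufficientStatistics
    attempts: int
    events: int


def sample_consistent_segment(
    network: ReactionNetwork,
    theta: np.ndarray,
    start_state: SystemState | np.ndarray,
    t_prev: float,
    t_i: float,
    target_obs: np.ndarray,
    observed_mask: np.ndarray,
    max_retries: int,
    rng: np.random.Generator,
    max_events: int = 10_000_000,
) -> ConsistentSegment:
    """Rejection-sample a segment over ``[t_prev, t_i]`` ending on the datum.

    The segment must match ``target_obs`` on every observed species at
    ``t_i``; unobserved species evolve freely and are carried forward in
    the returned end state.
    """
    theta = validate_theta(theta, network.n_reactions)
    x_start = (
        start_state.x if isinstance(start_state, SystemState) else np.asarray(start_state)
    ).astype(np.int64)
    order, s1, s2, net = network.kernel_tables()
    obs_idx = np.nonzero(np.asarray(observed_mask, dtype=bool))[0]
    target = np.asarray(target_obs, dtype=np.int64)
    x_out = np.empty_like(x_start)
    r_out = np.zeros(network.n_reactions, dtype=np.int64)
    H_out = np.zeros(network.n_reactions)
    status, attempts, events = _kernels.consistent_segment(
        order, s1, s2, net, theta, x_start, float(t_i - t_prev), obs_idx, target,
        int(max_retries), int(max_events), 2**62, rng, x_out, r_out, H_out,
    )
    if status == -2:
        raise RunawayError(
            f"segment [{t_prev}, {t_i}]: a single attempt exceeded {max_events} firings"
        )
    if status == -1:
        raise RareEventError(
            f"no consistent segment over [{t_prev}, {t_i}] in {max_retries} attempts "
            f"(empirical acceptance rate < {1.0 / max_retries:.2e}); the current "
            "rates make the data a rare event — consider re-entering the CE phase",
            acceptance_rate=0.0,
        )
    return ConsistentSegment(x_out, SufficientStatistics(r_out, H_out), attempts, events)


@dataclass
class ConsistentEnsemble:
    """``K'`` full-horizon trajectories consistent with every data point.

    Only the sufficient statistics are retained: per-trajectory firing
    counts (K', M) and integrated factors (K', M), which determine both
    the EM update and all log-likelihood differences.
    """

    counts: np.ndarray
    integrated_h: np.ndarray
    attempts: int
    events: int

    @property
    def size(self) -> int:
        return int(self.counts.shape[0])

    def log_likelihoods(self, theta: np.ndarray) -> np.ndarray:
        """Per-trajectory theta-kernel log-likelihood (log-h terms omitted:
        they cancel in every difference the ascent control takes)."""
        theta = np.asarray(theta, dtype=np.float64)
        return self.counts @ np.log(theta) - self.integrated_h @ theta


def draw_consistent_ensemble(
    network: ReactionNetwork,
    data: ObservedDataset,
    theta: np.ndarray,
    k_prime: int,
    config: MCEMConfig,
    rng: np.random.Generator,
    event_budget: int | None = None,
    events_so_far: int = 0,
) -> ConsistentEnsemble:
    """Draw ``K'`` data-consistent trajectories by segment-wise rejection.

    Each of the ``K'`` slots simulates the observation intervals in
    order, retrying a segment until its end state matches the datum on
    the observed species.  With partial observation each slot continues
    from its own simulated end state, so unobserved species are carried
    through; under full observation that state necessarily equals the
    datum.
    """
    theta = validate_theta(theta, network.n_reactions)
    order, s1, s2, net = network.kernel_tables()
    obs_idx = data.observed_indices
    times = np.concatenate([[0.0], data.times])
    M = network.n_reactions
    counts = np.zeros((k_prime, M), dtype=np.int64)
    integrated_h = np.zeros((k_prime, M))
    r_seg = np.zeros(M, dtype=np.int64)
    H_seg = np.zeros(M)
    x_out = np.empty_like(data.x0)
    attempts_total = 0
    events_total = events_so_far
    for kp in range(k_prime):
        x = data.x0.astype(np.int64).copy()
        for i in range(data.d):
            remaining = 2**62 if event_budget is None else event_budget - events_total
            status, attempts, events = _kernels.consistent_segment(
                order, s1, s2, net, theta, x,
                float(times[i + 1] - times[i]), obs_idx, data.values[i],
                config.max_segment_retries, config.max_events_per_segment,
                remaining, rng, x_out, r_seg, H_seg,
            )
            attempts_total += attempts
            events_total += events
            if status == -2:
                raise RunawayError(
                    f"trajectory {kp}, interval {i + 1}: an attempt exceeded "
                    f"{config.max_events_per_segment} firings"
                )
            if status == -3:
                raise EventBudgetExceeded(
                    f"simulated-event budget {event_budget} exhausted while drawing "
                    f"consistent trajectory {kp + 1}/{k_prime}",
                    events=events_total,
                )
            if status == -1:
                rate = attempts_total and k_prime * data.d / attempts_total
                raise RareEventError(
                    f"trajectory {kp}, interval {i + 1} ([{times[i]}, {times[i + 1]}]): "
                    f"no consistent segment in {config.max_segment_retries} attempts; "
                    "the current rates make the data a rare event — consider "
                    "re-entering the CE phase or raising max_segment_retries",
                    acceptance_rate=float(rate),
                )
            counts[kp] += r_seg
            integrated_h[kp] += H_seg
            x = x_out.copy()
    return ConsistentEnsemble(counts, integrated_h, attempts_total, events_total - events_so_far)


def mcem_parameter_update(ensemble: ConsistentEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """EM update: pooled complete-data MLE over the consistent ensemble.

    Raises when some pooled ``H_j`` is zero.  Returns ``(theta, fired)``
    with ``theta_j = 0`` for reactions that fired in no trajectory.
    """
    if ensemble.size < 1:
        raise ValueError("need at least one consistent trajectory")
    if (ensemble.integrated_h.sum(axis=0) == 0).any():
        raise ValueError("pooled H_j = 0 across the consistent ensemble")
    return pooled_mle(ensemble.counts, ensemble.integrated_h)


@dataclass(frozen=True)
class AscentDecision:
    accept: bool
    k_prime_next: int
    delta_q: float
    standard_error: float
    lower: float
    upper: float


def ascent_control_update(
    ensemble: ConsistentEnsemble,
    theta_new: np.ndarray,
    theta_old: np.ndarray,
    config: MCEMConfig,
    k_prime: int,
) -> AscentDecision:
    """Accept/reject an update from Monte Carlo confidence bounds.

    The per-trajectory log-likelihood differences ``l_k = log f_new -
    log f_old`` estimate the change in conditional log-likelihood with
    mean ``dQ`` and standard error ``sd(l)/sqrt(K')``.  If the lower
    ``1-alpha`` normal bound is negative the apparent ascent may be
    noise: reject and enlarge ``K' <- K' + ceil(K'/k)``.  Otherwise
    accept; the upper ``1-gamma`` bound is the stopping evidence.
    """
    ell = ensemble.log_likelihoods(theta_new) - ensemble.log_likelihoods(theta_old)
    dq = float(ell.mean())
    se = float(ell.std(ddof=1) / math.sqrt(ensemble.size)) if ensemble.size > 1 else 0.0
    z_alpha = float(_stats.norm.ppf(1.0 - config.alpha))
    z_gamma = float(_stats.norm.ppf(1.0 - config.gamma))
    lower = dq - z_alpha * se
    upper = dq + z_gamma * se
    if lower < 0.0:
        return AscentDecision(False, k_prime + math.ceil(k_prime / config.k), dq, se, lower, upper)
    return AscentDecision(True, k_prime, dq, se, lower, upper)


def run_mcem(
    network: ReactionNetwork,
    data: ObservedDataset,
    theta_init: np.ndarray,
    config: MCEMConfig | None = None,
    rng: np.random.Generator | None = None,
    event_budget: int | None = None,
) -> "MCEMResult":
    """Iterate draw / update / ascent-control until convergence.

    Returns the MLE, the last consistent ensemble and the iteration
    trace.  ``event_budget`` (total simulated firings, accepted or
    rejected) turns an over-expensive run into
    :class:`EventBudgetExceeded` — used by cost comparisons.
    """
    config = config or MCEMConfig()
    rng = rng or np.random.default_rng()
    theta = validate_theta(theta_init, network.n_reactions).copy()
    k_prime = config.k_prime_init
    consecutive = 0
    trace: list[dict] = []
    total_events = 0
    ensemble: ConsistentEnsemble | None = None
    converged = False
    M = network.n_reactions

    for n in range(1, config.max_iterations + 1):
        try:
            ensemble = draw_consistent_ensemble(
                network, data, theta, k_prime, config, rng,
                event_budget=event_budget, events_so_far=total_events,
            )
        except (RareEventError, EventBudgetExceeded) as exc:
            exc.trace = trace  # diagnostics for the caller
            raise
        total_events += ensemble.events
        theta_new, fired = pooled_mle(ensemble.counts, ensemble.integrated_h)
        theta_new = shrink_unfired(theta_new, fired, theta)
        decision = ascent_control_update(ensemble, theta_new, theta, config, k_prime)
        trace.append(
            {
                "iteration": n,
                "k_prime": k_prime,
                "accepted": decision.accept,
                "delta_q": decision.delta_q,
                "lower": decision.lower,
                "upper": decision.upper,
                "events": total_events,
                # ascent proxy: mean complete-data log-likelihood of the
                # consistent ensemble at the iteration's operative estimate
                "mean_loglik": float(
                    ensemble.log_likelihoods(
                        theta_new if decision.accept else theta
                    ).mean()
                ),
                **{f"theta_{j + 1}": float((theta_new if decision.accept else theta)[j]) for j in range(M)},
            }
        )
        logger.info(
            "MCEM n=%d K'=%d dQ=%.4g [%.4g, %.4g] %s",
            n, k_prime, decision.delta_q, decision.lower, decision.upper,
            "accept" if decision.accept else "reject",
        )
        if decision.accept:
            theta = theta_new
        # the upper bound certifies the change is small whether or not the
        # ascent was certified, so it counts toward stopping either way;
        # K' grows only when the change is both uncertified and possibly
        # larger than the stopping tolerance
        if decision.upper < config.stop_tolerance:
            consecutive += 1
            if consecutive >= config.stop_consecutive:
                converged = True
                break
        else:
            consecutive = 0
            if not decision.accept:
                k_prime = decision.k_prime_next
                if k_prime > config.max_k_prime:
                    raise KPrimeCapError(
                        f"K' growth reached {k_prime} > cap {config.max_k_prime} at "
                        f"iteration {n} (dQ={decision.delta_q:.4g}, "
                        f"SE={decision.standard_error:.4g}); the Monte Carlo noise "
                        "never certified an ascent"
                    )

    if not converged:
        logger.warning("MCEM stopped at max_iterations=%d without meeting the "
                       "stopping rule", config.max_iterations)
    return MCEMResult(theta, ensemble, trace, converged, total_events, k_prime)


@dataclass
class MCEMResult:
    """MLE, last consistent ensemble and per-iteration trace."""

    theta: np.ndarray
    ensemble: ConsistentEnsemble | None
    trace: list[dict] = field(repr=False)
    converged: bool = False
    total_events: int = 0
    k_prime_final: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)
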