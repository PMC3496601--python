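"""End-to-end estimation: CE initialization, MCEM refinement, uncertainty.

This is the three-step procedure most callers want: a modified
cross-entropy phase turns an uninformed starting vector (all ones by
default) into a plausible estimate; ascent-based MCEM refines it to the
MLE; a final consistent ensemble at the MLE yields the log-scale
covariance with confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ce import CEConfig, CEResult, run_ce_phase
from .mcem import MCEMConfig, MCEMResult, run_mcem
from .network import ObservedDataset, ReactionNetwork
from .streams import named_streams
from .uncertainty import CovarianceEstimate, confidence_interval, estimate_log_covariance

__all__ = ["FitResult", "fit"]

logger = logging.getLogger(__name__)

CI_LEVELS = (0.68, 0.95, 0.99)


@dataclass
class FitResult:
    """Estimates and traces from a full (or CE-skipped) fit."""

    theta_hat: np.ndarray
    ce: CEResult | None
    mcem: MCEMResult
    covariance: CovarianceEstimate | None = None
    seed: int | None = None

    @property
    def theta_ce(self) -> np.ndarray | None:
        return None if self.ce is None else self.ce.theta

    def intervals(self, level: float = 0.95) -> list[tuple[float, float] | None]:
        if self.covariance is None:
            raise ValueError("fit ran without uncertainty estimation")
        return [
            confidence_interval(self.covariance, j, level)
            for j in range(self.theta_hat.size)
        ]

    @property
    def total_events(self) -> int:
        ce_events = 0 if self.ce is None else self.ce.total_events
        return ce_events + self.mcem.total_events


def fit(
    network: ReactionNetwork,
    data: ObservedDataset,
    theta_init: np.ndarray | None = None,
    ce_config: CEConfig | None = None,
    mcem_config: MCEMConfig | None = None,
    *,
    skip_ce: bool = False,
    uncertainty_k_prime: int | None = 10_000,
    seed: int | None = None,
    event_budget: int | None = None,
) -> FitResult:
    """Fit rate constants to a discretely observed dataset.

    ``skip_ce`` runs plain ascent-based MCEM from ``theta_init`` — the
    baseline whose cost explodes when the start is far from the truth.
    ``uncertainty_k_prime=None`` skips the covariance step.  All phases
    draw from independent named substreams of ``seed``.
    """
    streams = named_streams(seed)
    theta0 = np.ones(network.n_reactions) if theta_init is None else np.asarray(theta_init, float)

    ce_result: CEResult | None = None
    if not skip_ce:
        ce_result = run_ce_phase(network, data, theta0, ce_config, streams["ce"])
        theta0 = ce_result.theta
        logger.info("CE phase done in %d iterations: theta_CE=%s",
                    ce_result.n_iterations, np.array2string(theta0, precision=4))

    mcem_result = run_mcem(
        network, data, theta0, mcem_config, streams["mcem"], event_budget=event_budget
    )
    logger.info("MCEM done in %d iterations (converged=%s): theta_hat=%s",
                mcem_result.n_iterations, mcem_result.converged,
                np.array2string(mcem_result.theta, precision=4))

    cov: CovarianceEstimate | None = None
    if uncertainty_k_prime is not None:
        cov = estimate_log_covariance(
            network, data, mcem_result.theta, uncertainty_k_prime,
            streams["uncertainty"], mcem_config,
        )
    return FitResult(mcem_result.theta, ce_result, mcem_result, cov, seed)
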