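"""MLE covariance on the log-rate scale; confidence intervals and ellipses.

The MLE ``theta_hat`` is modelled as log-normal: ``omega = log theta``
is asymptotically multivariate normal with covariance ``Sigma``,
estimated from a fresh ensemble of ``K'`` data-consistent trajectories
simulated at ``theta_hat``.  Writing per-trajectory score components
``s_j = r_j - theta_j H_j`` and curvature components ``theta_j H_j``,

    Sigma^{-1} = diag( mean_k theta_j H_jk )
                 - [ mean_k s_k s_k^T - (mean_k s_k)(mean_k s_k)^T ],

i.e. observed information minus excess score variance (the missing-data
correction).  Intervals and ellipse boundaries are computed for omega
under normality and mapped through ``exp`` componentwise, which keeps
every confidence bound strictly positive and warps ellipses on the
theta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .mcem import MCEMConfig, draw_consistent_ensemble
from .network import ObservedDataset, ReactionNetwork, validate_theta

__all__ = [
    "CovarianceEstimate",
    "estimate_log_covariance",
    "confidence_interval",
    "confidence_ellipse",
    "ellipse_contains",
]

logger = logging.getLogger(__name__)

CONDITION_LIMIT = 1e12


@dataclass
class CovarianceEstimate:
    """Log-scale mean ``omega_hat`` and covariance ``sigma_hat``.

    ``invalid[j]`` marks parameters whose interval is undefined (printed
    "n/a"): non-positive variance, failed inversion, or a reaction that
    never fired in the uncertainty ensemble.
    """

    omega_hat: np.ndarray
    sigma_hat: np.ndarray
    k_prime: int
    invalid: np.ndarray

    @property
    def theta_hat(self) -> np.ndarray:
        return np.exp(self.omega_hat)

    def __post_init__(self) -> None:
        if not np.allclose(self.sigma_hat, self.sigma_hat.T, equal_nan=True):
            raise ValueError("sigma_hat must be symmetric")


def estimate_log_covariance(
    network: ReactionNetwork,
    data: ObservedDataset,
    theta_hat: np.ndarray,
    k_prime: int = 10_000,
    rng: np.random.Generator | None = None,
    config: MCEMConfig | None = None,
) -> CovarianceEstimate:
    """Estimate ``Sigma`` from ``K'`` consistent trajectories at ``theta_hat``.

    A singular information matrix does not raise: the affected
    parameters are flagged and their intervals render as "n/a".  The
    second-moment terms are assembled from centred score vectors in one
    pass with float64 accumulation over the ensemble axis.
    """
    theta_hat = validate_theta(theta_hat, network.n_reactions)
    rng = rng or np.random.default_rng()
    config = config or MCEMConfig()
    ensemble = draw_consistent_ensemble(network, data, theta_hat, k_prime, config, rng)
    theta_h = ensemble.integrated_h * theta_hat  # (K', M) curvature components
    scores = ensemble.counts - theta_h  # (K', M) score components
    mean_curv = theta_h.mean(axis=0)
    s_bar = scores.mean(axis=0)
    centered = scores - s_bar
    # mean(s s^T) - s_bar s_bar^T  ==  mean of centred outer products
    excess = centered.T @ centered / ensemble.size
    info = np.diag(mean_curv) - excess  # = Sigma^{-1}
    M = network.n_reactions
    invalid = ensemble.counts.sum(axis=0) == 0

    w, V = np.linalg.eigh(info)
    w_max = float(np.abs(w).max())
    bad = (w <= 0) | (np.abs(w) * CONDITION_LIMIT < w_max)
    if bad.any():
        logger.warning(
            "information matrix not positive definite (eigenvalues %s); "
            "flagging all parameters", np.array2string(w, precision=3)
        )
        sigma = np.full((M, M), np.nan)
        sigma[np.diag_indices(M)] = np.nan
        invalid = np.ones(M, dtype=bool)
    else:
        sigma = (V / w) @ V.T
        sigma = (sigma + sigma.T) / 2.0
        invalid = invalid | (np.diag(sigma) <= 0)
    return CovarianceEstimate(np.log(theta_hat), sigma, k_prime, invalid)


def confidence_interval(
    estimate: CovarianceEstimate, j: int, level: float = 0.95
) -> tuple[float, float] | None:
    """Two-sided interval for ``theta_j``: ``exp(omega_j +- z sqrt(Sigma_jj))``.

    Returns None (rendered "n/a") for flagged parameters.  Bounds are
    strictly positive by construction; a zero variance collapses the
    interval onto the point estimate.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if estimate.invalid[j]:
        return None
    z = float(_stats.norm.ppf((1.0 + level) / 2.0))
    half = z * np.sqrt(estimate.sigma_hat[j, j])
    return (
        float(np.exp(estimate.omega_hat[j] - half)),
        float(np.exp(estimate.omega_hat[j] + half)),
    )


def _pair_submatrix(estimate: CovarianceEstimate, pair: tuple[int, int]) -> np.ndarray:
    j, l = pair
    return estimate.sigma_hat[np.ix_([j, l], [j, l])]


def confidence_ellipse(
    estimate: CovarianceEstimate,
    pair: tuple[int, int],
    level: float = 0.95,
    n_points: int = 200,
) -> np.ndarray | None:
    """Boundary of the level-``q`` confidence ellipse for a rate pair.

    Points ``exp(omega_pair + sqrt(chi2_2(q)) L (cos phi, sin phi)^T)``
    with ``L`` the Cholesky factor of the 2x2 log-scale submatrix; the
    componentwise ``exp`` warps the ellipse on the theta scale.  Returns
    None when the submatrix is not positive definite.
    """
    j, l = pair
    if estimate.invalid[j] or estimate.invalid[l]:
        return None
    sub = _pair_submatrix(estimate, pair)
    try:
        L = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError:
        return None
    radius = np.sqrt(_stats.chi2.ppf(level, df=2))
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=True)
    circle = np.stack([np.cos(phi), np.sin(phi)])  # (2, n)
    omega = estimate.omega_hat[[j, l]][:, None] + radius * (L @ circle)
    return np.exp(omega.T)  # (n_points, 2) on the theta scale


def ellipse_contains(
    estimate: CovarianceEstimate,
    pair: tuple[int, int],
    theta_point: tuple[float, float],
    level: float = 0.95,
) -> bool:
    """Whether a rate pair lies inside the level-``q`` ellipse.

    Containment on the theta scale is the quadratic form of
    ``log(theta_point) - omega_pair`` under the inverse 2x2 submatrix
    being at most ``chi2_2(q)``.
    """
    j, l = pair
    if estimate.invalid[j] or estimate.invalid[l]:
        raise ValueError("ellipse undefined for flagged parameters")
    sub = _pair_submatrix(estimate, pair)
    diff = np.log(np.asarray(theta_point, dtype=np.float64)) - estimate.omega_hat[[j, l]]
    q = float(diff @ np.linalg.solve(sub, diff))
    return q <= float(_stats.chi2.ppf(level, df=2))
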