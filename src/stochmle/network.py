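"""Mass-action reaction networks, complete trajectories and their likelihood.

A well-stirred chemical system with ``N`` species is described by ``M``
mass-action reactions.  Reaction ``j`` fires with propensity
``a_j(x) = theta_j * h_j(x)`` where ``theta_j`` is a positive kinetic
constant (units 1/time) and ``h_j(x)`` counts the number of distinct
reactant combinations in state ``x``:

* zeroth order:            ``h = 1``
* unimolecular (A -> .):   ``h = x_A``
* homo-bimolecular (2A):   ``h = x_A (x_A - 1) / 2``
* hetero-bimolecular (A+B):``h = x_A x_B``

A complete trajectory over ``[0, T]`` is the firing record
``z = ((tau_1, j_1), ..., (tau_r, j_r))`` plus the residual interval
``tau_{r+1}`` up to the horizon.  Its log-likelihood is

    log f_theta(x0, z) = sum_j [ r_j log theta_j - theta_j H_j ]
                         + sum_i log h_{j_i}(x_{i-1}),

with ``r_j`` the number of firings of reaction ``j`` and
``H_j = sum_i h_j(x_{i-1}) tau_i`` the combinatorial factor integrated
along the piecewise-constant state path (residual interval included).
The pair ``(r_j, H_j)`` is sufficient: the complete-data MLE is
``theta_j = r_j / H_j`` per reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SystemState",
    "CompleteTrajectory",
    "SufficientStatistics",
    "ObservedDataset",
    "InvalidTrajectoryError",
    "evaluate_h",
    "evaluate_propensities",
    "apply_reaction",
    "sufficient_statistics",
    "complete_log_likelihood",
    "complete_data_mle",
    "validate_theta",
]

# reaction order codes used by the numba kernels
ZEROTH, UNIMOLECULAR, HOMO_BIMOLECULAR, HETERO_BIMOLECULAR = 0, 1, 2, 3

_ORDER_NAMES = {
    ZEROTH: "zeroth",
    UNIMOLECULAR: "unimolecular",
    HOMO_BIMOLECULAR: "homo-bimolecular",
    HETERO_BIMOLECULAR: "hetero-bimolecular",
}


class InvalidTrajectoryError(ValueError):
    """A trajectory fired a reaction from a state where it cannot occur."""


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction given by reactant and product stoichiometry.

    Stoichiometries are per-species non-negative integer vectors over the
    network's species ordering.  Total reactant molecularity must be <= 2;
    the reaction order is derived from the reactant stoichiometry.
    """

    reactant_stoichiometry: np.ndarray
    product_stoichiometry: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        rs = np.asarray(self.reactant_stoichiometry, dtype=np.int64)
        ps = np.asarray(self.product_stoichiometry, dtype=np.int64)
        if rs.ndim != 1 or ps.shape != rs.shape:
            raise ValueError("stoichiometry vectors must be 1-D and congruent")
        if (rs < 0).any() or (ps < 0).any():
            raise ValueError("stoichiometric coefficients must be non-negative")
        if rs.sum() > 2:
            raise ValueError(
                f"reaction {self.name or rs}: total reactant molecularity "
                f"{int(rs.sum())} > 2 is not supported (mass action of order <= 2)"
            )
        object.__setattr__(self, "reactant_stoichiometry", rs)
        object.__setattr__(self, "product_stoichiometry", ps)

    @property
    def order_code(self) -> int:
        rs = self.reactant_stoichiometry
        total = int(rs.sum())
        if total == 0:
            return ZEROTH
        if total == 1:
            return UNIMOLECULAR
        return HOMO_BIMOLECULAR if int(rs.max()) == 2 else HETERO_BIMOLECULAR

    @property
    def order(self) -> str:
        return _ORDER_NAMES[self.order_code]

    @property
    def net_change(self) -> np.ndarray:
        return self.product_stoichiometry - self.reactant_stoichiometry


@dataclass(frozen=True)
class ReactionNetwork:
    """Species names plus an ordered list of mass-action reactions."""

    species_names: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __init__(self, species_names: Sequence[str], reactions: Iterable[Reaction]):
        species = tuple(species_names)
        if len(species) < 1:
            raise ValueError("a network needs at least one species")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species names")
        rxns = tuple(reactions)
        if len(rxns) < 1:
            raise ValueError("a network needs at least one reaction")
        for rxn in rxns:
            if rxn.reactant_stoichiometry.shape[0] != len(species):
                raise ValueError("reaction stoichiometry length != number of species")
        object.__setattr__(self, "species_names", species)
        object.__setattr__(self, "reactions", rxns)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- dense views used by simulation kernels -------------------------------
    @property
    def reactant_matrix(self) -> np.ndarray:
        return np.stack([r.reactant_stoichiometry for r in self.reactions])

    @property
    def product_matrix(self) -> np.ndarray:
        return np.stack([r.product_stoichiometry for r in self.reactions])

    @property
    def net_matrix(self) -> np.ndarray:
        return self.product_matrix - self.reactant_matrix

    def kernel_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(order_code, species_1, species_2, net_change) arrays for kernels.

        ``species_2`` is -1 except for hetero-bimolecular reactions.
        """
        M = self.n_reactions
        order = np.empty(M, dtype=np.int64)
        s1 = np.full(M, -1, dtype=np.int64)
        s2 = np.full(M, -1, dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            order[j] = rxn.order_code
            idx = np.nonzero(rxn.reactant_stoichiometry)[0]
            if order[j] == UNIMOLECULAR or order[j] == HOMO_BIMOLECULAR:
                s1[j] = idx[0]
            elif order[j] == HETERO_BIMOLECULAR:
                s1[j], s2[j] = idx[0], idx[1]
        return order, s1, s2, self.net_matrix


@dataclass
class SystemState:
    """Molecule counts at a point in time."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        if (self.x < 0).any():
            raise ValueError("molecule counts must be non-negative")
        if self.t < 0:
            raise ValueError("time must be non-negative")


@dataclass
class CompleteTrajectory:
    """Full firing record over ``[0, T]`` starting from ``x0``.

    ``waiting_times[i]`` is the exponential waiting time before the i-th
    firing and ``reaction_indices[i]`` the reaction that fired;
    ``terminal_residual`` is the quiet interval between the last firing
    and the horizon ``T``.
    """

    x0: np.ndarray
    waiting_times: np.ndarray
    reaction_indices: np.ndarray
    terminal_residual: float
    horizon: float

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.int64)
        self.waiting_times = np.asarray(self.waiting_times, dtype=np.float64)
        self.reaction_indices = np.asarray(self.reaction_indices, dtype=np.int64)
        if self.waiting_times.shape != self.reaction_indices.shape:
            raise ValueError("waiting times and reaction indices must align")
        if (self.waiting_times <= 0).any():
            raise ValueError("waiting times must be positive")
        if self.terminal_residual < 0:
            raise ValueError("terminal residual must be non-negative")
        total = math.fsum(self.waiting_times) + self.terminal_residual
        if not math.isclose(total, self.horizon, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"waiting times + residual ({total}) do not sum to horizon {self.horizon}"
            )

    @property
    def n_events(self) -> int:
        return int(self.waiting_times.shape[0])

    def replay(self, network: ReactionNetwork) -> Iterator[tuple[np.ndarray, float, int]]:
        """Yield ``(state_before, tau, j)`` per event, then ``(state, residual, -1)``."""
        x = self.x0.copy()
        net = network.net_matrix
        for tau, j in zip(self.waiting_times, self.reaction_indices):
            yield x.copy(), float(tau), int(j)
            x = x + net[int(j)]
            if (x < 0).any():
                raise InvalidTrajectoryError(
                    f"replay drove species counts negative after reaction {j}"
                )
        yield x.copy(), float(self.terminal_residual), -1

    def state_at(self, network: ReactionNetwork, t: float) -> np.ndarray:
        """State at time ``t`` (closed on the right: firings at t count)."""
        x = self.x0.copy()
        elapsed = 0.0
        net = network.net_matrix
        for tau, j in zip(self.waiting_times, self.reaction_indices):
            elapsed += tau
            if elapsed > t:
                break
            x = x + net[int(j)]
        return x


@dataclass
class SufficientStatistics:
    """Per-reaction firing counts ``r_j`` and integrated factors ``H_j``."""

    counts: np.ndarray
    integrated_h: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.integrated_h = np.asarray(self.integrated_h, dtype=np.float64)
        if self.counts.shape != self.integrated_h.shape:
            raise ValueError("counts and integrated_h must align")
        if (self.counts < 0).any() or (self.integrated_h < 0).any():
            raise ValueError("sufficient statistics must be non-negative")


@dataclass
class ObservedDataset:
    """Initial full state plus counts of observed species at ``d`` times.

    ``values[i, :]`` holds the counts of the observed species (in species
    order restricted by ``observed_mask``) at time ``times[i]``.  ``x0`` is
    always fully observed and is separate from the ``d`` observations.
    """

    x0: np.ndarray
    times: np.ndarray
    observed_mask: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.times.ndim != 1 or (np.diff(self.times) <= 0).any():
            raise ValueError("observation times must be strictly increasing")
        if (self.times <= 0).any():
            raise ValueError("observation times must be positive (x0 holds t=0)")
        if not self.observed_mask.any():
            raise ValueError("at least one species must be observed")
        if self.values.shape != (self.times.size, int(self.observed_mask.sum())):
            raise ValueError("values must be d x (#observed species)")
        if (self.values < 0).any():
            raise ValueError("observed counts must be non-negative")

    @property
    def d(self) -> int:
        return int(self.times.size)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    @property
    def observed_indices(self) -> np.ndarray:
        return np.nonzero(self.observed_mask)[0]

    @property
    def fully_observed(self) -> bool:
        return bool(self.observed_mask.all())


# --------------------------------------------------------------------------
# propensity algebra


def evaluate_h(network: ReactionNetwork, j: int, state: SystemState | np.ndarray) -> int:
    """Number of distinct reactant combinations for reaction ``j`` in ``state``.

    Returns 0 whenever the state lacks the required reactants.
    """
    x = state.x if isinstance(state, SystemState) else np.asarray(state)
    rxn = network.reactions[j]
    code = rxn.order_code
    if code == ZEROTH:
        return 1
    idx = np.nonzero(rxn.reactant_stoichiometry)[0]
    if code == UNIMOLECULAR:
        return int(x[idx[0]])
    if code == HOMO_BIMOLECULAR:
        n = int(x[idx[0]])
        return n * (n - 1) // 2
    if code == HETERO_BIMOLECULAR:
        return int(x[idx[0]]) * int(x[idx[1]])
    raise ValueError(f"unknown reaction order code {code}")  # pragma: no cover


def evaluate_propensities(
    network: ReactionNetwork, theta: np.ndarray, state: SystemState | np.ndarray
) -> tuple[np.ndarray, float]:
    """Propensities ``a_j = theta_j h_j(x)`` and their total ``a0``."""
    theta = validate_theta(theta, network.n_reactions)
    a = np.array(
        [theta[j] * evaluate_h(network, j, state) for j in range(network.n_reactions)]
    )
    return a, float(a.sum())


def apply_reaction(
    network: ReactionNetwork, state: SystemState, j: int
) -> SystemState:
    """State after firing reaction ``j`` (time unchanged)."""
    new_x = state.x + network.reactions[j].net_change
    if (new_x < 0).any():
        # h_j = 0 forbids firing from such states; reaching here means the
        # caller fired a reaction the propensity algebra rules out
        raise InvalidTrajectoryError(
            f"firing reaction {j} from x={state.x.tolist()} yields a negative count"
        )
    return SystemState(new_x, state.t)


def validate_theta(theta: Sequence[float] | np.ndarray, m: int | None = None) -> np.ndarray:
    theta = np.asarray(theta, dtype=np.float64)
    if m is not None and theta.shape != (m,):
        raise ValueError(f"theta must have length {m}, got shape {theta.shape}")
    if not np.isfinite(theta).all() or (theta <= 0).any():
        raise ValueError("kinetic constants must be finite and strictly positive")
    return theta


# --------------------------------------------------------------------------
# sufficient statistics and likelihood


def sufficient_statistics(
    network: ReactionNetwork, trajectory: CompleteTrajectory
) -> SufficientStatistics:
    """Firing counts and integrated combinatorial factors of a trajectory.

    ``H_j`` is accumulated with compensated (Kahan) summation: horizons are
    routinely split into 1e4-1e6 waiting times and the per-interval terms
    can span many orders of magnitude.
    """
    M = network.n_reactions
    counts = np.zeros(M, dtype=np.int64)
    H = np.zeros(M, dtype=np.float64)
    comp = np.zeros(M, dtype=np.float64)
    for x, tau, j in trajectory.replay(network):
        for jj in range(M):
            term = evaluate_h(network, jj, x) * tau - comp[jj]
            total = H[jj] + term
            comp[jj] = (total - H[jj]) - term
            H[jj] = total
        if j >= 0:
            counts[j] += 1
    return SufficientStatistics(counts, H)


def complete_log_likelihood(
    network: ReactionNetwork,
    theta: np.ndarray,
    trajectory: CompleteTrajectory,
    *,
    theta_kernel_only: bool = False,
) -> float:
    """Log-likelihood of a complete trajectory.

    With ``theta_kernel_only=True`` the theta-independent ``log h`` terms
    are dropped, leaving ``sum_j [r_j log theta_j - theta_j H_j]`` — the
    part that matters for optimisation over theta.
    """
    theta = validate_theta(theta, network.n_reactions)
    stats = sufficient_statistics(network, trajectory)
    ll = log_likelihood_from_stats(theta, stats)
    if theta_kernel_only:
        return ll
    log_h = 0.0
    for x, _tau, j in trajectory.replay(network):
        if j < 0:
            continue
        h = evaluate_h(network, j, x)
        if h == 0:
            raise InvalidTrajectoryError(
                f"reaction {j} fired from state {x.tolist()} where h_j = 0"
            )
        log_h += math.log(h)
    return ll + log_h


def log_likelihood_from_stats(theta: np.ndarray, stats: SufficientStatistics) -> float:
    """Theta-dependent kernel ``sum_j [r_j log theta_j - theta_j H_j]``."""
    return float(np.sum(stats.counts * np.log(theta) - theta * stats.integrated_h))


def complete_data_mle(stats: SufficientStatistics) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction closed-form MLE ``theta_j = r_j / H_j``.

    Returns ``(theta_hat, fired)`` where ``fired[j]`` is False for
    reactions that never fired; their component is 0 and the caller
    decides how to handle it (the CE phase shrinks instead of zeroing).
    """
    counts, H = stats.counts, stats.integrated_h
    if ((H == 0) & (counts > 0)).any():
        raise ValueError("H_j = 0 with r_j > 0 violates trajectory invariants")
    fired = counts > 0
    theta = np.zeros_like(H)
    np.divide(counts, H, out=theta, where=fired)
    return theta, fired


def pooled_mle(
    counts: np.ndarray, integrated_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled complete-data MLE over a set of trajectories.

    ``counts`` and ``integrated_h`` are (n_trajectories, M); the estimate
    is ``theta_j = sum_k r_jk / sum_k H_jk``, the single-trajectory MLE
    applied to the pooled sufficient statistics.  Both the cross-entropy
    update (over elite trajectories) and the Monte Carlo EM update (over
    data-consistent trajectories) are this computation — they coincide
    when their selections pick the same set.

    Returns ``(theta, fired)``; ``theta_j`` is 0 where no trajectory fired
    reaction ``j`` (callers substitute a shrink policy, see
    :func:`shrink_unfired`).  Raises when a reaction fired but accumulated
    no combinatorial factor, which violates trajectory invariants.
    """
    counts = np.atleast_2d(np.asarray(counts))
    integrated_h = np.atleast_2d(np.asarray(integrated_h, dtype=np.float64))
    r = counts.sum(axis=0)
    H = integrated_h.sum(axis=0)
    return complete_data_mle(SufficientStatistics(r, H))


SHRINK_FACTOR = 10.0
SHRINK_FLOOR = 1e-10


def shrink_unfired(
    theta_new: np.ndarray, fired: np.ndarray, theta_prev: np.ndarray
) -> np.ndarray:
    """Replace zero estimates of never-fired reactions by a geometric shrink.

    A reaction with no firings among the selected trajectories would get
    ``theta_j = 0``, freezing it forever.  Instead its previous estimate
    is divided by 10 (floored at 1e-10): the data say the reaction is
    rare, but exploration must stay possible.
    """
    out = np.where(fired, theta_new, np.maximum(theta_prev / SHRINK_FACTOR, SHRINK_FLOOR))
    return out
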