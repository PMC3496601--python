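"""Built-in benchmark models: five stochastic systems of increasing size.

Each entry returns the exact published configuration — network, true rate
constants, initial state, horizon ``T`` and number of observation times
``d`` — used throughout the test-bench experiments:

* ``pure_birth``               0 -> S (homogeneous Poisson process)
* ``birth_death``              0 -> S, S -> 0, started in equilibrium
* ``birth_death_modified``     birth-death suite with equilibrium tending to 0
* ``decay_dimer_reversible``   decay + reversible dimerization (3 reactions)
* ``decay_dimer_irreversible`` decay + irreversible dimerization (3 reactions)
* ``decay_dimer_4rxn``         reversible dimerization + conversion (4 reactions)
* ``autoreg``                  prokaryotic auto-regulatory gene network (8 reactions)
* ``yeast_polarization``       pheromone-induced G-protein cycle (8 reactions)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Reaction, ReactionNetwork

__all__ = ["BuiltinModel", "builtin_model", "modified_birth_death_suite", "BUILTIN_MODELS"]


@dataclass(frozen=True)
class BuiltinModel:
    name: str
    network: ReactionNetwork
    theta_star: np.ndarray
    x0: np.ndarray
    horizon: float
    d: int


def _rxn(species: list[str], reactants: dict[str, int], products: dict[str, int], name: str) -> Reaction:
    rs = np.array([reactants.get(s, 0) for s in species], dtype=np.int64)
    ps = np.array([products.get(s, 0) for s in species], dtype=np.int64)
    return Reaction(rs, ps, name=name)


def _pure_birth() -> BuiltinModel:
    sp = ["S"]
    net = ReactionNetwork(sp, [_rxn(sp, {}, {"S": 1}, "birth")])
    return BuiltinModel("pure_birth", net, np.array([1.0]), np.array([0]), 1000.0, 30)


def _birth_death() -> BuiltinModel:
    sp = ["S"]
    net = ReactionNetwork(
        sp,
        [_rxn(sp, {}, {"S": 1}, "birth"), _rxn(sp, {"S": 1}, {}, "death")],
    )
    return BuiltinModel("birth_death", net, np.array([1.0, 0.06]), np.array([17]), 200.0, 40)


# Birth-death suite whose equilibrium value theta1/theta2 steps down from 5
# to .1; each variant starts roughly at its stochastic equilibrium.
_MODIFIED_THETA2 = (0.1, 0.5, 1.0, 2.5, 5.0)
_MODIFIED_X0 = (5, 1, 1, 1, 1)


def _birth_death_modified(variant: int = 0) -> BuiltinModel:
    if not 0 <= variant < len(_MODIFIED_THETA2):
        raise ValueError(f"variant must be in 0..{len(_MODIFIED_THETA2) - 1}")
    base = _birth_death()
    return BuiltinModel(
        "birth_death_modified",
        base.network,
        np.array([0.5, _MODIFIED_THETA2[variant]]),
        np.array([_MODIFIED_X0[variant]]),
        25.0,
        25,
    )


def modified_birth_death_suite() -> list[BuiltinModel]:
    """All five modified birth-death variants, in published order."""
    return [_birth_death_modified(v) for v in range(len(_MODIFIED_THETA2))]


def _decay_dimer(third: str) -> BuiltinModel:
    sp = ["S1", "S2"]
    rxns = [
        _rxn(sp, {"S1": 1}, {}, "decay"),
        _rxn(sp, {"S1": 2}, {"S2": 1}, "dimerization"),
    ]
    if third == "reversible":
        rxns.append(_rxn(sp, {"S2": 1}, {"S1": 2}, "dissociation"))
        name = "decay_dimer_reversible"
    else:
        rxns.append(_rxn(sp, {"S2": 1}, {}, "dimer_decay"))
        name = "decay_dimer_irreversible"
    net = ReactionNetwork(sp, rxns)
    return BuiltinModel(name, net, np.array([0.2, 0.04, 0.5]), np.array([40, 0]), 5.0, 25)


def _decay_dimer_4rxn() -> BuiltinModel:
    sp = ["S1", "S2", "S3"]
    net = ReactionNetwork(
        sp,
        [
            _rxn(sp, {"S1": 1}, {}, "decay"),
            _rxn(sp, {"S1": 2}, {"S2": 1}, "dimerization"),
            _rxn(sp, {"S2": 1}, {"S1": 2}, "dissociation"),
            _rxn(sp, {"S2": 1}, {"S3": 1}, "conversion"),
        ],
    )
    return BuiltinModel(
        "decay_dimer_4rxn",
        net,
        np.array([0.2, 0.04, 0.5, 1.0]),
        np.array([1000, 10, 10]),
        0.1,
        5,
    )


def _autoreg() -> BuiltinModel:
    sp = ["DNA", "DNA.P2", "mRNA", "P", "P2"]
    net = ReactionNetwork(
        sp,
        [
            _rxn(sp, {"DNA": 1, "P2": 1}, {"DNA.P2": 1}, "repression"),
            _rxn(sp, {"DNA.P2": 1}, {"DNA": 1, "P2": 1}, "derepression"),
            _rxn(sp, {"DNA": 1}, {"DNA": 1, "mRNA": 1}, "transcription"),
            _rxn(sp, {"mRNA": 1}, {}, "mRNA_decay"),
            _rxn(sp, {"P": 2}, {"P2": 1}, "dimerization"),
            _rxn(sp, {"P2": 1}, {"P": 2}, "dissociation"),
            _rxn(sp, {"mRNA": 1}, {"mRNA": 1, "P": 1}, "translation"),
            _rxn(sp, {"P": 1}, {}, "P_decay"),
        ],
    )
    return BuiltinModel(
        "autoreg",
        net,
        np.array([0.1, 0.7, 0.35, 0.3, 0.1, 0.9, 0.2, 0.1]),
        np.array([7, 3, 10, 10, 10]),
        50.0,
        100,
    )


def _yeast_polarization() -> BuiltinModel:
    sp = ["R", "L", "RL", "G", "Ga", "Gbg", "Gd"]
    net = ReactionNetwork(
        sp,
        [
            _rxn(sp, {}, {"R": 1}, "receptor_synthesis"),
            _rxn(sp, {"R": 1}, {}, "receptor_decay"),
            _rxn(sp, {"L": 1, "R": 1}, {"RL": 1, "L": 1}, "ligand_binding"),
            _rxn(sp, {"RL": 1}, {"R": 1}, "complex_decay"),
            _rxn(sp, {"RL": 1, "G": 1}, {"Ga": 1, "Gbg": 1}, "G_activation"),
            _rxn(sp, {"Ga": 1}, {"Gd": 1}, "Ga_deactivation"),
            _rxn(sp, {"Gd": 1, "Gbg": 1}, {"G": 1}, "G_reassociation"),
            _rxn(sp, {}, {"RL": 1}, "complex_synthesis"),
        ],
    )
    return BuiltinModel(
        "yeast_polarization",
        net,
        np.array([0.38, 0.04, 0.082, 0.12, 0.021, 0.1, 0.005, 13.21]),
        np.array([500, 4, 110, 300, 2, 20, 90]),
        5.0,
        15,
    )


_FACTORIES = {
    "pure_birth": _pure_birth,
    "birth_death": _birth_death,
    "birth_death_modified": _birth_death_modified,
    "decay_dimer_reversible": lambda: _decay_dimer("reversible"),
    "decay_dimer_irreversible": lambda: _decay_dimer("irreversible"),
    "decay_dimer_4rxn": _decay_dimer_4rxn,
    "autoreg": _autoreg,
    "yeast_polarization": _yeast_polarization,
}

BUILTIN_MODELS = tuple(sorted(_FACTORIES))


def builtin_model(name: str, variant: int = 0) -> BuiltinModel:
    """Look up a built-in benchmark model by name.

    ``variant`` selects among the five ``birth_death_modified`` settings
    (theta2* = .1, .5, 1, 2.5, 5) and is ignored elsewhere.
    """
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid names: {', '.join(BUILTIN_MODELS)}"
        ) from None
    if name == "birth_death_modified":
        return factory(variant)
    return factory()
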