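"""File formats: model specs (YAML), datasets (CSV), results (JSON).

Model spec
----------
A YAML document with a species list and reactions written as
``reactants -> products`` equations with named rate parameters::

    species: [S1, S2]
    reactions:
      - equation: S1 -> 0
        rate: k1
      - equation: S1 + S1 -> S2
        rate: k2
    parameters:        # optional true values
      k1: 0.2
      k2: 0.04

Stoichiometric coefficients may be written ``2 S1`` or by repeating the
species; ``0`` or an empty side denotes no reactants/products.

Dataset
-------
A delimited table whose first column is time and remaining columns are
species (header names must match the network).  Row 0 is ``t = 0`` with
the full initial state; blank/NA cells mark unobserved species at the
later times.  A species must be either observed at every ``t > 0`` or at
none of them.

Results
-------
A JSON document with the point estimates, log-scale covariance,
confidence intervals at 68/95/99% ("n/a" entries serialized as nulls),
both phase traces, the seed and a config echo — enough to regenerate
trace plots and to re-run the fit bit-for-bit.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .network import ObservedDataset, Reaction, ReactionNetwork

__all__ = [
    "ModelSpecError",
    "read_model_spec",
    "write_model_spec",
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
]


class ModelSpecError(ValueError):
    """Malformed model specification file."""


_TERM_RE = re.compile(r"^(?:(\d+)\s*\*?\s*)?([A-Za-z_][\w.\-]*)$")


def _parse_side(side: str, species: list[str], context: str) -> np.ndarray:
    stoich = np.zeros(len(species), dtype=np.int64)
    side = side.strip()
    if side in ("", "0", "∅", "[]", "null"):
        return stoich
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ModelSpecError(f"{context}: cannot parse term {term!r}")
        coeff = int(m.group(1) or 1)
        name = m.group(2)
        if name not in species:
            raise ModelSpecError(f"{context}: unknown species {name!r}")
        stoich[species.index(name)] += coeff
    return stoich


def read_model_spec(path: str | Path) -> tuple[ReactionNetwork, np.ndarray | None]:
    """Load a network (and optional true rates) from a YAML model spec.

    Species keep the file's ordering.  Reactions of total reactant
    molecularity above two are rejected with the offending equation.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise ModelSpecError(f"{path}: expected mapping with 'species' and 'reactions'")
    species = [str(s) for s in doc["species"]]
    if len(set(species)) != len(species):
        raise ModelSpecError(f"{path}: duplicate species names")
    reactions = []
    rate_names = []
    for idx, entry in enumerate(doc["reactions"], start=1):
        context = f"{path}: reaction {idx}"
        if not isinstance(entry, dict) or "equation" not in entry:
            raise ModelSpecError(f"{context}: expected mapping with an 'equation'")
        eq = str(entry["equation"])
        if "->" not in eq:
            raise ModelSpecError(f"{context}: equation {eq!r} lacks '->'")
        lhs, rhs = eq.split("->", 1)
        reactants = _parse_side(lhs, species, context)
        products = _parse_side(rhs, species, context)
        if reactants.sum() > 2:
            raise ModelSpecError(
                f"{context}: total reactant molecularity {int(reactants.sum())} > 2 "
                f"in {eq!r}; only mass-action reactions of order <= 2 are supported"
            )
        name = str(entry.get("rate", f"theta{idx}"))
        reactions.append(Reaction(reactants, products, name=name))
        rate_names.append(name)
    network = ReactionNetwork(species, reactions)
    theta = None
    if "parameters" in doc and doc["parameters"]:
        params = doc["parameters"]
        missing = [n for n in rate_names if n not in params]
        if missing:
            raise ModelSpecError(f"{path}: parameters block lacks values for {missing}")
        theta = np.array([float(params[n]) for n in rate_names])
    return network, theta


def _format_side(stoich: np.ndarray, species: tuple[str, ...]) -> str:
    terms = []
    for s, c in zip(species, stoich):
        if c == 1:
            terms.append(s)
        elif c > 1:
            terms.extend([s] * int(c))
    return " + ".join(terms) if terms else "0"


def write_model_spec(
    path: str | Path, network: ReactionNetwork, theta: np.ndarray | None = None
) -> None:
    doc: dict[str, Any] = {
        "species": list(network.species_names),
        "reactions": [
            {
                "equation": f"{_format_side(r.reactant_stoichiometry, network.species_names)}"
                f" -> {_format_side(r.product_stoichiometry, network.species_names)}",
                "rate": r.name or f"theta{j + 1}",
            }
            for j, r in enumerate(network.reactions)
        ],
    }
    if theta is not None:
        doc["parameters"] = {
            rxn["rate"]: float(t) for rxn, t in zip(doc["reactions"], theta)
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_dataset(path: str | Path, network: ReactionNetwork) -> ObservedDataset:
    """Load a delimited time-series table into an :class:`ObservedDataset`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus species columns")
    time_col = df.columns[0]
    species_cols = list(df.columns[1:])
    expected = list(network.species_names)
    if species_cols != expected:
        raise ValueError(
            f"{path}: species columns {species_cols} do not match network species {expected}"
        )
    times = df[time_col].to_numpy(dtype=np.float64)
    if times[0] != 0.0:
        raise ValueError(f"{path}: first row must be t = 0 with the full initial state")
    if (np.diff(times) <= 0).any():
        raise ValueError(f"{path}: times must be strictly increasing")
    values = df[species_cols].to_numpy(dtype=np.float64)
    if np.isnan(values[0]).any():
        raise ValueError(f"{path}: the t = 0 row must observe every species")
    body = values[1:]
    observed_mask = ~np.isnan(body).any(axis=0)
    partial = np.isnan(body).any(axis=0) & ~np.isnan(body).all(axis=0)
    if partial.any():
        bad = [expected[i] for i in np.nonzero(partial)[0]]
        raise ValueError(
            f"{path}: species {bad} are observed at some times but not others; "
            "a species must be observed at every t > 0 or at none"
        )
    obs = body[:, observed_mask]
    if not np.isfinite(obs).all() or (obs < 0).any() or (obs != np.round(obs)).any():
        raise ValueError(f"{path}: observed counts must be non-negative integers")
    x0 = values[0]
    if (x0 < 0).any() or (x0 != np.round(x0)).any():
        raise ValueError(f"{path}: initial state must be non-negative integers")
    return ObservedDataset(
        x0=x0.astype(np.int64),
        times=times[1:],
        observed_mask=observed_mask,
        values=obs.astype(np.int64),
    )


def write_dataset(path: str | Path, network: ReactionNetwork, data: ObservedDataset) -> None:
    n = network.n_species
    full = np.full((data.d + 1, n), np.nan)
    full[0] = data.x0
    full[1:, data.observed_mask] = data.values
    df = pd.DataFrame(full, columns=list(network.species_names))
    df.insert(0, "time", np.concatenate([[0.0], data.times]))
    df.to_csv(path, index=False, float_format="%.10g")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_results(path: str | Path, result, network: ReactionNetwork,
                  config_echo: dict | None = None) -> dict:
    """Serialize a :class:`~stochmle.pipeline.FitResult` to JSON.

    Undefined ("n/a") confidence intervals are written as nulls.
    Returns the document that was written.
    """
    from .pipeline import CI_LEVELS  # avoid import cycle at module load

    doc: dict[str, Any] = {
        "species": list(network.species_names),
        "rates": [r.name or f"theta{j+1}" for j, r in enumerate(network.reactions)],
        "theta_hat": _jsonify(result.theta_hat),
        "seed": result.seed,
        "ce_trace": _jsonify(result.ce.trace) if result.ce is not None else None,
        "mcem_trace": _jsonify(result.mcem.trace),
        "mcem_converged": bool(result.mcem.converged),
        "config": _jsonify(config_echo or {}),
    }
    cov = result.covariance
    if cov is not None:
        doc["omega_hat"] = _jsonify(cov.omega_hat)
        doc["sigma_hat"] = _jsonify(cov.sigma_hat)
        doc["invalid"] = _jsonify(cov.invalid)
        doc["confidence_intervals"] = {
            str(int(level * 100)): _jsonify(result.intervals(level)) for level in CI_LEVELS
        }
    Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
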