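"""Pathway reconstruction and stoichiometric algebra.

The default packaged network covers the mevalonate pathway from acetyl-CoA
through IPP/DMAPP condensations into the heterologous carotenoid branch
(phytoene synthesis, four CrtI desaturation steps, lycopene cyclisation) plus
the native squalene branch (ERG9a/ERG9b) and two accumulation sinks for
lycopene and beta-carotene.  Species are split into *balanced* metabolites,
whose production and consumption are fully contained in the model and which
are therefore mass-balanced at steady state, and *unbalanced* (external)
metabolites that exchange with the rest of metabolism and are only
concentration-bounded.

At steady state the balanced stoichiometric matrix leaves three degrees of
freedom once isozyme pairs (HMG1/HMG2, BTS1/CrtE) are lumped; the sinks
SK_lyc and SK_b_car together with the squalene-forming flux ERG9b form a
valid free coordinate set from which every other flux follows by mass
balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

FREE_FLUX_IDS = ("SK_lyc", "SK_b_car", "ERG9b")


class NetworkError(ValueError):
    """Raised when a network file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    balanced: bool
    conc_lo: float
    conc_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.conc_lo < self.conc_hi):
            raise NetworkError(
                f"metabolite {self.id!r}: need 0 < conc_lo < conc_hi, "
                f"got [{self.conc_lo}, {self.conc_hi}]"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]
    enzyme_id: str | None = None
    is_sink: bool = False


@dataclass(frozen=True)
class RegulationEntry:
    reaction_id: str
    effector_id: str
    mode: str  # "competitive_inhibition" | "allosteric_inhibition"


@dataclass
class FluxState:
    """Full flux vector (mmol/L/h) aligned with a model's reaction order."""

    reaction_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.reaction_ids),):
            raise ValueError("flux vector length does not match reaction ids")
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.values[self._index[reaction_id]])

    def as_dict(self) -> dict[str, float]:
        return {r: float(v) for r, v in zip(self.reaction_ids, self.values)}


@dataclass
class NetworkModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    enzymes: list[str]
    regulation: list[RegulationEntry] = field(default_factory=list)
    isozyme_groups: list[frozenset[str]] = field(default_factory=list)
    promiscuous_groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self.met_index) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(self.rxn_index) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        enzyme_set = set(self.enzymes)
        if len(enzyme_set) != len(self.enzymes):
            raise NetworkError("duplicate enzyme ids")
        for rxn in self.reactions:
            for met in rxn.stoich:
                if met not in self.met_index:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            if rxn.is_sink:
                if rxn.enzyme_id is not None:
                    raise NetworkError(f"sink {rxn.id!r} must not carry an enzyme")
                bal = [m for m in rxn.stoich if self.metabolite(m).balanced]
                if len(rxn.stoich) != 1 or len(bal) != 1:
                    raise NetworkError(
                        f"sink {rxn.id!r} must consume exactly one balanced metabolite"
                    )
            else:
                if rxn.enzyme_id not in enzyme_set:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references unknown enzyme {rxn.enzyme_id!r}"
                    )
                if not any(self.metabolite(m).balanced for m in rxn.stoich):
                    raise NetworkError(
                        f"reaction {rxn.id!r} touches no balanced metabolite and is not a sink"
                    )
        for entry in self.regulation:
            if entry.reaction_id not in self.rxn_index:
                raise NetworkError(
                    f"regulation references unknown reaction {entry.reaction_id!r}"
                )
            if entry.effector_id not in self.met_index:
                raise NetworkError(
                    f"regulation references unknown metabolite {entry.effector_id!r}"
                )
            if entry.mode not in ("competitive_inhibition", "allosteric_inhibition"):
                raise NetworkError(f"unknown regulation mode {entry.mode!r}")
        for group in self.isozyme_groups + self.promiscuous_groups:
            for rid in group:
                if rid not in self.rxn_index:
                    raise NetworkError(f"group references unknown reaction {rid!r}")

    # -- convenience ----------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self.met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.rxn_index[rxn_id]]

    @property
    def balanced_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.balanced]

    @property
    def unbalanced_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.balanced]

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def enzymatic_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_sink]

    def reactions_of_enzyme(self, enzyme_id: str) -> list[str]:
        return [r.id for r in self.reactions if r.enzyme_id == enzyme_id]

    def regulation_for(self, rxn_id: str, mode: str | None = None) -> list[RegulationEntry]:
        return [
            e for e in self.regulation
            if e.reaction_id == rxn_id and (mode is None or e.mode == mode)
        ]

    def conc_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([m.conc_lo for m in self.metabolites])
        hi = np.array([m.conc_hi for m in self.metabolites])
        return lo, hi


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_network(path: str | Path | None = None) -> NetworkModel:
    """Load a network reconstruction from a JSON file.

    With ``path=None`` the packaged default mevalonate/carotenoid
    reconstruction is loaded.  Metabolite and reaction order follow the file,
    so loading is deterministic.
    """
    if path is None:
        with resources.files("carokin.data").joinpath("network.json").open() as fh:
            raw = json.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    try:
        metabolites = [
            Metabolite(
                id=m["id"], name=m.get("name", m["id"]), balanced=bool(m["balanced"]),
                conc_lo=float(m["conc_lo"]), conc_hi=float(m["conc_hi"]),
            )
            for m in raw["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                enzyme_id=r.get("enzyme"),
                is_sink=bool(r.get("is_sink", False)),
            )
            for r in raw["reactions"]
        ]
        regulation = [
            RegulationEntry(e["reaction"], e["effector"], e["mode"])
            for e in raw.get("regulation", [])
        ]
        model = NetworkModel(
            metabolites=metabolites,
            reactions=reactions,
            enzymes=list(raw["enzymes"]),
            regulation=regulation,
            isozyme_groups=[frozenset(g) for g in raw.get("isozyme_groups", [])],
            promiscuous_groups=[frozenset(g) for g in raw.get("promiscuous_groups", [])],
        )
    except KeyError as exc:  # missing required field
        raise NetworkError(f"network file missing required field: {exc}") from exc
    return model


# ---------------------------------------------------------------------------
# stoichiometric algebra
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: NetworkModel, balanced_only: bool = False) -> np.ndarray:
    """Signed stoichiometric matrix, rows = metabolites, cols = reactions."""
    mets = [m for m in model.metabolites if m.balanced] if balanced_only else model.metabolites
    idx = {m.id: i for i, m in enumerate(mets)}
    N = np.zeros((len(mets), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoich.items():
            if met in idx:
                N[idx[met], j] = coef
    return N


def _lumped_matrix(model: NetworkModel) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Balanced stoichiometric matrix with each isozyme group as one column.

    Members of an isozyme group share one chemistry, so the lumped flux is
    the sum of the member fluxes and the lumped column is their common
    stoichiometry.  Returns the lumped matrix and the column labels
    (singleton tuples for plain reactions, the member ids for groups).
    """
    N = stoichiometric_matrix(model, balanced_only=True)
    labels: list[tuple[str, ...]] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    groups = {rid: tuple(sorted(g)) for g in model.isozyme_groups for rid in g}
    for j, rxn in enumerate(model.reactions):
        if rxn.id in seen:
            continue
        if rxn.id in groups:
            members = groups[rxn.id]
            member_cols = [N[:, model.rxn_index[m]] for m in members]
            for other in member_cols[1:]:
                if not np.array_equal(member_cols[0], other):
                    raise NetworkError(
                        f"isozyme group {members} members differ in balanced stoichiometry"
                    )
            col = member_cols[0]
            seen.update(members)
            labels.append(members)
        else:
            col = N[:, j]
            labels.append((rxn.id,))
        cols.append(np.asarray(col))
    return np.column_stack(cols), labels


def free_flux_dimension(model: NetworkModel, lump_isozymes: bool = True) -> int:
    """Dimension of the steady-state flux space over balanced metabolites."""
    if lump_isozymes:
        N, _ = _lumped_matrix(model)
    else:
        N = stoichiometric_matrix(model, balanced_only=True)
    return N.shape[1] - int(np.linalg.matrix_rank(N))


def propagate_fluxes(
    model: NetworkModel,
    free: Mapping[str, float],
    split_rule: Mapping[str, float] | None = None,
) -> FluxState:
    """Expand the three free fluxes into the full 22-component flux vector.

    ``free`` maps the free reaction ids (default network: SK_lyc, SK_b_car,
    ERG9b) to non-negative fluxes in mmol/L/h.  ``split_rule`` optionally
    maps the first (sorted) member of each isozyme group to its share of the
    lumped flux, default 0.5; lumped fluxes are independent of the split.
    """
    missing = [k for k in FREE_FLUX_IDS if k not in free]
    if set(free) - set(FREE_FLUX_IDS):
        raise NetworkError(f"unknown free flux ids: {sorted(set(free) - set(FREE_FLUX_IDS))}")
    if missing:
        raise NetworkError(f"missing free fluxes: {missing}")
    for k, v in free.items():
        if v < 0:
            raise NetworkError(f"free flux {k!r} must be >= 0, got {v}")

    N, labels = _lumped_matrix(model)
    free_cols = [i for i, lab in enumerate(labels) if lab[0] in FREE_FLUX_IDS and len(lab) == 1]
    dep_cols = [i for i in range(len(labels)) if i not in free_cols]
    A = N[:, dep_cols]
    b = -N[:, free_cols] @ np.array([free[labels[i][0]] for i in free_cols])
    if A.shape[0] != A.shape[1]:
        raise NetworkError(
            "balanced system is not square after fixing the free fluxes; "
            "free set does not determine the network"
        )
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NetworkError("singular flux propagation") from exc

    lumped = {}
    for i, lab in enumerate(labels):
        lumped[lab] = free[lab[0]] if i in free_cols else float(x[dep_cols.index(i)])

    values = np.zeros(len(model.reactions))
    for lab, v in lumped.items():
        if len(lab) == 1:
            values[model.rxn_index[lab[0]]] = v
        else:
            first = lab[0]
            frac = 0.5 if split_rule is None else float(split_rule.get(first, 0.5))
            if not (0.0 <= frac <= 1.0):
                raise NetworkError(f"split fraction for {first!r} must be in [0, 1]")
            shares = [frac, 1.0 - frac]
            for rid, s in zip(lab, shares):
                values[model.rxn_index[rid]] = s * v
    return FluxState(model.reaction_ids, values)


def steady_state_residual(model: NetworkModel, flux: FluxState) -> float:
    """Max absolute balanced-metabolite imbalance of a flux vector."""
    N = stoichiometric_matrix(model, balanced_only=True)
    return float(np.max(np.abs(N @ flux.values))) if N.size else 0.0
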