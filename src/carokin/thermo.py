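"""Thermodynamic feasibility and reference-state sampling.

Every kinetic particle is built on a *reference thermodynamic state*: one
Gibbs reaction energy per reaction and one absolute concentration per
metabolite, mutually consistent (dG_r = dG0 + RT * sum_i s_i ln c_i) and
compatible with the reference flux directions (a reaction carrying positive
flux must dissipate energy, sign(dG_r) = -sign(v)).

Feasible dG ranges are obtained TMFA-style: extremise the linear expression
dG0 + RT * sum s_i ln c_i over the box of log-concentrations, then intersect
with the half-line enforcing the flux direction.  Reference states are drawn
by walking the pathway reaction by reaction, sampling each dG_r uniformly on
its conditional feasible range and fixing one pivot concentration exactly;
draws hitting an empty conditional range are rejected and resampled (see
ThermoSampler).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import NetworkModel, Reaction

R_GAS = 8.314462618e-3  # kJ/mol/K
T_DEFAULT = 298.15      # K, matches the conditions assumed for the dG0 inputs


class ThermoError(ValueError):
    pass


@dataclass
class ThermoTable:
    """Standard Gibbs reaction energies (kJ/mol) with provenance uncertainty."""

    dg0: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    temperature: float = T_DEFAULT
    gas_constant: float = R_GAS

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature


def load_thermo_table(path: str | Path | None = None, temperature: float = T_DEFAULT) -> ThermoTable:
    """Load a dG0 table (CSV: reaction,dG0,sd,...); default = packaged table."""
    if path is None:
        text = resources.files("carokin.data").joinpath("thermo_dG0.csv").read_text()
        df = pd.read_csv(io.StringIO(text), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    dg0 = dict(zip(df["reaction"], df["dG0"].astype(float)))
    sd = dict(zip(df["reaction"], df.get("sd", pd.Series(dtype=float)).astype(float))) if "sd" in df else {}
    return ThermoTable(dg0=dg0, sd=sd, temperature=temperature)


@dataclass
class ReferenceThermoState:
    """Sampled reaction energies and reference concentrations (mol/L)."""

    dg_r: dict[str, float]          # per enzymatic reaction; sinks absent
    ref_conc: np.ndarray            # aligned with model.metabolites
    within_bounds: np.ndarray       # boolean, same alignment
    rt: float = R_GAS * T_DEFAULT   # kJ/mol, the RT the energies refer to

    def conc_of(self, model: NetworkModel, met_id: str) -> float:
        return float(self.ref_conc[model.met_index[met_id]])


def reaction_quotient_log(rxn: Reaction, model: NetworkModel, conc: np.ndarray) -> float:
    """ln Q = sum_i s_i ln c_i for a reaction at absolute concentrations."""
    return float(sum(coef * np.log(conc[model.met_index[met]]) for met, coef in rxn.stoich.items()))


def dg_at(model: NetworkModel, thermo: ThermoTable, rxn_id: str, conc: np.ndarray) -> float:
    """Gibbs reaction energy (kJ/mol) at absolute concentrations."""
    rxn = model.reaction(rxn_id)
    if rxn_id not in thermo.dg0:
        raise ThermoError(f"no dG0 entry for reaction {rxn_id!r}")
    return thermo.dg0[rxn_id] + thermo.RT * reaction_quotient_log(rxn, model, conc)


def dg_feasible_range(
    model: NetworkModel,
    thermo: ThermoTable,
    rxn_id: str,
    flux_sign: int = 1,
) -> tuple[float, float]:
    """TMFA feasible range of dG_r for one reaction.

    Extremises dG0 + RT * sum s_i ln c_i over the metabolite concentration
    box (two LPs) and intersects with the direction half-line: dG <= 0 for
    positive flux, dG >= 0 for negative flux (the boundary value 0 is
    half-open; the sampler keeps a strict margin away from it).  flux_sign 0
    returns the unclipped range.
    """
    rxn = model.reaction(rxn_id)
    if rxn_id not in thermo.dg0:
        raise ThermoError(f"no dG0 entry for reaction {rxn_id!r} (sinks carry no dG)")
    mets = list(rxn.stoich)
    coefs = np.array([rxn.stoich[m] for m in mets], dtype=float)
    lo = np.array([np.log(model.metabolite(m).conc_lo) for m in mets])
    hi = np.array([np.log(model.metabolite(m).conc_hi) for m in mets])
    bounds = list(zip(lo, hi))
    res_min = linprog(c=coefs, bounds=bounds, method="highs")
    res_max = linprog(c=-coefs, bounds=bounds, method="highs")
    if not (res_min.success and res_max.success):
        raise ThermoError(f"LP failure for reaction {rxn_id!r}")
    dg_lo = thermo.dg0[rxn_id] + thermo.RT * res_min.fun
    dg_hi = thermo.dg0[rxn_id] - thermo.RT * res_max.fun
    if flux_sign > 0:
        dg_hi = min(dg_hi, 0.0)
    elif flux_sign < 0:
        dg_lo = max(dg_lo, 0.0)
    if dg_lo > dg_hi:
        raise ThermoError(
            f"reaction {rxn_id!r}: no thermodynamically feasible dG range for "
            f"flux sign {flux_sign} (box range [{dg_lo:.2f}, {dg_hi:.2f}] kJ/mol)"
        )
    return float(dg_lo), float(dg_hi)


class ThermoSampler:
    """Draws reference thermodynamic states consistent with flux directions.

    Reactions sharing one chemistry (isozymes) share a single sampled dG_r.
    The direction margin keeps sampled energies strictly away from
    equilibrium (|dG_r| >= margin), which also bounds the exchange fluxes of
    the kinetic particles built on top of the state.

    Sampling walks the pathway: each chemistry group is assigned a *pivot*
    metabolite that first appears in that group, the remaining metabolites
    are drawn log-uniformly up front, and each group's dG_r is then drawn
    uniformly inside its conditional feasible range (its TMFA range
    intersected with what the pivot's concentration box still allows given
    the already-fixed concentrations); the pivot concentration follows
    exactly.  Draws hitting an empty conditional range are rejected and the
    whole state is resampled, so accepted states satisfy every constraint
    exactly rather than within an optimiser tolerance.
    """

    def __init__(
        self,
        model: NetworkModel,
        thermo: ThermoTable,
        v_signs: Mapping[str, int] | None = None,
        margin: float = 0.25,
        max_tries: int = 500,
    ) -> None:
        self.model = model
        self.thermo = thermo
        self.margin = float(margin)
        self.max_tries = int(max_tries)

        # group enzymatic reactions by chemistry
        groups: dict[tuple, list[str]] = {}
        for rxn in model.enzymatic_reactions:
            key = tuple(sorted(rxn.stoich.items()))
            groups.setdefault(key, []).append(rxn.id)
        self.groups = list(groups.values())

        self.signs = {}
        for g in self.groups:
            sgns = {int(np.sign((v_signs or {}).get(r, 1))) for r in g}
            if len(sgns) != 1:
                raise ThermoError(f"isozyme group {g} has inconsistent flux signs")
            self.signs[g[0]] = sgns.pop()

        self.ranges = {}
        for g in self.groups:
            lo, hi = dg_feasible_range(model, thermo, g[0], self.signs[g[0]])
            s = self.signs[g[0]]
            if s > 0:
                hi = min(hi, 0.0) - self.margin
            elif s < 0:
                lo = max(lo, 0.0) + self.margin
            if lo > hi:
                raise ThermoError(
                    f"reaction {g[0]!r}: feasible dG range vanishes at margin {self.margin}"
                )
            self.ranges[g[0]] = (lo, hi)

        lo, hi = model.conc_bounds()
        self.x_lo, self.x_hi = np.log(lo), np.log(hi)
        self._assign_pivots()

    def _assign_pivots(self) -> None:
        """Pick, per chemistry group, a metabolite first appearing there."""
        seen: set[str] = set()
        self.pivots: list[tuple[str, float]] = []
        for g in self.groups:
            stoich = self.model.reaction(g[0]).stoich
            candidates = [m for m in stoich if m not in seen]
            # prefer balanced products: they carry the widest boxes
            candidates.sort(
                key=lambda m: (not self.model.metabolite(m).balanced, stoich[m] < 0)
            )
            if not candidates:
                raise ThermoError(
                    f"no pivot metabolite available for reaction group {g}; "
                    "supply a reaction ordering in which each reaction introduces "
                    "at least one new metabolite"
                )
            self.pivots.append((candidates[0], float(stoich[candidates[0]])))
            seen.update(stoich)
        pivot_ids = {p for p, _ in self.pivots}
        self.free_mets = [m.id for m in self.model.metabolites if m.id not in pivot_ids]

    def sample(self, seed) -> ReferenceThermoState:
        rng = np.random.default_rng(seed)
        RT = self.thermo.RT
        midx = self.model.met_index
        for _ in range(self.max_tries):
            x = np.full(len(self.model.metabolites), np.nan)
            for met in self.free_mets:
                i = midx[met]
                x[i] = rng.uniform(self.x_lo[i], self.x_hi[i])
            dg_r: dict[str, float] = {}
            ok = True
            for g, (pivot, coef) in zip(self.groups, self.pivots):
                rxn = self.model.reaction(g[0])
                sigma = sum(
                    c * x[midx[m]] for m, c in rxn.stoich.items() if m != pivot
                )
                pi = midx[pivot]
                end_a = self.thermo.dg0[g[0]] + RT * (sigma + coef * self.x_lo[pi])
                end_b = self.thermo.dg0[g[0]] + RT * (sigma + coef * self.x_hi[pi])
                lo = max(min(end_a, end_b), self.ranges[g[0]][0])
                hi = min(max(end_a, end_b), self.ranges[g[0]][1])
                if lo > hi:
                    ok = False
                    break
                dg = rng.uniform(lo, hi)
                x[pi] = (dg - self.thermo.dg0[g[0]] - RT * sigma) / (RT * coef)
                for rid in g:
                    dg_r[rid] = float(dg)
            if not ok:
                continue
            conc = np.exp(x)
            return ReferenceThermoState(
                dg_r=dg_r, ref_conc=conc,
                within_bounds=(x >= self.x_lo - 1e-12) & (x <= self.x_hi + 1e-12),
                rt=RT,
            )
        raise ThermoError(
            f"could not sample a jointly consistent reference state in {self.max_tries} tries"
        )


def sample_reference_thermo(
    model: NetworkModel,
    thermo: ThermoTable,
    v_signs: Mapping[str, int] | None = None,
    seed=0,
    margin: float = 0.25,
) -> ReferenceThermoState:
    """One-shot reference-state draw (see ThermoSampler for the hot-loop API)."""
    return ThermoSampler(model, thermo, v_signs=v_signs, margin=margin).sample(seed)
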