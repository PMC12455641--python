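"""Elementary-mechanism kinetics: patterns, particle sampling, rate evaluation.

Each enzymatic reaction is described by an elementary mechanism pattern: a
graph of enzyme states (free enzyme E, substrate/product complexes, dead-end
inhibitor complexes) connected by reversible elementary steps, each step
binding or releasing at most one metabolite.  Ordered sequential binding is
used throughout (the uni-uni pattern is the familiar E -> EA -> EP -> E
cycle).  Three structure levels are supported:

* ``simple``    - substrates and products only,
* ``regulated`` - adds dead-end competitive-inhibitor complexes and a
  two-conformation allosteric modifier (used for HMG2),
* ``detailed``  - additionally merges the two catalytic cycles of a
  promiscuous enzyme (CrtYB: phytoene synthase + lycopene cyclase) through a
  shared free-enzyme state.

A *kinetic particle* assigns every elementary step forward/reverse rate
constants.  Sampling is anchored: per catalytic cycle, step reversibilities
(the fraction of the reaction's Gibbs energy dissipated by each step) are
drawn from a flat Dirichlet and state abundances from another flat
Dirichlet; the elementary constants then follow algebraically such that at
the reference concentrations, with enzyme level 1, the cycle's net rate
equals the reference flux exactly and the Haldane relationship holds by
construction.

Rates away from the reference are evaluated by solving the steady-state
enzyme-state balance (a numerical King-Altman solve): A(c) u = 0 with
sum(u) = 1, net flux = enzyme_level * (net rate through the catalytic
step).  Analytic derivatives of the flux with respect to log-concentrations
are obtained by implicit differentiation of the same linear system and are
reused both for elasticities and for the steady-state optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .network import FluxState, NetworkModel, Reaction
from .thermo import ReferenceThermoState


class KineticsError(ValueError):
    pass


class StructureLevel(str, Enum):
    simple = "simple"
    regulated = "regulated"
    detailed = "detailed"


@dataclass(frozen=True)
class Step:
    from_state: int
    to_state: int
    met_fwd: str | None  # metabolite bound on the forward transition
    met_rev: str | None  # metabolite bound on the reverse transition
    kind: str            # "binding" | "catalytic" | "release" | "dead_end"


@dataclass(frozen=True)
class Cycle:
    reaction_id: str
    step_indices: tuple[int, ...]
    designated: int  # index of the catalytic (metabolite-free) step


@dataclass(frozen=True)
class AllostericSpec:
    effector_id: str
    hill: float = 1.0


@dataclass
class MechanismPattern:
    reaction_ids: tuple[str, ...]
    states: list[str]
    steps: list[Step]
    cycles: list[Cycle]
    dead_end_steps: tuple[int, ...] = ()
    allosteric: AllostericSpec | None = None

    def __post_init__(self) -> None:
        # connectivity of the step graph
        n = len(self.states)
        adj = {i: set() for i in range(n)}
        for s in self.steps:
            adj[s.from_state].add(s.to_state)
            adj[s.to_state].add(s.from_state)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != n:
            raise KineticsError(f"pattern {self.reaction_ids}: state graph not connected")
        for cyc in self.cycles:
            walk = [self.steps[i] for i in cyc.step_indices]
            if walk[0].from_state != 0 or walk[-1].to_state != 0:
                raise KineticsError(
                    f"cycle {cyc.reaction_id}: catalytic walk must start and end at free enzyme"
                )
            for a, b in zip(walk, walk[1:]):
                if a.to_state != b.from_state:
                    raise KineticsError(f"cycle {cyc.reaction_id}: steps are not a closed walk")


def _expand(stoich: Mapping[str, float], sign: int) -> list[str]:
    out: list[str] = []
    for met, coef in stoich.items():
        if sign * coef > 0:
            n = abs(coef)
            if abs(n - round(n)) > 1e-9:
                raise KineticsError(f"non-integer stoichiometry for {met!r} not supported")
            out.extend([met] * int(round(n)))
    return out


def build_pattern(
    reactions: Sequence[Reaction],
    level: StructureLevel,
    regulation: Sequence = (),
) -> MechanismPattern:
    """Construct the mechanism pattern for one reaction (or a promiscuous group).

    ``regulation`` holds the RegulationEntry items applying to these
    reactions; they are ignored at the ``simple`` level.
    """
    level = StructureLevel(level)
    states = ["E"]
    steps: list[Step] = []
    cycles: list[Cycle] = []
    for rxn in reactions:
        if rxn.is_sink:
            raise KineticsError("sinks have no mechanism pattern (mass action)")
        subs = _expand(rxn.stoich, -1)
        prods = _expand(rxn.stoich, +1)
        if not subs or not prods:
            raise KineticsError(f"reaction {rxn.id!r}: need at least one substrate and product")
        idx: list[int] = []
        cur = 0
        label = "E"
        for s in subs:
            label += f".{s}"
            states.append(f"{label}|{rxn.id}")
            steps.append(Step(cur, len(states) - 1, s, None, "binding"))
            idx.append(len(steps) - 1)
            cur = len(states) - 1
        # catalytic conversion to the full product complex
        states.append(f"E.{'.'.join(prods)}|{rxn.id}")
        steps.append(Step(cur, len(states) - 1, None, None, "catalytic"))
        designated = len(steps) - 1
        idx.append(designated)
        cur = len(states) - 1
        for k, p in enumerate(prods):
            last = k == len(prods) - 1
            if last:
                nxt = 0
            else:
                states.append(f"E.{'.'.join(prods[k + 1:])}|{rxn.id}")
                nxt = len(states) - 1
            steps.append(Step(cur, nxt, None, p, "release"))
            idx.append(len(steps) - 1)
            cur = nxt
        cycles.append(Cycle(rxn.id, tuple(idx), designated))

    dead_end: list[int] = []
    allosteric: AllostericSpec | None = None
    if level in (StructureLevel.regulated, StructureLevel.detailed):
        for entry in regulation:
            if entry.mode == "competitive_inhibition":
                states.append(f"E.{entry.effector_id}(dead)")
                steps.append(Step(0, len(states) - 1, entry.effector_id, None, "dead_end"))
                dead_end.append(len(steps) - 1)
            elif entry.mode == "allosteric_inhibition":
                allosteric = AllostericSpec(effector_id=entry.effector_id)
    return MechanismPattern(
        reaction_ids=tuple(r.id for r in reactions),
        states=states,
        steps=steps,
        cycles=cycles,
        dead_end_steps=tuple(dead_end),
        allosteric=allosteric,
    )


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

@dataclass
class CompiledPattern:
    pattern: MechanismPattern
    n_states: int
    sf: np.ndarray            # step from-state
    st: np.ndarray            # step to-state
    mf: np.ndarray            # global metabolite index bound forward (-1 none)
    mr: np.ndarray            # global metabolite index bound reverse (-1 none)
    cycles: list[tuple[int, int]]   # (global reaction index, designated step)
    enzyme_idx: int
    met_ids: np.ndarray       # unique global metabolite indices in the pattern
    eff_idx: int = -1         # allosteric effector global index (-1 none)
    # local met index per step for derivative assembly (-1 none)
    lf: np.ndarray | None = None
    lr: np.ndarray | None = None

    def __post_init__(self) -> None:
        loc = {g: i for i, g in enumerate(self.met_ids)}
        self.lf = np.array([loc.get(g, -1) for g in self.mf])
        self.lr = np.array([loc.get(g, -1) for g in self.mr])


@dataclass
class CompiledModel:
    """Model + structure level compiled to index arrays for fast evaluation."""

    model: NetworkModel
    level: StructureLevel
    patterns: list[CompiledPattern]
    sink_rxn: list[int]
    sink_met: list[int]

    @property
    def n_reactions(self) -> int:
        return len(self.model.reactions)


def compile_model(model: NetworkModel, level: StructureLevel | str) -> CompiledModel:
    level = StructureLevel(level)
    groups: list[list[Reaction]] = []
    if level is StructureLevel.detailed:
        merged = {rid for g in model.promiscuous_groups for rid in g}
        for g in model.promiscuous_groups:
            groups.append([model.reaction(r) for r in sorted(g)])
    else:
        merged = set()
    for rxn in model.enzymatic_reactions:
        if rxn.id not in merged:
            groups.append([rxn])

    patterns = []
    for grp in groups:
        reg = [e for r in grp for e in model.regulation_for(r.id)]
        pat = build_pattern(grp, level, reg)
        enzymes = {r.enzyme_id for r in grp}
        if len(enzymes) != 1:
            raise KineticsError(f"promiscuous group {pat.reaction_ids} spans several enzymes")
        midx = model.met_index
        sf = np.array([s.from_state for s in pat.steps])
        stv = np.array([s.to_state for s in pat.steps])
        mfv = np.array([midx[s.met_fwd] if s.met_fwd else -1 for s in pat.steps])
        mrv = np.array([midx[s.met_rev] if s.met_rev else -1 for s in pat.steps])
        mets = np.unique(np.concatenate([mfv[mfv >= 0], mrv[mrv >= 0]]))
        patterns.append(CompiledPattern(
            pattern=pat,
            n_states=len(pat.states),
            sf=sf, st=stv, mf=mfv, mr=mrv,
            cycles=[(model.rxn_index[c.reaction_id], c.designated) for c in pat.cycles],
            enzyme_idx=model.enzymes.index(grp[0].enzyme_id),
            met_ids=mets,
            eff_idx=(midx[pat.allosteric.effector_id] if pat.allosteric else -1),
        ))
    sink_rxn, sink_met = [], []
    for rxn in model.reactions:
        if rxn.is_sink:
            sink_rxn.append(model.rxn_index[rxn.id])
            sink_met.append(model.met_index[next(iter(rxn.stoich))])
    return CompiledModel(model=model, level=level, patterns=patterns,
                         sink_rxn=sink_rxn, sink_met=sink_met)


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------

@dataclass
class PatternParams:
    kf: np.ndarray
    kr: np.ndarray
    u_ref: np.ndarray
    reversibilities: dict[str, np.ndarray] = field(default_factory=dict)
    allosteric_L: float | None = None
    allosteric_K: float | None = None
    hill: float = 1.0


@dataclass
class KineticParticle:
    level: StructureLevel
    refstate: ReferenceThermoState
    v_ref: FluxState
    params: list[PatternParams]
    seed: int | None = None

    def to_jsonable(self) -> dict:
        return {
            "level": self.level.value,
            "seed": self.seed,
            "v_ref": self.v_ref.as_dict(),
            "dg_r": self.refstate.dg_r,
            "ref_conc": self.refstate.ref_conc.tolist(),
            "rt": self.refstate.rt,
            "params": [
                {
                    "kf": p.kf.tolist(), "kr": p.kr.tolist(), "u_ref": p.u_ref.tolist(),
                    "allosteric_L": p.allosteric_L, "allosteric_K": p.allosteric_K,
                }
                for p in self.params
            ],
        }


def particle_from_jsonable(cm: CompiledModel, d: Mapping) -> KineticParticle:
    """Rebuild a particle serialized with :meth:`KineticParticle.to_jsonable`."""
    if d["level"] != cm.level.value:
        raise KineticsError(f"particle level {d['level']!r} does not match compiled model")
    refstate = ReferenceThermoState(
        dg_r={k: float(v) for k, v in d["dg_r"].items()},
        ref_conc=np.array(d["ref_conc"], float),
        within_bounds=np.ones(len(d["ref_conc"]), dtype=bool),
        rt=float(d.get("rt", 8.314462618e-3 * 298.15)),
    )
    v_ref = FluxState(cm.model.reaction_ids,
                      np.array([d["v_ref"][r] for r in cm.model.reaction_ids]))
    params = [
        PatternParams(
            kf=np.array(p["kf"], float), kr=np.array(p["kr"], float),
            u_ref=np.array(p["u_ref"], float),
            allosteric_L=p.get("allosteric_L"), allosteric_K=p.get("allosteric_K"),
        )
        for p in d["params"]
    ]
    if len(params) != len(cm.patterns):
        raise KineticsError("pattern count mismatch while deserializing particle")
    return KineticParticle(level=cm.level, refstate=refstate, v_ref=v_ref,
                           params=params, seed=d.get("seed"))


def _dirichlet_floor(rng: np.random.Generator, n: int, floor: float, tries: int = 100) -> np.ndarray:
    if n == 1:
        return np.ones(1)
    for _ in range(tries):
        x = rng.dirichlet(np.ones(n))
        if x.min() >= floor:
            return x
    raise KineticsError(f"could not draw a Dirichlet sample with floor {floor} in {tries} tries")


def sample_particle(
    cm: CompiledModel,
    refstate: ReferenceThermoState,
    v_ref: FluxState,
    seed,
    tilt: Mapping[str, tuple[float, float]] | None = None,
    rt: float | None = None,
    rev_floor: float = 0.02,
    abund_floor: float = 1e-3,
) -> KineticParticle:
    """Draw one anchored, thermodynamically consistent kinetic particle.

    ``tilt`` optionally maps enzyme ids to a (lo, hi) range for the
    free-enzyme abundance share, used by the synthetic-data generator to
    force an enzyme towards saturation (small share) or towards first-order
    operation (share near 1).
    """
    rng = np.random.default_rng(seed)
    rt = refstate.rt if rt is None else rt
    model = cm.model
    conc = refstate.ref_conc
    params: list[PatternParams] = []
    for cp in cm.patterns:
        pat = cp.pattern
        n_steps = len(pat.steps)
        u = _dirichlet_floor(rng, cp.n_states, abund_floor)
        enz_id = model.enzymes[cp.enzyme_idx]
        if tilt and enz_id in tilt:
            lo, hi = tilt[enz_id]
            share = rng.uniform(lo, hi)
            u[1:] *= (1.0 - share) / (1.0 - u[0])
            u[0] = share
        kf = np.zeros(n_steps)
        kr = np.zeros(n_steps)
        revs: dict[str, np.ndarray] = {}
        v_scale = []
        for (rxn_idx, _), cyc in zip(cp.cycles, pat.cycles):
            rid = cyc.reaction_id
            v = v_ref[rid]
            if v <= 0:
                raise KineticsError(f"reference flux for {rid!r} must be positive")
            dgr = refstate.dg_r[rid]
            if dgr >= 0:
                raise KineticsError(f"reference dG for {rid!r} must be negative")
            v_scale.append(v)
            m = len(cyc.step_indices)
            r = _dirichlet_floor(rng, m, rev_floor)
            revs[rid] = r
            ratio = np.exp(-r * dgr / rt)          # one-way flux ratios > 1
            v_minus = v / (ratio - 1.0)
            v_plus = v_minus * ratio
            for k, si in enumerate(cyc.step_indices):
                s = pat.steps[si]
                cf = conc[cp.mf[si]] if cp.mf[si] >= 0 else 1.0
                cr = conc[cp.mr[si]] if cp.mr[si] >= 0 else 1.0
                kf[si] = v_plus[k] / (u[s.from_state] * cf)
                kr[si] = v_minus[k] / (u[s.to_state] * cr)
        w_scale = float(np.mean(v_scale))
        for si in pat.dead_end_steps:
            s = pat.steps[si]
            w = w_scale * 10.0 ** rng.uniform(-1, 1)
            kf[si] = w / (u[s.from_state] * conc[cp.mf[si]])
            kr[si] = w / u[s.to_state]
        L = K = None
        if pat.allosteric is not None:
            L = 10.0 ** rng.uniform(-4, 4)
            K = conc[cp.eff_idx] * 10.0 ** rng.uniform(-1, 1)
        params.append(PatternParams(kf=kf, kr=kr, u_ref=u.copy(),
                                    reversibilities=revs,
                                    allosteric_L=L, allosteric_K=K))
    return KineticParticle(level=cm.level, refstate=refstate, v_ref=v_ref,
                           params=params,
                           seed=int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.SeedSequence) else None)


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def _allosteric_factor(p: PatternParams, cp: CompiledPattern, conc: np.ndarray,
                       ref_conc: np.ndarray) -> tuple[float, float]:
    """(activity factor normalised to 1 at reference, d ln factor / d ln c_eff)."""
    if p.allosteric_L is None:
        return 1.0, 0.0
    L, K, n = p.allosteric_L, p.allosteric_K, p.hill
    x = conc[cp.eff_idx] / K
    x0 = ref_conc[cp.eff_idx] / K
    f = 1.0 / (1.0 + L * (1.0 + x) ** n)
    f0 = 1.0 / (1.0 + L * (1.0 + x0) ** n)
    dln = -L * n * (1.0 + x) ** (n - 1.0) * x * f
    return f / f0, dln


def _occupancies(cp: CompiledPattern, p: PatternParams, conc: np.ndarray):
    """Solve the enzyme-state balance; returns (u, lu factorisation, rates)."""
    n = cp.n_states
    ratef = p.kf * np.where(cp.mf >= 0, conc[np.maximum(cp.mf, 0)], 1.0)
    rater = p.kr * np.where(cp.mr >= 0, conc[np.maximum(cp.mr, 0)], 1.0)
    M = np.zeros((n, n))
    np.add.at(M, (cp.st, cp.sf), ratef)
    np.add.at(M, (cp.sf, cp.sf), -ratef)
    np.add.at(M, (cp.sf, cp.st), rater)
    np.add.at(M, (cp.st, cp.st), -rater)
    M[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    try:
        lu = lu_factor(M)
    except Exception as exc:
        raise KineticsError(
            f"singular enzyme-state matrix for pattern {cp.pattern.reaction_ids}"
        ) from exc
    u = lu_solve(lu, b)
    # one step of iterative refinement: the catalytic net rate is a small
    # difference of large one-way fluxes, so occupancies need full accuracy
    u += lu_solve(lu, b - M @ u)
    return u, lu, M, ratef, rater


def pattern_rate(
    cm: CompiledModel,
    particle: KineticParticle,
    pattern_index: int,
    conc_abs: np.ndarray,
    enzyme_level: float = 1.0,
) -> np.ndarray:
    """Net flux(es) of one pattern at absolute concentrations (mol/L)."""
    if np.any(conc_abs <= 0):
        raise KineticsError("concentrations must be positive")
    cp = cm.patterns[pattern_index]
    p = particle.params[pattern_index]
    u, _, _, _, _ = _occupancies(cp, p, conc_abs)
    s, _ = _allosteric_factor(p, cp, conc_abs, particle.refstate.ref_conc)
    out = np.empty(len(cp.cycles))
    for i, (_, d) in enumerate(cp.cycles):
        out[i] = enzyme_level * s * (p.kf[d] * u[cp.sf[d]] - p.kr[d] * u[cp.st[d]])
    return out


# ---------------------------------------------------------------------------
# batched evaluation engine
#
# Patterns are grouped by state count so the enzyme-state solves of the whole
# network run through a handful of batched LAPACK calls instead of one scipy
# factorisation per pattern.  The per-particle constants (concatenated rate
# constants, designated-step constants) are cached on the particle.
# ---------------------------------------------------------------------------

@dataclass
class _Batch:
    n: int                      # states per pattern
    pats: list[int]             # pattern indices in this group
    k: int                      # group size
    L: int                      # max distinct metabolites per pattern
    s_pat: np.ndarray           # per step: position of its pattern in group
    s_sf: np.ndarray
    s_st: np.ndarray
    s_mf: np.ndarray            # global met idx bound fwd (-1 none)
    s_mr: np.ndarray
    s_lf: np.ndarray            # local met column (-1 none)
    s_lr: np.ndarray
    m_idx: np.ndarray           # flat M-assembly indices, shape (4, n_steps)
    c_pat: np.ndarray           # per cycle: pattern position in group
    c_sf: np.ndarray            # designated-step from/to states
    c_st: np.ndarray
    c_rxn: np.ndarray           # global reaction index
    c_step: np.ndarray          # designated step index within its pattern


def _build_batches(cm: CompiledModel) -> list[_Batch]:
    by_n: dict[int, list[int]] = {}
    for ip, cp in enumerate(cm.patterns):
        by_n.setdefault(cp.n_states, []).append(ip)
    batches = []
    for n, pats in sorted(by_n.items()):
        s_pat, s_sf, s_st, s_mf, s_mr, s_lf, s_lr = [], [], [], [], [], [], []
        c_pat, c_sf, c_st, c_rxn, c_step = [], [], [], [], []
        L = max(len(cm.patterns[ip].met_ids) for ip in pats)
        for pos, ip in enumerate(pats):
            cp = cm.patterns[ip]
            ns = len(cp.sf)
            s_pat.extend([pos] * ns)
            s_sf.extend(cp.sf); s_st.extend(cp.st)
            s_mf.extend(cp.mf); s_mr.extend(cp.mr)
            s_lf.extend(cp.lf); s_lr.extend(cp.lr)
            for (rxn_idx, d) in cp.cycles:
                c_pat.append(pos)
                c_sf.append(cp.sf[d]); c_st.append(cp.st[d])
                c_rxn.append(rxn_idx); c_step.append(d)
        s_pat = np.array(s_pat); s_sf = np.array(s_sf); s_st = np.array(s_st)
        base = s_pat * n * n
        m_idx = np.stack([
            base + s_st * n + s_sf,   # +ratef
            base + s_sf * n + s_sf,   # -ratef
            base + s_sf * n + s_st,   # +rater
            base + s_st * n + s_st,   # -rater
        ])
        batches.append(_Batch(
            n=n, pats=pats, k=len(pats), L=L,
            s_pat=s_pat, s_sf=s_sf, s_st=s_st,
            s_mf=np.array(s_mf), s_mr=np.array(s_mr),
            s_lf=np.array(s_lf), s_lr=np.array(s_lr),
            m_idx=m_idx,
            c_pat=np.array(c_pat), c_sf=np.array(c_sf), c_st=np.array(c_st),
            c_rxn=np.array(c_rxn), c_step=np.array(c_step),
        ))
    return batches


def _batches_of(cm: CompiledModel) -> list[_Batch]:
    if not hasattr(cm, "_batches"):
        cm._batches = _build_batches(cm)
    return cm._batches


def _particle_batch_consts(cm: CompiledModel, particle: KineticParticle):
    cache = getattr(particle, "_bconsts", None)
    if cache is not None and cache[0] is cm:
        return cache[1]
    out = []
    for b in _batches_of(cm):
        kf = np.concatenate([particle.params[ip].kf for ip in b.pats])
        kr = np.concatenate([particle.params[ip].kr for ip in b.pats])
        offs = np.cumsum([0] + [len(cm.patterns[ip].kf if hasattr(cm.patterns[ip], 'kf') else particle.params[ip].kf) for ip in b.pats])[:-1]
        kfd = np.array([particle.params[b.pats[p]].kf[d] for p, d in zip(b.c_pat, b.c_step)])
        krd = np.array([particle.params[b.pats[p]].kr[d] for p, d in zip(b.c_pat, b.c_step)])
        out.append((kf, kr, kfd, krd))
    particle._bconsts = (cm, out)
    return out


def _eval_batched(cm, particle, conc_rel, enz_rel, want_jac):
    ref = particle.refstate.ref_conc
    conc = conc_rel * ref
    n_r = cm.n_reactions
    v = np.zeros(n_r)
    J = np.zeros((n_r, len(conc))) if want_jac else None
    consts = _particle_batch_consts(cm, particle)
    for b, (kf, kr, kfd, krd) in zip(_batches_of(cm), consts):
        n, k = b.n, b.k
        ratef = kf * np.where(b.s_mf >= 0, conc[np.maximum(b.s_mf, 0)], 1.0)
        rater = kr * np.where(b.s_mr >= 0, conc[np.maximum(b.s_mr, 0)], 1.0)
        Mflat = np.zeros(k * n * n)
        np.add.at(Mflat, np.concatenate([b.m_idx[0], b.m_idx[1], b.m_idx[2], b.m_idx[3]]),
                  np.concatenate([ratef, -ratef, rater, -rater]))
        M = Mflat.reshape(k, n, n)
        M[:, 0, :] = 1.0
        rhs = np.zeros((k, n))
        rhs[:, 0] = 1.0
        try:
            U = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
            # one refinement pass (catalytic net rates are small differences)
            U += np.linalg.solve(M, (rhs - np.einsum("kij,kj->ki", M, U))[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:
            bad = [cm.patterns[ip].pattern.reaction_ids for ip in b.pats]
            raise KineticsError(f"singular enzyme-state matrix among patterns {bad}") from exc
        # allosteric factors per pattern in group
        sfac = np.ones(k)
        dlns = np.zeros(k)
        for pos, ip in enumerate(b.pats):
            cp = cm.patterns[ip]
            if cp.eff_idx >= 0:
                sfac[pos], dlns[pos] = _allosteric_factor(particle.params[ip], cp, conc, ref)
        e_cyc = enz_rel[np.array([cm.patterns[b.pats[p]].enzyme_idx for p in b.c_pat])]
        u_f = U[b.c_pat, b.c_sf]
        u_t = U[b.c_pat, b.c_st]
        flux = e_cyc * sfac[b.c_pat] * (kfd * u_f - krd * u_t)
        v[b.c_rxn] = flux
        if want_jac:
            Dflat = np.zeros(k * n * b.L)
            mask_f = b.s_lf >= 0
            mask_r = b.s_lr >= 0
            baseD = b.s_pat * n * b.L
            vals = []
            idxs = []
            if mask_f.any():
                contrib = ratef[mask_f] * U[b.s_pat[mask_f], b.s_sf[mask_f]]
                idxs.append(baseD[mask_f] + b.s_st[mask_f] * b.L + b.s_lf[mask_f])
                vals.append(contrib)
                idxs.append(baseD[mask_f] + b.s_sf[mask_f] * b.L + b.s_lf[mask_f])
                vals.append(-contrib)
            if mask_r.any():
                contrib = rater[mask_r] * U[b.s_pat[mask_r], b.s_st[mask_r]]
                idxs.append(baseD[mask_r] + b.s_sf[mask_r] * b.L + b.s_lr[mask_r])
                vals.append(contrib)
                idxs.append(baseD[mask_r] + b.s_st[mask_r] * b.L + b.s_lr[mask_r])
                vals.append(-contrib)
            if idxs:
                np.add.at(Dflat, np.concatenate(idxs), np.concatenate(vals))
            D = Dflat.reshape(k, n, b.L)
            D[:, 0, :] = 0.0
            DU = -np.linalg.solve(M, D)
            dv = (e_cyc * sfac[b.c_pat])[:, None] * (
                kfd[:, None] * DU[b.c_pat, b.c_sf, :] - krd[:, None] * DU[b.c_pat, b.c_st, :]
            )
            for ci in range(len(b.c_rxn)):
                mets = cm.patterns[b.pats[b.c_pat[ci]]].met_ids
                J[b.c_rxn[ci], mets] += dv[ci, :len(mets)]
            for pos, ip in enumerate(b.pats):
                cp = cm.patterns[ip]
                if cp.eff_idx >= 0:
                    for (rxn_idx, _) in cp.cycles:
                        J[rxn_idx, cp.eff_idx] += v[rxn_idx] * dlns[pos]
    for rxn_idx, met_idx in zip(cm.sink_rxn, cm.sink_met):
        v[rxn_idx] = particle.v_ref.values[rxn_idx] * conc_rel[met_idx]
        if want_jac:
            J[rxn_idx, met_idx] = v[rxn_idx]
    return v, J


def network_rates(
    cm: CompiledModel,
    particle: KineticParticle,
    conc_rel: np.ndarray,
    enz_rel: np.ndarray,
) -> np.ndarray:
    """Full flux vector at relative concentrations/enzyme levels.

    ``conc_rel`` is aligned with model.metabolites (1.0 = reference),
    ``enz_rel`` with model.enzymes.  Sinks are first-order mass action in
    their substrate, anchored at the reference flux.
    """
    v, _ = _eval_batched(cm, particle, np.asarray(conc_rel, float),
                         np.asarray(enz_rel, float), want_jac=False)
    return v


def rates_and_conc_jacobian(
    cm: CompiledModel,
    particle: KineticParticle,
    conc_rel: np.ndarray,
    enz_rel: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fluxes and the unscaled Jacobian dv/dln(c) (n_reactions x n_metabolites).

    Derivatives come from implicit differentiation of the state balance:
    du/dlnc_m = -M^{-1} (dM/dlnc_m) u with the normalisation row held fixed.
    """
    return _eval_batched(cm, particle, np.asarray(conc_rel, float),
                         np.asarray(enz_rel, float), want_jac=True)


def enzyme_map_matrix(cm: CompiledModel) -> np.ndarray:
    """0/1 matrix (reactions x enzymes); dv/de_j = v_j/e_j on its support."""
    E = np.zeros((cm.n_reactions, len(cm.model.enzymes)))
    for rxn in cm.model.enzymatic_reactions:
        E[cm.model.rxn_index[rxn.id], cm.model.enzymes.index(rxn.enzyme_id)] = 1.0
    return E


def haldane_residuals(cm: CompiledModel, particle: KineticParticle) -> dict[str, float]:
    """|sum ln(kf*cf/(kr*cr)) + dG_r/RT| per cycle at reference concentrations.

    Zero (to rounding) for particles built by :func:`sample_particle`; the
    residual is expressed per unit RT.
    """
    rt = particle.refstate.rt
    conc = particle.refstate.ref_conc
    out = {}
    for cp, p in zip(cm.patterns, particle.params):
        for cyc in cp.pattern.cycles:
            acc = 0.0
            for si in cyc.step_indices:
                cf = conc[cp.mf[si]] if cp.mf[si] >= 0 else 1.0
                cr = conc[cp.mr[si]] if cp.mr[si] >= 0 else 1.0
                acc += np.log(p.kf[si] * cf) - np.log(p.kr[si] * cr)
            out[cyc.reaction_id] = abs(acc + particle.refstate.dg_r[cyc.reaction_id] / rt)
    return out


def anchoring_residuals(cm: CompiledModel, particle: KineticParticle) -> np.ndarray:
    """Relative deviation of v(reference) from v_ref for every reaction."""
    ones_c = np.ones(len(cm.model.metabolites))
    ones_e = np.ones(len(cm.model.enzymes))
    v = network_rates(cm, particle, ones_c, ones_e)
    return np.abs(v - particle.v_ref.values) / np.maximum(np.abs(particle.v_ref.values), 1e-300)
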