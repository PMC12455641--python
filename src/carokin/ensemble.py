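"""Condition simulation, discrepancy scoring and ABC rejection.

Each sampled particle is asked to reproduce every non-reference condition:
relative enzyme levels are confined to their experimental 95% confidence
boxes and relative metabolite concentrations to fixed physiological windows
(0.01-100 for balanced, 0.1-10 for unbalanced species), and a steady state
is sought by driving the balanced-metabolite imbalance ||N v|| to zero with
a bounded trust-region least-squares solve started from the enzyme means.
Particles that cannot reach steady state in some condition are flagged
infeasible and excluded from the posterior.  The discrepancy between
simulated and measured free fluxes is a weighted Euclidean norm with
inverse-variance weights derived from the measurement confidence intervals;
the posterior sample is the lowest-scoring cutoff fraction (ABC rejection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .dataprep import ConditionData
from .kinetics import (CompiledModel, KineticParticle, enzyme_map_matrix,
                       network_rates, rates_and_conc_jacobian, sample_particle)
from .network import FluxState, stoichiometric_matrix
from .thermo import ThermoSampler

FREE_FLUX_IDS = ("SK_lyc", "SK_b_car", "ERG9b")


class EnsembleError(ValueError):
    pass


@dataclass
class SolverOptions:
    balanced_rel_bounds: tuple[float, float] = (0.01, 100.0)
    unbalanced_rel_bounds: tuple[float, float] = (0.1, 10.0)
    max_nfev: int = 150           # per solve stage
    imbalance_tol: float = 1e-6   # times the median reference flux


@dataclass
class SimulatedCondition:
    condition_id: str
    conc_rel: np.ndarray
    enz_rel: np.ndarray
    flux: np.ndarray
    residual: float               # max absolute balanced imbalance (mmol/L/h)
    feasible: bool

    def free_fluxes(self, rxn_index: Mapping[str, int]) -> dict[str, float]:
        return {k: float(self.flux[rxn_index[k]]) for k in FREE_FLUX_IDS}


@dataclass
class EnsembleResult:
    level: str
    condition_ids: list[str]
    particles: list[KineticParticle]
    sq_errors: np.ndarray         # (n_particles, n_conditions), nan if infeasible
    feasible: np.ndarray          # (n_particles, n_conditions) bool
    simulations: list[list[SimulatedCondition | None]] = field(default_factory=list)
    posterior: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.particles)

    def scores(self, condition_subset: Sequence[str] | None = None) -> np.ndarray:
        """Per-particle discrepancy over a condition subset (nan = infeasible)."""
        ids = self.condition_ids if condition_subset is None else list(condition_subset)
        cols = [self.condition_ids.index(c) for c in ids]
        sq = self.sq_errors[:, cols]
        ok = self.feasible[:, cols].all(axis=1)
        out = np.sqrt(sq.sum(axis=1))
        out[~ok] = np.nan
        return out


# ---------------------------------------------------------------------------
# steady-state simulation of one condition
# ---------------------------------------------------------------------------

def _enzyme_boxes(cm: CompiledModel, cond: ConditionData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    enzymes = cm.model.enzymes
    mean = np.ones(len(enzymes))
    lo = np.ones(len(enzymes))
    hi = np.ones(len(enzymes))
    for i, e in enumerate(enzymes):
        m, l, h = cond.rel_enzyme.get(e, (1.0, 1.0, 1.0))
        mean[i], lo[i], hi[i] = m, l, h
    eps = 1e-9 * np.maximum(1.0, np.abs(mean))
    lo = np.minimum(lo, mean) - eps
    hi = np.maximum(hi, mean) + eps
    return mean, lo, hi


class SteadyStateSolver:
    """Cached steady-state solver for one compiled model.

    The solve proceeds in two stages: first the balanced log-concentrations
    alone, with enzymes clamped at the means of the experimental relative
    levels (the documented initial guess) - a square, fast problem that
    succeeds for most particles; if it stalls, a joint solve over
    concentrations and enzymes within their confidence boxes is attempted.
    """

    def __init__(self, cm: CompiledModel, options: SolverOptions = SolverOptions()):
        self.cm = cm
        self.options = options
        model = cm.model
        self.n_m = len(model.metabolites)
        self.N_bal = stoichiometric_matrix(model, balanced_only=True)
        self.E_map = enzyme_map_matrix(cm)
        balanced = np.array([m.balanced for m in model.metabolites])
        self.bal_idx = np.flatnonzero(balanced)
        self.x_lo = np.where(balanced, np.log(options.balanced_rel_bounds[0]),
                             np.log(options.unbalanced_rel_bounds[0]))
        self.x_hi = np.where(balanced, np.log(options.balanced_rel_bounds[1]),
                             np.log(options.unbalanced_rel_bounds[1]))

    def _stage1(self, particle, e_mean, scale, x_fixed=None, x_lo=None, x_hi=None):
        cm, N = self.cm, self.N_bal
        bal = self.bal_idx
        x_lo = self.x_lo if x_lo is None else x_lo
        x_hi = self.x_hi if x_hi is None else x_hi
        base = np.zeros(self.n_m) if x_fixed is None else np.asarray(x_fixed, float)

        def assemble(x):
            cr = np.exp(base)
            cr[bal] = np.exp(x)
            return cr

        def fun(x):
            return (N @ network_rates(cm, particle, assemble(x), e_mean)) / scale

        def jac(x):
            _, J = rates_and_conc_jacobian(cm, particle, assemble(x), e_mean)
            return (N @ J[:, bal]) / scale

        x0 = np.clip(base[bal], x_lo[bal], x_hi[bal])
        res = least_squares(fun, x0, jac=jac,
                            bounds=(x_lo[bal], x_hi[bal]), method="trf",
                            xtol=1e-13, ftol=1e-13, gtol=1e-14,
                            max_nfev=self.options.max_nfev)
        return assemble(res.x), e_mean.copy(), 2.0 * res.cost

    def _stage2(self, particle, cr0, er0, e_lo, e_hi, scale, x_lo=None, x_hi=None):
        cm, N = self.cm, self.N_bal
        n_m = self.n_m
        x_lo = self.x_lo if x_lo is None else x_lo
        x_hi = self.x_hi if x_hi is None else x_hi

        def split(z):
            return np.exp(z[:n_m]), z[n_m:]

        def fun(z):
            cr, er = split(z)
            return (N @ network_rates(cm, particle, cr, er)) / scale

        def jac(z):
            cr, er = split(z)
            v, Jc = rates_and_conc_jacobian(cm, particle, cr, er)
            Je = self.E_map * (v[:, None] / np.maximum(er[None, :], 1e-12))
            return np.hstack([N @ Jc, N @ Je]) / scale

        z0 = np.concatenate([np.log(np.clip(cr0, np.exp(x_lo), np.exp(x_hi))),
                             np.clip(er0, e_lo, e_hi)])
        lo = np.concatenate([x_lo, e_lo])
        hi = np.concatenate([x_hi, e_hi])
        res = least_squares(fun, z0, jac=jac, bounds=(lo, hi), method="trf",
                            xtol=1e-13, ftol=1e-13, gtol=1e-14,
                            max_nfev=self.options.max_nfev)
        cr, er = split(res.x)
        return cr, er, 2.0 * res.cost

    def solve_boxes(
        self,
        particle: KineticParticle,
        label: str,
        e_mean: np.ndarray,
        e_lo: np.ndarray,
        e_hi: np.ndarray,
        x_lo: np.ndarray | None = None,
        x_hi: np.ndarray | None = None,
        x_start: np.ndarray | None = None,
    ) -> SimulatedCondition:
        """Steady state under explicit enzyme and log-concentration boxes."""
        cm = self.cm
        scale = float(np.median(np.abs(particle.v_ref.values)))
        tol_cost = (self.options.imbalance_tol) ** 2  # scaled units
        try:
            cr, er, cost = self._stage1(particle, np.clip(e_mean, e_lo, e_hi), scale,
                                        x_fixed=x_start, x_lo=x_lo, x_hi=x_hi)
            if cost > tol_cost:
                cr, er, cost = self._stage2(particle, cr, er, e_lo, e_hi, scale,
                                            x_lo=x_lo, x_hi=x_hi)
            v = network_rates(cm, particle, cr, er)
        except Exception:
            return SimulatedCondition(label, np.ones(self.n_m), e_mean,
                                      np.full(cm.n_reactions, np.nan), np.inf, False)
        residual = float(np.max(np.abs(self.N_bal @ v)))
        feasible = residual <= self.options.imbalance_tol * scale
        return SimulatedCondition(label, cr, er, v, residual, feasible)

    def solve(self, particle: KineticParticle, cond: ConditionData) -> SimulatedCondition:
        e_mean, e_lo, e_hi = _enzyme_boxes(self.cm, cond)
        return self.solve_boxes(particle, cond.strain, e_mean, e_lo, e_hi)


def simulate_condition(
    cm: CompiledModel,
    particle: KineticParticle,
    cond: ConditionData,
    options: SolverOptions = SolverOptions(),
) -> SimulatedCondition:
    """Find a steady state consistent with a condition's enzyme CI box."""
    return SteadyStateSolver(cm, options).solve(particle, cond)


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------

def _weights(cond: ConditionData) -> dict[str, float]:
    w = {}
    for k in FREE_FLUX_IDS:
        m, lo, hi = cond.free_fluxes[k]
        sigma = (hi - lo) / 2.0 / 1.959963984540054
        if sigma <= 0:
            raise EnsembleError(f"zero-width CI for flux {k!r} in condition {cond.strain!r}")
        w[k] = 1.0 / sigma**2
    return w


def condition_sq_error(sim_free: Mapping[str, float], cond: ConditionData) -> float:
    """Weighted squared error of simulated vs observed free fluxes."""
    w = _weights(cond)
    return float(sum(w[k] * (sim_free[k] - cond.free_fluxes[k][0]) ** 2 for k in FREE_FLUX_IDS))


def discrepancy(
    sim_free_by_condition: Mapping[str, Mapping[str, float]],
    conditions: Mapping[str, ConditionData],
) -> float:
    """Weighted Euclidean discrepancy across conditions (sqrt of summed squares)."""
    total = 0.0
    for cid, cond in conditions.items():
        total += condition_sq_error(sim_free_by_condition[cid], cond)
    return float(np.sqrt(total))


# ---------------------------------------------------------------------------
# prior sampling, rejection, cross-validation
# ---------------------------------------------------------------------------

def run_prior(
    cm: CompiledModel,
    sampler: ThermoSampler,
    v_ref: FluxState,
    conditions: Sequence[ConditionData],
    n_particles: int,
    seed,
    particles: Sequence[KineticParticle] | None = None,
    options: SolverOptions = SolverOptions(),
    tilt: Mapping[str, tuple[float, float]] | None = None,
    keep_simulations: bool = False,
) -> EnsembleResult:
    """Sample a prior ensemble and simulate every training condition.

    ``particles`` may inject pre-built particles (e.g. a known ground truth);
    the remaining ``n_particles - len(particles)`` are sampled.  Per-particle
    randomness derives from a root seed by counter offset, so results do not
    depend on evaluation order.
    """
    if n_particles < 1:
        raise EnsembleError("need at least one particle")
    rxn_index = cm.model.rxn_index
    injected = list(particles or [])
    if len(injected) > n_particles:
        raise EnsembleError("more injected particles than n_particles")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_particles)
    solver = SteadyStateSolver(cm, options)
    all_particles: list[KineticParticle] = []
    sq = np.full((n_particles, len(conditions)), np.nan)
    ok = np.zeros((n_particles, len(conditions)), dtype=bool)
    sims: list[list[SimulatedCondition | None]] = []
    for i in range(n_particles):
        if i < len(injected):
            p = injected[i]
        else:
            s_thermo, s_kin = children[i].spawn(2)
            refstate = sampler.sample(s_thermo)
            p = sample_particle(cm, refstate, v_ref, s_kin, tilt=tilt)
        all_particles.append(p)
        row: list[SimulatedCondition | None] = []
        for j, cond in enumerate(conditions):
            sim = solver.solve(p, cond)
            ok[i, j] = sim.feasible
            if sim.feasible:
                sq[i, j] = condition_sq_error(sim.free_fluxes(rxn_index), cond)
            row.append(sim if keep_simulations else None)
        sims.append(row)
    return EnsembleResult(
        level=cm.level.value,
        condition_ids=[c.strain for c in conditions],
        particles=all_particles,
        sq_errors=sq,
        feasible=ok,
        simulations=sims,
    )


def reject(ens: EnsembleResult, cutoff_fraction: float,
           condition_subset: Sequence[str] | None = None) -> EnsembleResult:
    """Flag the lowest-scoring cutoff fraction as the posterior sample.

    The cutoff count is ``floor(cutoff * n)`` over all particles; infeasible
    particles never enter the posterior.  Ties break by particle index.
    """
    if not (0.0 < cutoff_fraction <= 1.0):
        raise EnsembleError("cutoff fraction must be in (0, 1]")
    scores = ens.scores(condition_subset)
    k = int(np.floor(cutoff_fraction * ens.n))
    k = max(k, 1) if cutoff_fraction > 0 else 0
    feasible_idx = np.flatnonzero(~np.isnan(scores))
    if len(feasible_idx) < k:
        raise EnsembleError(
            f"only {len(feasible_idx)} feasible particles, need {k} for the cutoff"
        )
    order = feasible_idx[np.lexsort((feasible_idx, scores[feasible_idx]))]
    flags = np.zeros(ens.n, dtype=bool)
    flags[order[:k]] = True
    ens.posterior = flags
    return ens


def compare_prior_posterior(ens: EnsembleResult,
                            condition_subset: Sequence[str] | None = None
                            ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: posterior scores vs the full prior."""
    if ens.posterior is None or not ens.posterior.any():
        raise EnsembleError("no posterior flags set; run reject() first")
    scores = ens.scores(condition_subset)
    prior = scores[~np.isnan(scores)]
    post = scores[ens.posterior]
    if np.ptp(prior) == 0 and np.ptp(post) == 0 and (len(prior) == 0 or prior[0] == post[0]):
        warnings.warn("degenerate score distributions; rank-sum p set to 1")
        return 0.0, 1.0
    stat, p = stats.ranksums(post, prior)
    return float(stat), float(p)


@dataclass
class CrossValidationSummary:
    train_ids: list[str]
    test_ids: list[str]
    prior_test_median: float
    posterior_test_median: float
    ranksum_stat: float
    ranksum_p: float


def cross_validate(
    ens: EnsembleResult,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    cutoff_fraction: float,
    both_directions: bool = True,
) -> list[CrossValidationSummary]:
    """Rejection on training conditions, evaluation on held-out conditions.

    Reuses the per-condition squared errors of an already-simulated ensemble.
    With ``both_directions`` the train/test roles are also swapped.
    """
    if not test_ids:
        raise EnsembleError("empty test set")
    if set(train_ids) == set(test_ids):
        warnings.warn("train and test conditions are identical; degenerate validation")
    splits = [(list(train_ids), list(test_ids))]
    if both_directions and set(train_ids) != set(test_ids):
        splits.append((list(test_ids), list(train_ids)))
    out = []
    for tr, te in splits:
        reject(ens, cutoff_fraction, condition_subset=tr)
        test_scores = ens.scores(te)
        prior = test_scores[~np.isnan(test_scores)]
        post = test_scores[ens.posterior & ~np.isnan(test_scores)]
        if len(post) == 0:
            raise EnsembleError("no posterior particle is feasible on the test conditions")
        stat, p = stats.ranksums(post, prior)
        out.append(CrossValidationSummary(
            train_ids=tr, test_ids=te,
            prior_test_median=float(np.median(prior)),
            posterior_test_median=float(np.median(post)),
            ranksum_stat=float(stat), ranksum_p=float(p),
        ))
    return out
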