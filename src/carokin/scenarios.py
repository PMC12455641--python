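"""Perturbation scenarios on posterior ensembles and limitation-risk scoring.

Enzyme perturbations clamp the target enzyme to a relative factor (with 1%
slack to avoid over-constraining the steady-state solve) while every other
enzyme stays near 1 (also 1% slack) and metabolites move freely within their
physiological windows.  Metabolite perturbations clamp one unbalanced
metabolite (1% slack) and give all enzymes 10% freedom.  A composable base
state (e.g. CrtYB x 1.67, roughly two extra gene copies) lets secondary
perturbations stack on top of a primary intervention.

The robustness criterion classifies a component by the ensemble fraction f
of particles whose beta-carotene sink flux falls below the lower bound of
the reference-condition confidence interval: none if f <= 5%, medium
potential to become limiting if 5% < f <= 20%, high if f > 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble import SolverOptions, SteadyStateSolver
from .kinetics import CompiledModel, KineticParticle


class ScenarioError(ValueError):
    pass


DEFAULT_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0)   # log2-spaced step changes
HMG1_SWEEP_FACTORS = (1.0, 10.0, 17.8, 31.6, 56.2, 100.0)


@dataclass(frozen=True)
class PerturbationSpec:
    target: str
    factors: tuple[float, ...] = DEFAULT_FACTORS
    mode: str = "enzyme"                       # "enzyme" | "metabolite"
    base_state: Mapping[str, float] | None = None  # prior enzyme perturbation

    def __post_init__(self) -> None:
        if self.mode not in ("enzyme", "metabolite"):
            raise ScenarioError(f"unknown perturbation mode {self.mode!r}")
        if any(f <= 0 for f in self.factors):
            raise ScenarioError("perturbation factors must be positive")


@dataclass
class ScenarioResult:
    spec: PerturbationSpec
    factors: np.ndarray
    sk_b_car: np.ndarray      # (n_particles, n_factors), nan where infeasible
    sk_lyc: np.ndarray
    erg9b: np.ndarray
    feasible: np.ndarray      # bool, same shape
    extra: dict = field(default_factory=dict)

    @property
    def log10_ratio(self) -> np.ndarray:
        """log10(SK_b_car / SK_lyc) per particle and factor."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log10(self.sk_b_car / self.sk_lyc)

    def median(self, which: str = "sk_b_car") -> np.ndarray:
        """Per-factor median over feasible particles."""
        arr = getattr(self, which)
        return np.nanmedian(arr, axis=0)

    def delta_sign(self, which: str = "sk_b_car", baseline_factor: float = 1.0) -> np.ndarray:
        """Per-particle sign of the change at the largest factor vs baseline."""
        arr = getattr(self, which)
        if not np.any(np.isclose(self.factors, baseline_factor)):
            raise ScenarioError(f"baseline factor {baseline_factor} not in the grid")
        j0 = int(np.argmin(np.abs(self.factors - baseline_factor)))
        return np.sign(arr[:, -1] - arr[:, j0])


def _run(
    cm: CompiledModel,
    particles: Sequence[KineticParticle],
    spec: PerturbationSpec,
    options: SolverOptions,
    slack_target: float,
    enzyme_slack: float,
) -> ScenarioResult:
    model = cm.model
    solver = SteadyStateSolver(cm, options)
    n_e = len(model.enzymes)
    n_m = len(model.metabolites)
    factors = np.asarray(spec.factors, float)
    shape = (len(particles), len(factors))
    out = {k: np.full(shape, np.nan) for k in ("sk_b_car", "sk_lyc", "erg9b")}
    feas = np.zeros(shape, dtype=bool)
    ridx = {k: model.rxn_index[k] for k in ("SK_b_car", "SK_lyc", "ERG9b")}

    base = dict(spec.base_state or {})
    for e in base:
        if e not in model.enzymes:
            raise ScenarioError(f"base-state enzyme {e!r} not in model")

    for jf, f in enumerate(factors):
        e_mean = np.ones(n_e)
        for e, bf in base.items():
            e_mean[model.enzymes.index(e)] = bf
        x_lo = x_hi = None
        x_start = None
        if spec.mode == "enzyme":
            if spec.target not in model.enzymes:
                raise ScenarioError(f"target enzyme {spec.target!r} not in model")
            e_mean[model.enzymes.index(spec.target)] = f
            e_lo = e_mean * (1.0 - slack_target)
            e_hi = e_mean * (1.0 + slack_target)
        else:
            if spec.target not in model.met_index:
                raise ScenarioError(f"target metabolite {spec.target!r} not in model")
            if model.metabolite(spec.target).balanced:
                raise ScenarioError(
                    f"{spec.target!r} is balanced; metabolite perturbations apply "
                    "to unbalanced (external) species"
                )
            e_lo = e_mean * (1.0 - enzyme_slack)
            e_hi = e_mean * (1.0 + enzyme_slack)
            mi = model.met_index[spec.target]
            x_lo = solver.x_lo.copy()
            x_hi = solver.x_hi.copy()
            x_lo[mi] = np.log(f * (1.0 - slack_target))
            x_hi[mi] = np.log(f * (1.0 + slack_target))
            x_start = np.zeros(n_m)
            x_start[mi] = np.log(f)
        for ip, p in enumerate(particles):
            sim = solver.solve_boxes(p, f"{spec.target}x{f:g}", e_mean, e_lo, e_hi,
                                     x_lo=x_lo, x_hi=x_hi, x_start=x_start)
            feas[ip, jf] = sim.feasible
            if sim.feasible:
                out["sk_b_car"][ip, jf] = sim.flux[ridx["SK_b_car"]]
                out["sk_lyc"][ip, jf] = sim.flux[ridx["SK_lyc"]]
                out["erg9b"][ip, jf] = sim.flux[ridx["ERG9b"]]
    return ScenarioResult(spec=spec, factors=factors, feasible=feas,
                          sk_b_car=out["sk_b_car"], sk_lyc=out["sk_lyc"],
                          erg9b=out["erg9b"])


def perturb_enzyme(
    cm: CompiledModel,
    particles: Sequence[KineticParticle],
    spec: PerturbationSpec,
    options: SolverOptions = SolverOptions(),
) -> ScenarioResult:
    """One-enzyme-at-a-time perturbation; other enzymes held near 1 (1%)."""
    if spec.mode != "enzyme":
        raise ScenarioError("spec.mode must be 'enzyme'")
    return _run(cm, particles, spec, options, slack_target=0.01, enzyme_slack=0.01)


def perturb_metabolite(
    cm: CompiledModel,
    particles: Sequence[KineticParticle],
    spec: PerturbationSpec,
    options: SolverOptions = SolverOptions(),
) -> ScenarioResult:
    """Clamp one unbalanced metabolite (1%); enzymes free within 10%."""
    if spec.mode != "metabolite":
        raise ScenarioError("spec.mode must be 'metabolite'")
    return _run(cm, particles, spec, options, slack_target=0.01, enzyme_slack=0.10)


def hmg1_activity_sweep(
    cm: CompiledModel,
    particles: Sequence[KineticParticle],
    factors: Sequence[float] = HMG1_SWEEP_FACTORS,
    options: SolverOptions = SolverOptions(),
) -> ScenarioResult:
    """HMG1 activity increased 10- to 100-fold (truncated-HMG1 emulation)."""
    if "HMG1" not in cm.model.enzymes:
        raise ScenarioError("HMG1 not in model")
    spec = PerturbationSpec(target="HMG1", factors=tuple(factors), mode="enzyme")
    res = perturb_enzyme(cm, particles, spec, options)
    res.extra["sk_b_car_delta_sign"] = res.delta_sign("sk_b_car")
    return res


def classify_fraction(f: float, thresholds: Mapping[str, float] | None = None) -> str:
    """Map an ensemble fraction to a limitation-risk class (strict bounds)."""
    th = {"medium": 0.05, "high": 0.20, **(thresholds or {})}
    if not (0.0 <= f <= 1.0):
        raise ScenarioError("fraction must be in [0, 1]")
    if f > th["high"]:
        return "high"
    if f > th["medium"]:
        return "medium"
    return "none"


def robustness_classify(
    sk_b_car: np.ndarray,
    reference_ci_lo: float,
    thresholds: Mapping[str, float] | None = None,
) -> tuple[str, float]:
    """Limitation-risk class of one component from its perturbed fluxes.

    ``sk_b_car`` holds the per-particle beta-carotene sink fluxes under the
    perturbation (nan = infeasible solve, excluded); ``reference_ci_lo`` is
    the lower bound of the measured reference-flux confidence interval.
    Returns (class, fraction below threshold).
    """
    vals = np.asarray(sk_b_car, float).ravel()
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ScenarioError("no feasible particles to classify")
    f = float(np.mean(vals < reference_ci_lo))
    return classify_fraction(f, thresholds), f
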