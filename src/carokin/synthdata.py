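"""Ground-truth particles and synthetic multi-strain datasets.

The generator emulates the experimental design the pipeline is built for:
a reference producer strain defines the anchor condition, additional strains
differ by enzyme-level multipliers (heterologous gene copy-number effects),
fluxes are observed through multiplicative lognormal noise with 95%
confidence intervals, and transcript levels are observed as qPCR threshold
cycles with gene-specific amplification efficiencies.

Scenario-directed tilting shapes where the ground truth puts its flux
control: ``crtyb_limited`` saturates the promiscuous CrtYB enzyme (small
free-enzyme share, so its rate is insensitive to substrate build-up and the
enzyme level itself limits beta-carotene flux) while keeping the other
enzymes far from saturation; ``erg13_limited`` does the same for ERG13.

Default strain designs mirror a three-strain layout in which the two
non-reference strains express the heterologous carotenoid genes at roughly
61/89/68% and 27/51/33% of the reference (CrtE/CrtI/CrtYB).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .dataprep import ConditionData, QpcrTable, reference_condition_fluxes
from .kinetics import (CompiledModel, KineticParticle, StructureLevel,
                       compile_model, network_rates, rates_and_conc_jacobian,
                       sample_particle)
from .network import FluxState, NetworkModel, propagate_fluxes, stoichiometric_matrix
from .thermo import ThermoSampler, ThermoTable, load_thermo_table


class SynthDataError(ValueError):
    pass


DEFAULT_STRAINS: dict[str, dict[str, float]] = {
    "synth3": {"CrtE": 0.61, "CrtI": 0.89, "CrtYB": 0.68},
    "synth2": {"CrtE": 0.27, "CrtI": 0.51, "CrtYB": 0.33},
}

_SCENARIO_TILTS: dict[str, dict[str, tuple[float, float]]] = {
    "neutral": {},
    "crtyb_limited": {"CrtYB": (0.01, 0.04)},
    "erg13_limited": {"ERG13": (0.01, 0.04)},
}


@dataclass
class NoiseModel:
    flux_sd: float = 0.1       # lognormal sd of flux observations
    enzyme_sd: float = 0.05    # lognormal sd of relative enzyme levels
    cq_sd: float = 0.2         # Cq replicate standard deviation (cycles)
    sigma_floor: float = 1e-6  # minimal relative CI half-width scale


@dataclass
class SyntheticStudy:
    scenario: str
    cm: CompiledModel
    truth: KineticParticle
    v_ref: FluxState
    strains: dict[str, dict[str, float]]
    noise: NoiseModel
    conditions: list[ConditionData]
    true_free_fluxes: dict[str, dict[str, float]]
    seed: int


def default_reference_flux_state(model: NetworkModel) -> FluxState:
    """Anchor flux vector from the packaged chemostat fixture (best producer)."""
    ff = reference_condition_fluxes()
    return propagate_fluxes(model, {k: v[0] for k, v in ff.items()})


def generate_truth(
    model: NetworkModel,
    level: StructureLevel | str,
    seed,
    scenario: str = "neutral",
    thermo: ThermoTable | None = None,
    v_ref: FluxState | None = None,
) -> tuple[CompiledModel, KineticParticle]:
    """Sample a ground-truth particle with scenario-directed saturation tilting.

    In the ``*_limited`` scenarios the target enzyme's free-enzyme abundance
    share is forced low (saturation: high flux control) and every other
    enzyme's share high (first-order operation: control passed downstream).
    """
    if scenario not in _SCENARIO_TILTS:
        raise SynthDataError(f"unknown scenario {scenario!r}; options: {sorted(_SCENARIO_TILTS)}")
    cm = compile_model(model, level)
    thermo = thermo or load_thermo_table()
    v_ref = v_ref or default_reference_flux_state(model)
    tilt = dict(_SCENARIO_TILTS[scenario])
    if tilt:
        for e in model.enzymes:
            tilt.setdefault(e, (0.85, 0.95))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_thermo, s_kin = ss.spawn(2)
    refstate = ThermoSampler(model, thermo).sample(s_thermo)
    particle = sample_particle(cm, refstate, v_ref, s_kin, tilt=tilt or None)
    return cm, particle


def solve_strain_state(
    cm: CompiledModel,
    particle: KineticParticle,
    multipliers: Mapping[str, float],
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact steady state of a particle at clamped enzyme multipliers.

    Unbalanced metabolites stay at their reference concentrations (the strain
    differs only in enzyme dosage); the balanced log-concentrations are the
    unknowns.  Returns (relative concentrations, flux vector).
    """
    model = cm.model
    balanced = np.array([m.balanced for m in model.metabolites])
    bal_idx = np.flatnonzero(balanced)
    N_bal = stoichiometric_matrix(model, balanced_only=True)
    enz = np.ones(len(model.enzymes))
    for e, f in multipliers.items():
        if e not in model.enzymes:
            raise SynthDataError(f"unknown enzyme {e!r} in strain definition")
        enz[model.enzymes.index(e)] = f
    scale = float(np.median(np.abs(particle.v_ref.values)))

    def assemble(x):
        cr = np.ones(len(model.metabolites))
        cr[bal_idx] = np.exp(x)
        return cr

    def fun(x):
        v = network_rates(cm, particle, assemble(x), enz)
        return (N_bal @ v) / scale

    def jac(x):
        _, J = rates_and_conc_jacobian(cm, particle, assemble(x), enz)
        return (N_bal @ J[:, bal_idx]) / scale

    lim = np.log(1e4)
    res = least_squares(fun, np.zeros(len(bal_idx)), jac=jac,
                        bounds=(-lim, lim), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    cr = assemble(res.x)
    v = network_rates(cm, particle, cr, enz)
    resid = float(np.max(np.abs(N_bal @ v)))
    if resid > tol * scale:
        raise SynthDataError(
            f"no steady state for multipliers {dict(multipliers)} "
            f"(residual {resid:.2e} vs tolerance {tol * scale:.2e})"
        )
    return cr, v


def synth_conditions(
    cm: CompiledModel,
    truth: KineticParticle,
    strains: Mapping[str, Mapping[str, float]],
    noise: NoiseModel,
    seed,
    growth_rate: float = 0.101,
) -> tuple[list[ConditionData], dict[str, dict[str, float]]]:
    """Noisy ConditionData per strain plus the exact generating free fluxes."""
    rng = np.random.default_rng(seed)
    model = cm.model
    balanced = np.array([m.balanced for m in model.metabolites])
    z = 1.959963984540054
    conditions = []
    true_free = {}
    for name, mult in strains.items():
        cr, v = solve_strain_state(cm, truth, mult)
        # the generating state must live inside the windows the inference
        # stage assumes, or the synthetic data would be unexplainable by
        # construction
        if np.any(cr[balanced] < 0.01) or np.any(cr[balanced] > 100.0):
            raise SynthDataError(
                f"strain {name!r} ({dict(mult)}): generating steady state leaves "
                "the 0.01-100 relative concentration window"
            )
        free = {k: float(v[model.rxn_index[k]]) for k in ("SK_lyc", "SK_b_car", "ERG9b")}
        true_free[name] = free
        sd = max(noise.flux_sd, noise.sigma_floor)
        fluxes = {}
        for k, f in free.items():
            obs = f * np.exp(rng.normal(0.0, noise.flux_sd))
            fluxes[k] = (obs, obs * np.exp(-z * sd), obs * np.exp(z * sd))
        esd = max(noise.enzyme_sd, noise.sigma_floor)
        rel = {}
        for e in model.enzymes:
            m = mult.get(e, 1.0) * np.exp(rng.normal(0.0, noise.enzyme_sd))
            rel[e] = (m, m * np.exp(-z * esd), m * np.exp(z * esd))
        conditions.append(ConditionData(strain=name, growth_rate=growth_rate,
                                        free_fluxes=fluxes, rel_enzyme=rel))
    return conditions, true_free


def synth_qpcr(
    expression_ratios: Mapping[str, Mapping[str, float]],
    efficiencies: Mapping[str, float],
    replicate_sd: float,
    seed,
    reference_condition: str = "ref",
    cq_reference: float = 20.0,
    n_replicates: int = 3,
) -> list[QpcrTable]:
    """qPCR tables encoding known expression ratios.

    ``expression_ratios`` maps condition -> gene -> ratio vs the reference;
    Cq = Cq_ref - log(ratio)/log(E) + Normal(0, sd) per replicate.  Tables
    for the reference condition itself are included.
    """
    rng = np.random.default_rng(seed)
    tables = []
    genes = sorted({g for d in expression_ratios.values() for g in d})
    for gene in genes:
        E = efficiencies[gene]
        if E <= 1.0:
            raise SynthDataError(f"efficiency for {gene!r} must exceed 1")
        tables.append(QpcrTable(
            gene=gene, condition=reference_condition,
            cq_replicates=list(cq_reference + rng.normal(0, replicate_sd, n_replicates)),
            efficiency=E,
        ))
        for cond, ratios in expression_ratios.items():
            if gene not in ratios:
                continue
            ratio = ratios[gene]
            if ratio <= 0:
                raise SynthDataError(f"expression ratio for {gene!r} must be positive")
            cq = cq_reference - np.log(ratio) / np.log(E)
            tables.append(QpcrTable(
                gene=gene, condition=cond,
                cq_replicates=list(cq + rng.normal(0, replicate_sd, n_replicates)),
                efficiency=E,
            ))
    return tables


def make_study(
    model: NetworkModel,
    level: StructureLevel | str = StructureLevel.simple,
    scenario: str = "neutral",
    seed: int = 0,
    strains: Mapping[str, Mapping[str, float]] | None = None,
    noise: NoiseModel | None = None,
) -> SyntheticStudy:
    """One-call synthetic study: truth particle plus noisy strain conditions.

    Ground truths are drawn conditional on the study design: a candidate
    truth under which some strain admits no steady state inside the assumed
    physiological windows is discarded and redrawn (bounded retries), since
    such a truth could not have produced the experiment being emulated.
    """
    noise = noise or NoiseModel()
    strains = {k: dict(v) for k, v in (strains or DEFAULT_STRAINS).items()}
    ss = np.random.SeedSequence(seed)
    s_truth, s_cond = ss.spawn(2)
    last_err: Exception | None = None
    for s_try in s_truth.spawn(20):
        cm, truth = generate_truth(model, level, s_try, scenario)
        try:
            conditions, true_free = synth_conditions(cm, truth, strains, noise, s_cond)
            break
        except SynthDataError as err:
            last_err = err
    else:
        raise SynthDataError(
            f"no compatible ground truth found for the strain design: {last_err}"
        )
    return SyntheticStudy(
        scenario=scenario, cm=cm, truth=truth, v_ref=truth.v_ref,
        strains=strains, noise=noise, conditions=conditions,
        true_free_fluxes=true_free, seed=int(seed),
    )
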