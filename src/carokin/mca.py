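"""Metabolic control analysis on kinetic particles and ensembles.

Scaled elasticities (d ln v / d ln c, d ln v / d ln e) are obtained from the
analytic derivatives of the enzyme-state solve (central log-space finite
differences are available as an independent cross-check).  Control
coefficients follow the standard matrix formulae: with N_r the reduced
balanced stoichiometry, L the link matrix and dv/dc the unscaled Jacobian,

    C_S_unscaled = -L (N_r dv/dc L)^-1 N_r
    C_J_unscaled = I + (dv/dc) C_S_unscaled

scaled by reference fluxes/concentrations so the summation theorems hold:
flux-control rows sum to 1, concentration-control rows to 0.  Response
coefficients to enzyme levels and to unbalanced (external) metabolites
compose control with the corresponding elasticities.

Ensemble summaries bootstrap the mean of each coefficient over the posterior
particles; two-sided significance uses the percentile method with Bonferroni
correction across the coefficient family under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import (CompiledModel, KineticParticle, enzyme_map_matrix,
                       network_rates, rates_and_conc_jacobian)
from .network import stoichiometric_matrix


class MCAError(ValueError):
    pass


@dataclass
class Elasticities:
    """Scaled local sensitivities at one state."""

    conc: np.ndarray       # (reactions x metabolites), d ln v / d ln c
    enzyme: np.ndarray     # (reactions x enzymes), d ln v / d ln e
    flux: np.ndarray       # fluxes at the state (mmol/L/h)
    conc_rel: np.ndarray
    enz_rel: np.ndarray


@dataclass
class ControlMatrices:
    """Scaled control and response coefficients at one state."""

    reaction_ids: tuple[str, ...]
    balanced_ids: tuple[str, ...]
    enzyme_ids: tuple[str, ...]
    unbalanced_ids: tuple[str, ...]
    CJ: np.ndarray         # flux control (reactions x reactions)
    CS: np.ndarray         # concentration control (balanced x reactions)
    RJ_e: np.ndarray       # flux response to enzymes (reactions x enzymes)
    RS_e: np.ndarray       # concentration response to enzymes
    RJ_m: np.ndarray       # flux response to unbalanced metabolites
    RS_m: np.ndarray       # concentration response to unbalanced metabolites


def elasticities(
    cm: CompiledModel,
    particle: KineticParticle,
    conc_rel: np.ndarray | None = None,
    enz_rel: np.ndarray | None = None,
    method: str = "analytic",
    fd_step: float = 1e-6,
    steady_tol: float | None = None,
) -> Elasticities:
    """Scaled elasticity matrices at a state (default: the anchor state).

    ``steady_tol`` (times the median reference flux) optionally enforces
    that the state is a steady state before differentiating.
    """
    model = cm.model
    conc_rel = np.ones(len(model.metabolites)) if conc_rel is None else np.asarray(conc_rel, float)
    enz_rel = np.ones(len(model.enzymes)) if enz_rel is None else np.asarray(enz_rel, float)
    if steady_tol is not None:
        N = stoichiometric_matrix(model, balanced_only=True)
        v0 = network_rates(cm, particle, conc_rel, enz_rel)
        scale = float(np.median(np.abs(particle.v_ref.values)))
        if np.max(np.abs(N @ v0)) > steady_tol * scale:
            raise MCAError("state is not a steady state within tolerance")
    if method == "analytic":
        v, J = rates_and_conc_jacobian(cm, particle, conc_rel, enz_rel)
    elif method == "fd":
        v = network_rates(cm, particle, conc_rel, enz_rel)
        J = np.empty((cm.n_reactions, len(conc_rel)))
        for mi in range(len(conc_rel)):
            cp = conc_rel.copy(); cp[mi] *= np.exp(fd_step)
            cmn = conc_rel.copy(); cmn[mi] *= np.exp(-fd_step)
            J[:, mi] = (network_rates(cm, particle, cp, enz_rel)
                        - network_rates(cm, particle, cmn, enz_rel)) / (2 * fd_step)
    else:
        raise MCAError(f"unknown elasticity method {method!r}")
    denom = np.where(np.abs(v) > 1e-300, v, 1.0)
    eps_c = J / denom[:, None]
    eps_e = enzyme_map_matrix(cm)  # d ln v / d ln e = 1 on the catalysed reactions
    return Elasticities(conc=eps_c, enzyme=eps_e, flux=v,
                        conc_rel=conc_rel, enz_rel=enz_rel)


def _link_matrix(N: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce N to independent rows: N = L @ N_r.  Returns (L, N_r, row_idx)."""
    rank = np.linalg.matrix_rank(N)
    if rank == N.shape[0]:
        return np.eye(N.shape[0]), N, np.arange(N.shape[0])
    # pick independent rows via QR with pivoting on N^T
    from scipy.linalg import qr
    _, _, piv = qr(N.T, pivoting=True)
    rows = np.sort(piv[:rank])
    N_r = N[rows]
    L, *_ = np.linalg.lstsq(N_r.T, N.T, rcond=None)
    return L.T, N_r, rows


def control_coefficients_from_elasticities(
    eps_c_bal: np.ndarray,
    N_bal: np.ndarray,
    v: np.ndarray,
    c_bal_rel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (C_J, C_S) from scaled balanced elasticities and stoichiometry.

    Pure-matrix core, usable with hand-built elasticities (e.g. textbook
    two-step chains).  ``v`` are the reference-scaled fluxes used for the
    scaling; concentrations enter only through the scaling so relative units
    (1.0 at the evaluation state) are the default.
    """
    n_rxn, n_bal = eps_c_bal.shape
    c = np.ones(n_bal) if c_bal_rel is None else np.asarray(c_bal_rel, float)
    L, N_r, rows = _link_matrix(N_bal)
    dvdc = (v[:, None] * eps_c_bal) / c[None, :]          # unscaled Jacobian
    Mjac = N_r @ dvdc @ L
    try:
        Minv = np.linalg.inv(Mjac)
    except np.linalg.LinAlgError as exc:
        raise MCAError("singular steady-state Jacobian (structurally unstable particle)") from exc
    CS_uns = -L @ Minv @ N_r
    CJ_uns = np.eye(n_rxn) + dvdc @ CS_uns
    CS = (CS_uns * v[None, :]) / c[:, None]
    CJ = (CJ_uns * v[None, :]) / np.where(np.abs(v) > 1e-300, v, 1.0)[:, None]
    return CJ, CS


def control_coefficients(
    cm: CompiledModel,
    particle: KineticParticle,
    eps: Elasticities | None = None,
) -> ControlMatrices:
    """Full scaled control/response matrices for one particle at a state."""
    model = cm.model
    if eps is None:
        eps = elasticities(cm, particle)
    balanced = np.array([m.balanced for m in model.metabolites])
    bal_idx = np.flatnonzero(balanced)
    unbal_idx = np.flatnonzero(~balanced)
    N_bal = stoichiometric_matrix(model, balanced_only=True)
    CJ, CS = control_coefficients_from_elasticities(
        eps.conc[:, bal_idx], N_bal, eps.flux, eps.conc_rel[bal_idx]
    )
    RJ_e = CJ @ eps.enzyme
    RS_e = CS @ eps.enzyme
    RJ_m = CJ @ eps.conc[:, unbal_idx]
    RS_m = CS @ eps.conc[:, unbal_idx]
    return ControlMatrices(
        reaction_ids=model.reaction_ids,
        balanced_ids=tuple(model.balanced_ids),
        enzyme_ids=tuple(model.enzymes),
        unbalanced_ids=tuple(model.unbalanced_ids),
        CJ=CJ, CS=CS, RJ_e=RJ_e, RS_e=RS_e, RJ_m=RJ_m, RS_m=RS_m,
    )


def ensemble_mca(
    cm: CompiledModel,
    particles: Sequence[KineticParticle],
    skip_singular: bool = True,
) -> list[ControlMatrices]:
    """Control matrices at the anchor state for every posterior particle.

    Structurally unstable particles (singular Jacobian) are skipped and
    counted via the returned list length.
    """
    if not particles:
        raise MCAError("empty particle collection")
    out = []
    for p in particles:
        try:
            out.append(control_coefficients(cm, p))
        except MCAError:
            if not skip_singular:
                raise
    if not out:
        raise MCAError("all particles were structurally unstable")
    return out


def mean_response_to_enzymes(mats: Sequence[ControlMatrices], flux_id: str) -> dict[str, float]:
    """Posterior-mean flux response of one flux to each enzyme."""
    ridx = mats[0].reaction_ids.index(flux_id)
    acc = np.mean([m.RJ_e[ridx] for m in mats], axis=0)
    return dict(zip(mats[0].enzyme_ids, acc))


@dataclass
class BootstrapSummary:
    mean: float
    quantiles: dict[float, float]
    p_raw: float
    p_adjusted: float
    n_resamples: int


def bootstrap_significance(
    samples: np.ndarray,
    n_resamples: int = 1_000_000,
    alpha: float = 0.05,
    n_tests: int = 1,
    seed=0,
    chunk: int = 100_000,
) -> BootstrapSummary:
    """Percentile-method significance of a coefficient mean.

    Resamples the mean of ``samples`` with replacement; the two-sided p-value
    is twice the smaller tail probability of the bootstrap mean around zero,
    Bonferroni-adjusted by ``n_tests``.  A p of 0.0 means "below 1/B".
    """
    x = np.asarray(samples, float)
    if len(x) < 2:
        raise MCAError("need at least two coefficient samples to bootstrap")
    if n_resamples < 1000:
        warnings.warn("fewer than 1000 bootstrap resamples; p-values are coarse")
    rng = np.random.default_rng(seed)
    n = len(x)
    le = ge = 0
    qs_parts = []
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        means = x[rng.integers(0, n, size=(b, n))].mean(axis=1)
        le += int((means <= 0).sum())
        ge += int((means >= 0).sum())
        qs_parts.append(means)
        done += b
    means_all = np.concatenate(qs_parts)
    p_raw = 2.0 * min(le / n_resamples, ge / n_resamples)
    p_raw = min(p_raw, 1.0)
    quantiles = {q: float(np.quantile(means_all, q))
                 for q in (alpha / 2, 0.25, 0.5, 0.75, 1 - alpha / 2)}
    return BootstrapSummary(
        mean=float(x.mean()),
        quantiles=quantiles,
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_tests),
        n_resamples=int(n_resamples),
    )
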