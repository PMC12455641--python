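import numpy as np
import pytest


from carokin.kinetics import (StructureLevel, _occupancies, anchoring_residuals,
                              build_pattern, compile_model, haldane_residuals,
                              network_rates, particle_from_jsonable,
                              pattern_rate, rates_and_conc_jacobian,
                              sample_particle)
from carokin.thermo import dg_at


class TestPatternConstruction:
    def test_uni_uni_smallest_template(self, model):
        pat = build_pattern([model.reaction("IDI1")], StructureLevel.simple)
        assert len(pat.states) == 3
        assert len(pat.steps) == 3
        kinds = [s.kind for s in pat.steps]
        assert kinds == ["binding", "catalytic", "release"]

    def test_regulated_erg13_has_two_dead_end_complexes(self, model):
        pat = build_pattern([model.reaction("ERG13")], StructureLevel.regulated,
                            model.regulation_for("ERG13"))
        dead = [pat.steps[i] for i in pat.dead_end_steps]
        assert len(dead) == 2
        assert {s.met_fwd for s in dead} == {"aacoa", "coa"}
        assert all(s.from_state == 0 for s in dead)  # they block the free enzyme

    def test_detailed_crtyb_shares_free_enzyme(self, model):
        rxns = [model.reaction("CrtYBa"), model.reaction("CrtYBb")]
        pat = build_pattern(rxns, StructureLevel.detailed)
        assert pat.reaction_ids == ("CrtYBa", "CrtYBb")
        assert len(pat.cycles) == 2
        for cyc in pat.cycles:
            assert pat.steps[cyc.step_indices[0]].from_state == 0
            assert pat.steps[cyc.step_indices[-1]].to_state == 0

    def test_simple_level_has_one_pattern_per_enzymatic_reaction(self, compiled_levels):
        assert len(compiled_levels["simple"].patterns) == 20
        assert len(compiled_levels["detailed"].patterns) == 19  # CrtYB merged


@pytest.mark.parametrize("level", ["simple", "regulated", "detailed"])
def test_anchoring_and_haldane_by_construction(level, particle_factory):
    for seed in range(3):
        cm, p = particle_factory(level, seed=seed)
        assert anchoring_residuals(cm, p).max() < 1e-9
        assert max(haldane_residuals(cm, p).values()) < 1e-9


def test_particle_determinism(particle_factory):
    _, p1 = particle_factory("regulated", seed=5)
    _, p2 = particle_factory("regulated", seed=5)
    for a, b in zip(p1.params, p2.params):
        assert np.array_equal(a.kf, b.kf) and np.array_equal(a.kr, b.kr)


def test_uni_uni_rate_law_matches_reversible_michaelis_menten(particle_factory, model):
    """King-Altman occupancy solve vs the closed-form reversible MM rate law."""
    cm, p = particle_factory("simple", seed=1)
    ip = next(i for i, cp in enumerate(cm.patterns)
              if cp.pattern.reaction_ids == ("IDI1",))
    cp = cm.patterns[ip]
    pp = p.params[ip]
    k1, k2, k3 = pp.kf
    km1, km2, km3 = pp.kr
    # coefficient form of the 3-state King-Altman solution
    c0 = k2 * k3 + km1 * k3 + km1 * km2
    cA = k1 * (k2 + km2 + k3)
    cP = km3 * (km1 + km2 + k2)
    Vf, Vr = k1 * k2 * k3 / cA, km1 * km2 * km3 / cP
    KA, KP = c0 / cA, c0 / cP
    i_a, i_p = model.met_index["ipp"], model.met_index["dmapp"]
    conc = p.refstate.ref_conc.copy()
    worst = 0.0
    for fa in np.geomspace(0.05, 20, 6):
        for fp in np.geomspace(0.05, 20, 6):
            conc[i_a] = p.refstate.ref_conc[i_a] * fa
            conc[i_p] = p.refstate.ref_conc[i_p] * fp
            a, q = conc[i_a], conc[i_p]
            mm = (Vf * a / KA - Vr * q / KP) / (1 + a / KA + q / KP)
            got = pattern_rate(cm, p, ip, conc, 1.0)[0]
            worst = max(worst, abs(got - mm) / max(abs(mm), 1e-300))
    assert worst < 1e-9


@pytest.mark.parametrize("rxn_ids", [("ERG13",), ("MVD1",), ("CrtYBa", "CrtYBb")])
def test_occupancies_match_ode_relaxation(rxn_ids, particle_factory, model):
    """The linear-solve occupancies equal the long-time limit of the
    elementary master-equation ODE, propagated independently by repeated
    squaring of the matrix exponential over a short time step."""
    from scipy.linalg import expm

    level = "detailed" if len(rxn_ids) == 2 else "regulated"
    cm, p = particle_factory(level, seed=2)
    ip = next(i for i, cp in enumerate(cm.patterns)
              if cp.pattern.reaction_ids == rxn_ids)
    cp = cm.patterns[ip]
    pp = p.params[ip]
    rng = np.random.default_rng(0)
    conc = p.refstate.ref_conc * np.exp(rng.uniform(-1, 1, len(p.refstate.ref_conc)))

    # assemble the generator step by step (independent of the packed solver)
    n = cp.n_states
    M = np.zeros((n, n))
    for si, step in enumerate(cp.pattern.steps):
        f = pp.kf[si] * (conc[cp.mf[si]] if cp.mf[si] >= 0 else 1.0)
        r = pp.kr[si] * (conc[cp.mr[si]] if cp.mr[si] >= 0 else 1.0)
        M[step.to_state, step.from_state] += f
        M[step.from_state, step.from_state] -= f
        M[step.from_state, step.to_state] += r
        M[step.to_state, step.to_state] -= r
    P = expm(M / np.abs(M).max())
    for _ in range(80):  # propagate to t = 2^80 / max-rate
        P = P @ P
        P = P / P.sum(axis=0, keepdims=True)
    u0 = np.zeros(n)
    u0[0] = 1.0
    u_ode = P @ u0
    u_lin, *_ = _occupancies(cp, pp, conc)
    flux_lin = pattern_rate(cm, p, ip, conc, 1.0)
    for (rxn_idx, d), f_lin in zip(cp.cycles, flux_lin):
        f_ode = pp.kf[d] * u_ode[cp.sf[d]] - pp.kr[d] * u_ode[cp.st[d]]
        assert abs(f_ode - f_lin) / max(abs(f_lin), 1e-300) < 1e-6
    assert np.max(np.abs(u_ode - u_lin)) < 1e-8


def test_flux_vanishes_at_equilibrium(particle_factory, model, thermo):
    cm, p = particle_factory("simple", seed=3)
    conc = p.refstate.ref_conc.copy()
    i_a, i_p = model.met_index["ipp"], model.met_index["dmapp"]
    # move dmapp to the equilibrium point of the isomerase
    rt = thermo.RT
    conc[i_p] = conc[i_a] * np.exp(-thermo.dg0["IDI1"] / rt)
    assert abs(dg_at(model, thermo, "IDI1", conc)) < 1e-9
    ip = next(i for i, cp in enumerate(cm.patterns)
              if cp.pattern.reaction_ids == ("IDI1",))
    v = pattern_rate(cm, p, ip, conc, 1.0)[0]
    assert abs(v) < 1e-10 * p.v_ref["IDI1"]


def test_cut_set_consistency(particle_factory):
    """The net rate through every elementary step of a cycle is identical
    at the occupancy solution."""
    cm, p = particle_factory("detailed", seed=4)
    rng = np.random.default_rng(1)
    conc = p.refstate.ref_conc * np.exp(rng.uniform(-0.7, 0.7, len(p.refstate.ref_conc)))
    for cp, pp in zip(cm.patterns, p.params):
        u, *_ = _occupancies(cp, pp, conc)
        for cyc in cp.pattern.cycles:
            nets = []
            for si in cyc.step_indices:
                f = pp.kf[si] * (conc[cp.mf[si]] if cp.mf[si] >= 0 else 1.0) * u[cp.sf[si]]
                r = pp.kr[si] * (conc[cp.mr[si]] if cp.mr[si] >= 0 else 1.0) * u[cp.st[si]]
                nets.append(f - r)
            nets = np.array(nets)
            assert np.max(np.abs(nets - nets[0])) < 1e-10 * max(abs(nets[0]), 1e-300)


def test_flux_sign_opposes_gibbs_energy(particle_factory, model, thermo):
    cm, p = particle_factory("regulated", seed=6)
    rng = np.random.default_rng(2)
    vmax = np.abs(p.v_ref.values).max()
    for _ in range(100):
        cr = np.exp(rng.uniform(np.log(0.1), np.log(10), 29))
        er = np.exp(rng.uniform(-0.7, 0.7, 14))
        v = network_rates(cm, p, cr, er)
        conc = cr * p.refstate.ref_conc
        for rxn in model.enzymatic_reactions:
            vi = v[model.rxn_index[rxn.id]]
            if abs(vi) > 1e-12 * vmax:
                assert vi * dg_at(model, thermo, rxn.id, conc) < 0


def test_flux_linear_in_enzyme_level(particle_factory):
    cm, p = particle_factory("detailed", seed=7)
    rng = np.random.default_rng(3)
    cr = np.exp(rng.uniform(-1, 1, 29))
    v1 = network_rates(cm, p, cr, np.ones(14))
    v2 = network_rates(cm, p, cr, np.full(14, 2.5))
    enzymatic = [i for i, r in enumerate(cm.model.reactions) if not r.is_sink]
    assert np.allclose(v2[enzymatic], 2.5 * v1[enzymatic], rtol=1e-12)


def test_erg13_inhibitors_sequester_free_enzyme(particle_factory, model):
    cm, p = particle_factory("regulated", seed=8)
    ip = next(i for i, cp in enumerate(cm.patterns)
              if cp.pattern.reaction_ids == ("ERG13",))
    cp = cm.patterns[ip]
    i_inh = model.met_index["aacoa"]
    conc = p.refstate.ref_conc.copy()
    shares = []
    for f in (1.0, 2.0, 5.0, 20.0):
        conc[i_inh] = p.refstate.ref_conc[i_inh] * f
        u, *_ = _occupancies(cp, p.params[ip], conc)
        shares.append(u[0])
    assert all(a > b for a, b in zip(shares, shares[1:]))


def test_detailed_crtyb_enzyme_conservation(particle_factory):
    cm, p = particle_factory("detailed", seed=9)
    ip = next(i for i, cp in enumerate(cm.patterns) if len(cp.cycles) == 2)
    cp = cm.patterns[ip]
    rng = np.random.default_rng(4)
    conc = p.refstate.ref_conc * np.exp(rng.uniform(-1, 1, 29))
    u, *_ = _occupancies(cp, p.params[ip], conc)
    assert u.sum() == pytest.approx(1.0, abs=1e-12)
    assert (u > -1e-14).all()


def test_analytic_jacobian_matches_finite_differences(particle_factory):
    cm, p = particle_factory("detailed", seed=10)
    cr = np.full(29, 1.3)
    er = np.full(14, 0.8)
    v0, J = rates_and_conc_jacobian(cm, p, cr, er)
    assert np.allclose(v0, network_rates(cm, p, cr, er))
    h = 1e-6
    for mi in range(0, 29, 5):
        up, dn = cr.copy(), cr.copy()
        up[mi] *= np.exp(h)
        dn[mi] *= np.exp(-h)
        fd = (network_rates(cm, p, up, er) - network_rates(cm, p, dn, er)) / (2 * h)
        assert np.max(np.abs(fd - J[:, mi])) < 1e-4 * max(np.abs(J).max(), 1.0)


def test_particle_json_round_trip(particle_factory):
    cm, p = particle_factory("regulated", seed=11)
    q = particle_from_jsonable(cm, p.to_jsonable())
    rng = np.random.default_rng(5)
    cr = np.exp(rng.uniform(-0.5, 0.5, 29))
    er = np.exp(rng.uniform(-0.5, 0.5, 14))
    assert np.allclose(network_rates(cm, p, cr, er),
                       network_rates(cm, q, cr, er), rtol=1e-12)
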