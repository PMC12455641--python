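import numpy as np
import pytest

from carokin.mca import (MCAError, bootstrap_significance, control_coefficients,
                         control_coefficients_from_elasticities, elasticities,
                         ensemble_mca, mean_response_to_enzymes)
from carokin.network import stoichiometric_matrix


@pytest.fixture(scope="module")
def detailed_particle(particle_factory):
    return particle_factory("detailed", seed=30)


class TestElasticities:
    def test_own_enzyme_elasticity_is_one(self, detailed_particle):
        cm, p = detailed_particle
        eps = elasticities(cm, p)
        for rxn in cm.model.enzymatic_reactions:
            i = cm.model.rxn_index[rxn.id]
            j = cm.model.enzymes.index(rxn.enzyme_id)
            assert eps.enzyme[i, j] == 1.0
            assert eps.enzyme[i].sum() == 1.0

    def test_sink_elasticity_to_substrate_is_one(self, detailed_particle):
        cm, p = detailed_particle
        eps = elasticities(cm, p)
        i = cm.model.rxn_index["SK_lyc"]
        assert eps.conc[i, cm.model.met_index["lyco"]] == pytest.approx(1.0)
        assert np.count_nonzero(eps.conc[i]) == 1

    def test_analytic_matches_finite_differences(self, detailed_particle):
        cm, p = detailed_particle
        ea = elasticities(cm, p, method="analytic")
        ef = elasticities(cm, p, method="fd")
        assert np.max(np.abs(ea.conc - ef.conc)) < 1e-4

    def test_uni_uni_elasticities_match_mm_closed_form(self, particle_factory):
        # reversible MM: eps_A = (a/KA... derived from the coefficient form
        cm, p = particle_factory("simple", seed=31)
        model = cm.model
        ip = next(i for i, cp in enumerate(cm.patterns)
                  if cp.pattern.reaction_ids == ("IDI1",))
        pp = p.params[ip]
        k1, k2, k3 = pp.kf
        km1, km2, km3 = pp.kr
        c0 = k2 * k3 + km1 * k3 + km1 * km2
        cA = k1 * (k2 + km2 + k3)
        cP = km3 * (km1 + km2 + k2)
        i_a, i_p = model.met_index["ipp"], model.met_index["dmapp"]
        a, q = p.refstate.ref_conc[i_a], p.refstate.ref_conc[i_p]
        num = k1 * k2 * k3 * a - km1 * km2 * km3 * q
        den = c0 + cA * a + cP * q
        eps_a = k1 * k2 * k3 * a / num - cA * a / den
        eps_p = -km1 * km2 * km3 * q / num - cP * q / den
        eps = elasticities(cm, p)
        i = model.rxn_index["IDI1"]
        assert eps.conc[i, i_a] == pytest.approx(eps_a, rel=1e-9)
        assert eps.conc[i, i_p] == pytest.approx(eps_p, rel=1e-9)

    def test_non_steady_state_rejected_when_checked(self, detailed_particle):
        cm, p = detailed_particle
        cr = np.ones(len(cm.model.metabolites))
        cr[cm.model.met_index["lyco"]] = 5.0
        with pytest.raises(MCAError, match="steady state"):
            elasticities(cm, p, conc_rel=cr, steady_tol=1e-6)


class TestControlCoefficients:
    def test_summation_theorems(self, particle_factory):
        for level in ("simple", "regulated", "detailed"):
            for seed in (40, 41):
                cm, p = particle_factory(level, seed=seed)
                mats = control_coefficients(cm, p)
                assert np.abs(mats.CJ.sum(axis=1) - 1).max() < 1e-6
                assert np.abs(mats.CS.sum(axis=1)).max() < 1e-6

    def test_two_step_chain_closed_form(self):
        e1, e2 = 0.8, -0.5
        CJ, CS = control_coefficients_from_elasticities(
            np.array([[e1], [e2]]), np.array([[1.0, -1.0]]), np.ones(2))
        assert CJ[0] == pytest.approx([e2 / (e2 - e1), -e1 / (e2 - e1)])
        assert CJ[1] == pytest.approx(CJ[0])  # single flux through the chain
        assert CS[0, 0] == pytest.approx(1.0 / (e2 - e1))

    def test_connectivity_theorems(self, detailed_particle):
        cm, p = detailed_particle
        eps = elasticities(cm, p)
        mats = control_coefficients(cm, p, eps)
        bal = [cm.model.met_index[m] for m in cm.model.balanced_ids]
        assert np.abs(mats.CJ @ eps.conc[:, bal]).max() < 1e-8
        assert np.abs(mats.CS @ eps.conc[:, bal] + np.eye(len(bal))).max() < 1e-8

    def test_promiscuous_enzyme_response_sums_its_reactions(self, detailed_particle):
        cm, p = detailed_particle
        mats = control_coefficients(cm, p)
        j = mats.enzyme_ids.index("CrtYB")
        ca = mats.reaction_ids.index("CrtYBa")
        cb = mats.reaction_ids.index("CrtYBb")
        np.testing.assert_allclose(mats.RJ_e[:, j], mats.CJ[:, ca] + mats.CJ[:, cb],
                                   atol=1e-12)

    def test_scaled_coefficients_invariant_under_activity_scaling(self, detailed_particle):
        # homogeneity: scaling every reaction's activity (enzymes and sink
        # constants alike) scales all fluxes uniformly and leaves every
        # scaled coefficient unchanged
        cm, p = detailed_particle
        eps = elasticities(cm, p)
        N_bal = stoichiometric_matrix(cm.model, balanced_only=True)
        bal = [cm.model.met_index[m] for m in cm.model.balanced_ids]
        CJ1, CS1 = control_coefficients_from_elasticities(
            eps.conc[:, bal], N_bal, eps.flux)
        CJ2, CS2 = control_coefficients_from_elasticities(
            eps.conc[:, bal], N_bal, 2.0 * eps.flux)
        np.testing.assert_allclose(CJ2, CJ1, atol=1e-9)
        np.testing.assert_allclose(CS2, CS1, atol=1e-9)


class TestEnsembleMCA:
    def test_single_particle_mean_is_itself(self, detailed_particle):
        cm, p = detailed_particle
        mats = ensemble_mca(cm, [p])
        resp = mean_response_to_enzymes(mats, "SK_b_car")
        solo = control_coefficients(cm, p)
        i = solo.reaction_ids.index("SK_b_car")
        for j, e in enumerate(solo.enzyme_ids):
            assert resp[e] == pytest.approx(solo.RJ_e[i, j])

    def test_crtyb_limited_truth_ranks_crtyb_top_two(self, model):
        from carokin.synthdata import generate_truth
        for seed in (0, 5):
            cm, truth = generate_truth(model, "detailed", seed, "crtyb_limited")
            resp = mean_response_to_enzymes(ensemble_mca(cm, [truth]), "SK_b_car")
            ranked = sorted(resp, key=lambda e: -abs(resp[e]))
            assert "CrtYB" in ranked[:2]
            assert resp["CrtYB"] > 0

    def test_empty_collection_errors(self, detailed_particle):
        cm, _ = detailed_particle
        with pytest.raises(MCAError):
            ensemble_mca(cm, [])


class TestBootstrap:
    def test_constant_positive_sample_gives_zero_p(self):
        b = bootstrap_significance(np.full(50, 0.5), n_resamples=2000, seed=0)
        assert b.p_raw == 0.0
        assert b.mean == pytest.approx(0.5)

    def test_symmetric_sample_is_insignificant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 200)
        x = x - x.mean()  # exactly centred
        b = bootstrap_significance(x, n_resamples=20_000, seed=1, n_tests=5)
        assert b.p_adjusted > 0.5

    def test_power_matches_t_test(self):
        # n=100 draws from Normal(0.3, 1): rejection rate at alpha=0.05
        # should match the one-sample t-test power (~0.85) within MC error
        from scipy import stats
        rng = np.random.default_rng(4)
        n_sim, hits = 60, 0
        for i in range(n_sim):
            x = rng.normal(0.3, 1.0, 100)
            b = bootstrap_significance(x, n_resamples=2000, seed=i)
            hits += b.p_raw < 0.05
        power = stats.norm.cdf(0.3 / (1 / np.sqrt(100)) - 1.96)  # ~0.85
        assert abs(hits / n_sim - power) < 0.15

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.2, 1.0, 80)
        b1 = bootstrap_significance(x, n_resamples=5000, seed=9)
        b2 = bootstrap_significance(x[::-1].copy(), n_resamples=5000, seed=9)
        # resampling indices are positional, so permuting the sample must not
        # change the distributional summary beyond tiny reordering effects
        assert b1.mean == pytest.approx(b2.mean)
        assert abs(b1.p_raw - b2.p_raw) < 0.05

    def test_low_resample_count_warns(self):
        with pytest.warns(UserWarning, match="1000"):
            bootstrap_significance(np.array([0.1, 0.2, 0.3]), n_resamples=10, seed=0)
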