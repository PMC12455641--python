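import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carokin.dataprep import ConditionData
from carokin.ensemble import (EnsembleError, EnsembleResult, compare_prior_posterior,
                              condition_sq_error, cross_validate, discrepancy,
                              reject, run_prior, simulate_condition)
from carokin.synthdata import make_study, solve_strain_state


def _cond(strain="c1", fluxes=None, sigma=0.1, enzymes=None):
    fluxes = fluxes or {"SK_lyc": 1.0, "SK_b_car": 1.0, "ERG9b": 1.0}
    z = 1.959963984540054
    ff = {k: (v, v - z * sigma, v + z * sigma) for k, v in fluxes.items()}
    return ConditionData(strain=strain, growth_rate=0.1, free_fluxes=ff,
                         rel_enzyme=enzymes or {})


class TestDiscrepancy:
    def test_perfect_match_scores_zero(self):
        cond = _cond()
        assert condition_sq_error({"SK_lyc": 1.0, "SK_b_car": 1.0, "ERG9b": 1.0}, cond) == 0.0

    def test_one_sigma_deviation_scores_one(self):
        cond = _cond(sigma=0.25)
        sq = condition_sq_error({"SK_lyc": 1.25, "SK_b_car": 1.0, "ERG9b": 1.0}, cond)
        assert np.sqrt(sq) == pytest.approx(1.0, rel=1e-9)

    def test_two_conditions_give_sqrt_two(self):
        conds = {"a": _cond("a", sigma=0.2), "b": _cond("b", sigma=0.2)}
        sims = {"a": {"SK_lyc": 1.2, "SK_b_car": 1.0, "ERG9b": 1.0},
                "b": {"SK_lyc": 1.0, "SK_b_car": 1.2, "ERG9b": 1.0}}
        assert discrepancy(sims, conds) == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_zero_sigma_errors(self):
        cond = _cond(sigma=0.0)
        with pytest.raises(EnsembleError, match="zero-width"):
            condition_sq_error({"SK_lyc": 1.0, "SK_b_car": 1.0, "ERG9b": 1.0}, cond)

    @given(perm=st.permutations(["a", "b", "c"]))
    @settings(max_examples=10, deadline=None)
    def test_invariant_under_condition_reordering(self, perm):
        conds = {k: _cond(k, {"SK_lyc": 1 + i, "SK_b_car": 1.0, "ERG9b": 1.0})
                 for i, k in enumerate(["a", "b", "c"])}
        sims = {k: {"SK_lyc": 1.1 + i, "SK_b_car": 0.9, "ERG9b": 1.2}
                for i, k in enumerate(["a", "b", "c"])}
        base = discrepancy(sims, conds)
        reordered = discrepancy({k: sims[k] for k in perm}, {k: conds[k] for k in perm})
        assert reordered == pytest.approx(base, rel=1e-12)


def _fake_ensemble(scores, n_conditions=1):
    n = len(scores)
    sq = np.asarray(scores, float)[:, None] ** 2 / n_conditions
    sq = np.repeat(sq, n_conditions, axis=1)
    feasible = ~np.isnan(sq)
    return EnsembleResult(level="simple", condition_ids=[f"c{i}" for i in range(n_conditions)],
                          particles=[None] * n, sq_errors=sq, feasible=feasible)


class TestReject:
    def test_ten_thousand_at_one_percent_keeps_one_hundred(self):
        rng = np.random.default_rng(0)
        ens = _fake_ensemble(rng.exponential(1.0, 10_000))
        reject(ens, 0.01)
        assert int(ens.posterior.sum()) == 100
        scores = ens.scores()
        assert scores[ens.posterior].max() <= np.quantile(scores, 0.01)

    def test_ties_break_by_particle_index(self):
        ens = _fake_ensemble(np.ones(200))
        reject(ens, 0.01)
        assert np.flatnonzero(ens.posterior).tolist() == [0, 1]

    def test_cutoff_one_keeps_all_feasible(self):
        ens = _fake_ensemble(np.arange(1.0, 11.0))
        reject(ens, 1.0)
        assert int(ens.posterior.sum()) == 10

    def test_too_few_feasible_errors_with_counts(self):
        scores = np.full(100, np.nan)
        scores[0] = 1.0
        ens = _fake_ensemble(scores)
        with pytest.raises(EnsembleError, match="1 feasible"):
            reject(ens, 0.05)

    def test_invalid_cutoff(self):
        ens = _fake_ensemble(np.arange(1.0, 11.0))
        with pytest.raises(EnsembleError):
            reject(ens, 0.0)


class TestComparePriorPosterior:
    def test_lowest_subset_is_significant(self):
        rng = np.random.default_rng(1)
        ens = _fake_ensemble(rng.exponential(1.0, 2000))
        reject(ens, 0.01)
        _, p = compare_prior_posterior(ens)
        assert p < 0.01

    def test_null_p_values_are_roughly_uniform(self):
        # posterior chosen at random from the prior: p should not concentrate
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(40):
            ens = _fake_ensemble(rng.exponential(1.0, 300))
            flags = np.zeros(300, dtype=bool)
            flags[rng.choice(300, 15, replace=False)] = True
            ens.posterior = flags
            _, p = compare_prior_posterior(ens)
            ps.append(p)
        ps = np.array(ps)
        assert 0.15 <= np.mean(ps < 0.5) <= 0.85
        assert (ps < 0.001).mean() < 0.2

    def test_degenerate_distributions_warn_and_return_one(self):
        ens = _fake_ensemble(np.ones(50))
        reject(ens, 0.1)
        with pytest.warns(UserWarning):
            _, p = compare_prior_posterior(ens)
        assert p == 1.0


@pytest.fixture(scope="module")
def small_run(model, sampler):
    study = make_study(model, "simple", "neutral", seed=21)
    ens = run_prior(study.cm, sampler, study.v_ref, study.conditions, 40, seed=22)
    return study, ens


class TestRunPrior:
    def test_particle_count_and_determinism(self, model, sampler, small_run):
        study, ens = small_run
        assert ens.n == 40
        again = run_prior(study.cm, sampler, study.v_ref, study.conditions, 8, seed=22)
        np.testing.assert_array_equal(ens.sq_errors[:8], again.sq_errors)

    def test_most_particles_reach_steady_state(self, small_run):
        _, ens = small_run
        assert (~np.isnan(ens.scores())).sum() >= 0.6 * ens.n

    def test_truth_particle_scores_near_zero_on_noise_free_data(self, model, sampler):
        from carokin.synthdata import NoiseModel
        study = make_study(model, "simple", "neutral", seed=33,
                           noise=NoiseModel(flux_sd=0.0, enzyme_sd=0.0))
        ens = run_prior(study.cm, sampler, study.v_ref, study.conditions, 10,
                        seed=34, particles=[study.truth])
        reject(ens, 0.1)
        scores = ens.scores()
        assert ens.posterior[0]            # the truth is always selected
        assert scores[0] == np.nanmin(scores)
        assert scores[0] < 0.05            # ~0 vs the floor CI width

    def test_reference_condition_is_reproduced_exactly(self, model, sampler, small_run):
        study, _ = small_run
        ref_cond = ConditionData(
            strain="ref", growth_rate=0.101,
            free_fluxes={k: (v, 0.9 * v, 1.1 * v) for k, v in
                         {"SK_lyc": study.v_ref["SK_lyc"],
                          "SK_b_car": study.v_ref["SK_b_car"],
                          "ERG9b": study.v_ref["ERG9b"]}.items()},
            rel_enzyme={e: (1.0, 1.0, 1.0) for e in model.enzymes},
        )
        sim = simulate_condition(study.cm, study.truth, ref_cond)
        assert sim.feasible
        np.testing.assert_allclose(sim.flux, study.v_ref.values, rtol=1e-6)


class TestSimulateCondition:
    def test_self_consistency_recovers_generating_fluxes(self, model, sampler):
        study = make_study(model, "simple", "neutral", seed=55)
        mult = {"CrtE": 0.7, "CrtYB": 0.8}
        _, v_true = solve_strain_state(study.cm, study.truth, mult)
        cond = ConditionData(
            strain="self", growth_rate=0.101,
            free_fluxes={k: (v_true[model.rxn_index[k]],
                             0.9 * v_true[model.rxn_index[k]],
                             1.1 * v_true[model.rxn_index[k]])
                         for k in ("SK_lyc", "SK_b_car", "ERG9b")},
            rel_enzyme={e: (mult.get(e, 1.0),) * 3 for e in model.enzymes},
        )
        sim = simulate_condition(study.cm, study.truth, cond)
        assert sim.feasible
        for k in ("SK_lyc", "SK_b_car", "ERG9b"):
            i = model.rxn_index[k]
            assert sim.flux[i] == pytest.approx(v_true[i], rel=1e-4)

    def test_impossible_enzyme_box_is_infeasible_not_fatal(self, model, sampler, small_run):
        study, _ = small_run
        # CrtYB crushed to 1e-3 while demanding order-one sink fluxes:
        # the cyclase cannot carry the reference flux within the bounds
        cond = ConditionData(
            strain="broken", growth_rate=0.101,
            free_fluxes={k: (1.0, 0.9, 1.1) for k in ("SK_lyc", "SK_b_car", "ERG9b")},
            rel_enzyme={e: ((1e-3,) * 3 if e == "CrtYB" else (1.0, 1.0, 1.0))
                        for e in model.enzymes},
        )
        sim = simulate_condition(study.cm, study.truth, cond)
        assert not sim.feasible


class TestCrossValidate:
    def test_both_directions_and_median_improvement(self, small_run):
        study, ens = small_run
        folds = cross_validate(ens, ens.condition_ids[:1], ens.condition_ids[1:], 0.1)
        assert len(folds) == 2
        assert {tuple(f.train_ids) for f in folds} == {("synth3",), ("synth2",)}

    def test_degenerate_split_warns(self, small_run):
        _, ens = small_run
        with pytest.warns(UserWarning, match="identical"):
            folds = cross_validate(ens, ens.condition_ids, ens.condition_ids, 0.1)
        assert folds[0].posterior_test_median <= folds[0].prior_test_median

    def test_empty_test_set_errors(self, small_run):
        _, ens = small_run
        with pytest.raises(EnsembleError, match="empty test"):
            cross_validate(ens, ens.condition_ids, [], 0.1)
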