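"""Correlation screening, forward/backward steps and the full stepwise search."""

import numpy as np
import pytest

from vancopk import cohort, pk
from vancopk.cohort import CohortDesign, sample_covariates
from vancopk.covariates import (
    backward_step,
    candidate_terms,
    clinical_relevance,
    correlation_screen,
    forward_step,
    stepwise,
)
from vancopk.data import SubjectRecord
from vancopk.fit import CovariateTerm, FitResult, ModelSpec, base_model_spec, fit


def _fake_fit(spec, estimates):
    return FitResult(
        estimates=estimates, se={}, rse_percent={}, ci95={}, ofv=0.0, ebes={},
        converged=True, spec=spec, n_obs=0, n_subjects=0,
    )


class TestCorrelationScreen:
    def test_growth_covariates_grouped_with_weight_representative(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=300))
        groups = correlation_screen(subs, ["weight", "age", "height", "scr"])
        by_rep = {g.representative: set(g.members) for g in groups}
        assert {"weight", "age", "height"} <= by_rep["weight"]
        assert by_rep["scr"] == {"scr"}

    def test_independent_covariates_stay_separate(self):
        rng = np.random.default_rng(0)
        subs = [
            SubjectRecord(subject_id=str(i), weight=float(rng.uniform(2, 10)),
                          scr=float(rng.uniform(6, 45)))
            for i in range(500)
        ]
        groups = correlation_screen(subs, ["weight", "scr"])
        assert sorted(g.members for g in groups) == [("scr",), ("weight",)]

    def test_single_candidate_is_its_own_group(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=20))
        (g,) = correlation_screen(subs, ["weight"])
        assert g.members == ("weight",) and g.representative == "weight"

    def test_constant_covariate_excluded(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=30))
        for s in subs:
            s.bun = 3.0
        groups = correlation_screen(subs, ["weight", "bun"])
        assert all("bun" not in g.members for g in groups)


class TestSteps:
    def test_forward_adds_weight_on_weight_driven_data(self, final_params):
        ds = cohort.make_cohort(CohortDesign(seed=21, n_subjects=60), final_params)
        cands = candidate_terms(list(ds.subjects.values()), ["weight", "sex"])
        result, steps = forward_step(ds, base_model_spec(), cands)
        assert result is not None
        spec, _ = result
        added = [s for s in steps if s.accepted]
        assert len(added) == 1 and added[0].covariate == "weight"
        assert added[0].delta_ofv < -3.84

    def test_forward_with_no_candidates(self, final_params, small_cohort):
        result, steps = forward_step(ds=small_cohort, spec=base_model_spec(), candidates=[])
        assert result is None and steps == []

    def test_backward_removes_spurious_term(self, final_params):
        pop = final_params.replace(beta_scr_cl=0.0)  # SCR truly inert
        ds = cohort.make_cohort(CohortDesign(seed=22, n_subjects=60), pop)
        spec = base_model_spec().with_term(
            CovariateTerm("cl", "weight", "power", reference=70.0)
        ).with_term(CovariateTerm("cl", "scr", "power", reference=20.0))
        result, steps = backward_step(ds, spec)
        assert result is not None
        new_spec, _ = result
        kept = {(t.parameter, t.covariate) for t in new_spec.covariate_terms}
        assert ("cl", "weight") in kept and ("cl", "scr") not in kept
        removed = [s for s in steps if s.accepted]
        assert removed and removed[0].covariate == "scr"

    def test_backward_with_no_removable_terms(self, final_params, small_cohort):
        result, steps = backward_step(small_cohort, base_model_spec())
        assert result is None and steps == []


class TestClinicalRelevance:
    def test_ceftriaxone_factor_is_relevant(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=50))
        term = CovariateTerm("cl", "ceftriaxone", "factor")
        with_spec = base_model_spec().with_term(term)
        fw = _fake_fit(with_spec, {"theta_cl_ceftriaxone": 1.46})
        fo = _fake_fit(base_model_spec(), {})
        assert clinical_relevance(fw, fo, "cl", subs) is True

    def test_small_factor_fails(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=50))
        term = CovariateTerm("cl", "meropenem", "factor")
        fw = _fake_fit(base_model_spec().with_term(term), {"theta_cl_meropenem": 1.05})
        fo = _fake_fit(base_model_spec(), {})
        assert clinical_relevance(fw, fo, "cl", subs) is False

    def test_zero_power_fails(self):
        subs = sample_covariates(CohortDesign(seed=1, n_subjects=50))
        term = CovariateTerm("cl", "scr", "power", reference=20.0)
        fw = _fake_fit(base_model_spec().with_term(term), {"beta_cl_scr": 0.0})
        fo = _fake_fit(base_model_spec(), {})
        assert clinical_relevance(fw, fo, "cl", subs) is False


class TestStepwise:
    def test_pure_noise_candidates_return_base_model(self, final_params):
        pop = pk.PopulationParams(
            theta_cl=0.5, theta_v=2.9, power_wt_v=0.0,
            omega2_cl=0.145**2, sigma2_prop=0.194**2,
        )
        ds = cohort.make_cohort(CohortDesign(seed=30, n_subjects=60), pop)
        cands = candidate_terms(list(ds.subjects.values()), ["albumin", "sex"])
        res = stepwise(ds, base_model_spec(), cands)
        assert res.final_spec.covariate_terms == ()

    def test_trace_replays_to_final_spec_and_is_deterministic(self, final_params):
        ds = cohort.make_cohort(CohortDesign(seed=31, n_subjects=60), final_params)
        subs = list(ds.subjects.values())
        cands = candidate_terms(subs, ["weight", "scr"])
        r1 = stepwise(ds, base_model_spec(), cands)
        r2 = stepwise(ds, base_model_spec(), cands)
        assert r1.trace.to_dict() == r2.trace.to_dict()
        assert r1.trace.replay(base_model_spec()).covariate_terms == r1.final_spec.covariate_terms

    def test_screened_candidates_never_coselect_grouped_covariates(self, final_params):
        ds = cohort.make_cohort(CohortDesign(seed=32, n_subjects=60), final_params)
        subs = list(ds.subjects.values())
        groups = correlation_screen(subs, ["weight", "age", "height", "scr"])
        reps = [g.representative for g in groups]
        cands = candidate_terms(subs, reps)
        res = stepwise(ds, base_model_spec(), cands)
        chosen = {t.covariate for t in res.final_spec.covariate_terms}
        for g in groups:
            assert len(chosen & set(g.members)) <= 1
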