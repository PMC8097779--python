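"""FOCE-I/Laplace estimation: objectives, EB estimates, population fits."""

import math

import numpy as np
import pytest
from scipy import integrate

from vancopk import cohort, pk
from vancopk.cohort import CohortDesign
from vancopk.data import Event, PKDataset, SubjectRecord
from vancopk.fit import (
    CovariateTerm,
    ModelSpec,
    base_model_spec,
    estimate_ebes,
    final_model_spec,
    fit,
    individual_objective,
    ofv,
)

LOG_2PI = math.log(2.0 * math.pi)


def one_subject_dataset(conc=8.0, weight=4.0, scr=18.25, obs_time=2.0, sid="1"):
    s = SubjectRecord(subject_id=sid, weight=weight, scr=scr)
    return PKDataset(
        subjects={sid: s},
        events=[
            Event(sid, 0.0, "dose", amount=40.0, infusion_duration=1.0),
            Event(sid, obs_time, "observation", concentration=conc),
        ],
    )


class TestIndividualObjective:
    def test_matches_hand_computed_density(self, final_params):
        """-2 log joint density spelled out with the closed-form prediction."""
        ds = one_subject_dataset()
        spec = final_model_spec()
        eta = 0.3
        pop = final_params
        ind = pk.individual_params(pk.typical_params(ds.subjects["1"], pop), eta)
        f = pk.concentration(ind, [(0.0, 40.0, 1.0)], 2.0)
        var = pop.sigma2_prop * f * f
        y = 8.0
        expected = (
            math.log(2 * math.pi * var)
            + (y - f) ** 2 / var
            + math.log(2 * math.pi * pop.omega2_cl)
            + eta**2 / pop.omega2_cl
        )
        got = individual_objective(ds, "1", pop, spec, [eta])
        assert got == pytest.approx(expected, rel=1e-10)

    def test_time_translation_invariance(self, final_params):
        spec = final_model_spec()
        ds = one_subject_dataset()
        shifted = PKDataset(
            subjects=dict(ds.subjects),
            events=[
                Event(e.subject_id, e.time + 5.0, e.kind, e.amount,
                      e.infusion_duration, e.concentration)
                for e in ds.events
            ],
        )
        for eta in (-0.5, 0.0, 0.7):
            assert individual_objective(ds, "1", final_params, spec, [eta]) == pytest.approx(
                individual_objective(shifted, "1", final_params, spec, [eta]), rel=1e-12
            )

    def test_smooth_and_convex_near_mode(self, final_params):
        spec = final_model_spec()
        ds = one_subject_dataset()
        etas = np.linspace(-0.4, 0.4, 9)
        vals = [individual_objective(ds, "1", final_params, spec, [e]) for e in etas]
        d2 = np.diff(vals, 2)
        assert np.all(np.isfinite(vals)) and np.all(d2 > 0)


class TestEbes:
    def test_shrink_to_zero_as_bsv_vanishes(self, final_params, small_cohort):
        spec = final_model_spec()
        tight = final_params.replace(omega2_cl=1e-8)
        ebes = estimate_ebes(small_cohort, tight, spec)
        assert max(abs(v[0]) for v in ebes.values()) < 1e-3

    def test_recovers_known_etas_from_clean_data(self, final_params):
        spec = final_model_spec()
        rng = np.random.default_rng(3)
        subjects, events = {}, []
        true_etas = {}
        pop = final_params.replace(sigma2_prop=1e-10)
        for i in range(8):
            sid = str(i + 1)
            s = SubjectRecord(subject_id=sid, weight=3.0 + i, scr=15.0 + i)
            subjects[sid] = s
            eta = float(rng.normal(0.0, 0.12))
            true_etas[sid] = eta
            ind = pk.individual_params(pk.typical_params(s, pop), eta)
            doses = [(0.0, 10.0 * s.weight, 1.0), (6.0, 10.0 * s.weight, 1.0)]
            events.append(Event(sid, 0.0, "dose", amount=doses[0][1], infusion_duration=1.0))
            events.append(Event(sid, 6.0, "dose", amount=doses[1][1], infusion_duration=1.0))
            for t in (2.0, 6.0, 7.5):
                events.append(Event(sid, t, "observation",
                                    concentration=float(pk.concentration(ind, doses, t))))
        ds = PKDataset(subjects=subjects, events=events)
        ebes = estimate_ebes(ds, pop, spec)
        for sid, eta in true_etas.items():
            assert ebes[sid][0] == pytest.approx(eta, abs=1e-4)

    def test_symmetric_subjects_get_symmetric_ebes(self, final_params):
        spec = final_model_spec()
        a = one_subject_dataset(conc=9.0, sid="1")
        b = one_subject_dataset(conc=9.0, sid="2")
        ds = PKDataset(subjects={**a.subjects, **b.subjects}, events=a.events + b.events)
        ebes = estimate_ebes(ds, final_params, spec)
        assert ebes["1"][0] == pytest.approx(ebes["2"][0], abs=1e-10)


class TestOfv:
    def test_matches_numerical_marginal_likelihood(self, final_params):
        """Laplace OFV vs direct quadrature of the marginal density.

        With a small BSV the integrand is near-Gaussian, where the Laplace
        approximation is exact up to higher-order terms.
        """
        pop = final_params.replace(omega2_cl=0.003)
        spec = final_model_spec()
        ds = one_subject_dataset(conc=9.0)
        got = ofv(ds, pop, spec)

        def joint(eta):
            return math.exp(-0.5 * individual_objective(ds, "1", pop, spec, [eta]))

        integral, _ = integrate.quad(joint, -0.5, 0.5, epsabs=1e-14, epsrel=1e-12)
        exact = -2.0 * math.log(integral) - 1 * LOG_2PI  # n_obs = 1
        assert got == pytest.approx(exact, abs=2e-3)

    def test_additive_over_duplicated_subjects(self, final_params, small_cohort):
        spec = final_model_spec()
        base = ofv(small_cohort, final_params, spec)
        doubled = PKDataset(
            subjects={
                **small_cohort.subjects,
                **{
                    "d" + sid: SubjectRecord(**{**s.__dict__, "subject_id": "d" + sid})
                    for sid, s in small_cohort.subjects.items()
                },
            },
            events=small_cohort.events
            + [
                Event("d" + e.subject_id, e.time, e.kind, e.amount,
                      e.infusion_duration, e.concentration, e.observation_label, e.below_loq)
                for e in small_cohort.events
            ],
        )
        assert ofv(doubled, final_params, spec) == pytest.approx(2 * base, rel=1e-9)

    def test_invariant_to_subject_relabelling(self, final_params, small_cohort):
        spec = final_model_spec()
        relabel = {sid: f"z{int(sid):03d}" for sid in small_cohort.subjects}
        shuffled = PKDataset(
            subjects={
                relabel[sid]: SubjectRecord(**{**s.__dict__, "subject_id": relabel[sid]})
                for sid, s in small_cohort.subjects.items()
            },
            events=[
                Event(relabel[e.subject_id], e.time, e.kind, e.amount,
                      e.infusion_duration, e.concentration, e.observation_label, e.below_loq)
                for e in reversed(small_cohort.events)
            ],
        )
        assert ofv(shuffled, final_params, spec) == pytest.approx(
            ofv(small_cohort, final_params, spec), rel=1e-9
        )


class TestFit:
    def test_noiseless_data_recovers_generating_thetas(self, final_params):
        pop = final_params.replace(omega2_cl=0.0, sigma2_prop=0.0)
        ds = cohort.make_cohort(CohortDesign(seed=8, n_subjects=40), pop)
        res = fit(ds, final_model_spec(), compute_se=False)
        truth = {
            "theta_cl": 10.3, "theta_v": 50.6, "beta_cl_weight": 1.06,
            "beta_cl_scr": -0.315, "theta_cl_ceftriaxone": 1.46,
        }
        for name, val in truth.items():
            assert res.estimates[name] == pytest.approx(val, rel=1e-3), name

    def test_dropping_weight_costs_more_than_chi2_threshold(self, final_params, study_cohort):
        spec = final_model_spec()
        full = fit(study_cohort, spec, compute_se=False)
        no_wt = ModelSpec(
            covariate_terms=tuple(
                t for t in spec.covariate_terms
                if not (t.parameter == "cl" and t.covariate == "weight")
            )
        )
        reduced = fit(study_cohort, no_wt, compute_se=False)
        assert reduced.ofv - full.ofv > 6.63

    def test_nested_model_ofv_ordering(self, final_params, study_cohort):
        base = fit(study_cohort, base_model_spec(), n_restarts=2, compute_se=False)
        wt = fit(
            study_cohort,
            base_model_spec().with_term(CovariateTerm("cl", "weight", "power", reference=70.0)),
            n_restarts=2,
            compute_se=False,
        )
        assert wt.ofv <= base.ofv + 0.1  # nesting, up to optimizer tolerance

    def test_scale_equivariance_of_structural_estimates(self, final_params):
        ds = cohort.make_cohort(CohortDesign(seed=12, n_subjects=30), final_params)
        c = 2.5
        scaled = PKDataset(
            subjects=dict(ds.subjects),
            events=[
                Event(e.subject_id, e.time, e.kind,
                      None if e.amount is None else c * e.amount,
                      e.infusion_duration,
                      None if e.concentration is None else c * e.concentration,
                      e.observation_label, e.below_loq)
                for e in ds.events
            ],
        )
        spec = final_model_spec()
        a = fit(ds, spec, compute_se=False, include_bql=True)
        b = fit(scaled, spec, compute_se=False, include_bql=True)
        assert b.estimates["theta_cl"] == pytest.approx(a.estimates["theta_cl"], rel=1e-3)
        assert b.estimates["theta_v"] == pytest.approx(a.estimates["theta_v"], rel=1e-3)

    def test_median_estimates_near_truth_across_replicates(self, final_params):
        """Simulation-based recovery at the study design (20 replicates)."""
        spec = final_model_spec()
        names = ["theta_cl", "theta_v", "beta_cl_weight", "beta_cl_scr", "theta_cl_ceftriaxone"]
        truth = [10.3, 50.6, 1.06, -0.315, 1.46]
        ests = {n: [] for n in names}
        for seed in range(100, 120):
            ds = cohort.make_cohort(CohortDesign(seed=seed), final_params)
            res = fit(ds, spec, compute_se=False)
            for n in names:
                ests[n].append(res.estimates[n])
        for n, t in zip(names, truth):
            med = float(np.median(ests[n]))
            assert abs(med - t) / abs(t) < 0.15, (n, med)

    def test_large_cohort_consistency(self, final_params):
        ds = cohort.make_cohort(CohortDesign(seed=77, n_subjects=470), final_params)
        res = fit(ds, final_model_spec(), compute_se=False)
        assert abs(math.log(res.estimates["theta_cl"] / 10.3)) < 0.12
        assert abs(math.log(res.estimates["theta_v"] / 50.6)) < 0.08

    def test_reported_uncertainty_fields(self, final_params, small_cohort):
        res = fit(small_cohort, final_model_spec())
        for name, est in res.estimates.items():
            se = res.se[name]
            assert se >= 0
            assert res.rse_percent[name] == pytest.approx(100 * se / abs(est))
            lo, hi = res.ci95[name]
            assert lo <= est <= hi
        pp = res.population_params
        assert pp.theta_cl == res.estimates["theta_cl"]
        assert pp.power_wt_v == 1.0
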