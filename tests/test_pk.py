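"""Structural kinetics, covariate model and renal-function derivations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vancopk import pk
from vancopk.data import SubjectRecord

from _oracles import ode_concentration_1cpt, ode_concentration_2cpt


def subject(weight, scr, **kw):
    return SubjectRecord(subject_id="s", weight=weight, scr=scr, **kw)


class TestCovariateModel:
    def test_reference_covariates_return_population_values(self, final_params):
        ind = pk.typical_params(subject(70.0, 20.0), final_params)
        assert ind.cl == pytest.approx(10.3, abs=1e-12)
        assert ind.v == pytest.approx(50.6, abs=1e-12)

    def test_ceftriaxone_multiplies_clearance(self, final_params):
        ind = pk.typical_params(subject(70.0, 20.0, ceftriaxone=1), final_params)
        assert ind.cl == pytest.approx(10.3 * 1.46, rel=1e-12)
        assert ind.v == pytest.approx(50.6, rel=1e-12)

    def test_premature_neonate_closed_form(self, final_params):
        # independent evaluation of the power law for WT=0.95 kg, SCR=100
        cl = 10.3 * (0.95 / 70.0) ** 1.06 * (100.0 / 20.0) ** -0.315
        v = 50.6 * (0.95 / 70.0)
        ind = pk.typical_params(subject(0.95, 100.0), final_params)
        assert ind.cl == pytest.approx(cl, rel=1e-12)
        assert ind.v == pytest.approx(v, rel=1e-12)
        assert ind.cl == pytest.approx(0.0650, abs=5e-4)
        assert ind.v == pytest.approx(0.6867, abs=5e-4)

    @given(
        wt=st.floats(1.4, 18.0),
        scr=st.floats(5.5, 50.0),
        factor=st.floats(1.05, 1.6),
    )
    def test_monotone_in_weight_and_creatinine(self, final_params, wt, scr, factor):
        base = pk.typical_params(subject(wt, scr), final_params)
        heavier = pk.typical_params(subject(wt * factor, scr), final_params)
        sicker = pk.typical_params(subject(wt, scr * factor), final_params)
        assert heavier.cl > base.cl and heavier.v > base.v
        assert sicker.cl < base.cl

    def test_eta_scales_clearance_only(self):
        typ = pk.IndividualParams(cl=2.0, v=10.0)
        assert pk.individual_params(typ, 0.0) == typ
        up = pk.individual_params(typ, math.log(2.0))
        assert up.cl == pytest.approx(4.0) and up.v == 10.0
        down = pk.individual_params(typ, -math.log(2.0))
        assert down.cl == pytest.approx(1.0)

    def test_missing_covariate_raises(self, final_params):
        s = SubjectRecord(subject_id="s", weight=float("nan"), scr=20.0)
        s.weight = None
        with pytest.raises(ValueError):
            pk.typical_params(s, final_params)


class TestConcentration:
    def test_zero_before_first_dose(self):
        ind = pk.IndividualParams(cl=1.0, v=10.0)
        doses = [(2.0, 50.0, 1.0)]
        assert pk.concentration(ind, doses, 1.0) == 0.0
        assert pk.concentration(ind, doses, 0.0) == 0.0

    def test_mass_conservation_in_slow_elimination_limit(self):
        # k -> 0: everything infused is still in the compartment
        ind = pk.IndividualParams(cl=1e-8, v=10.0)
        c_end = pk.concentration(ind, [(0.0, 50.0, 2.0)], 2.0)
        assert c_end == pytest.approx(50.0 / 10.0, rel=1e-6)

    @given(
        cl=st.floats(0.05, 12.0),
        v=st.floats(0.5, 60.0),
        n_doses=st.integers(1, 6),
        tau=st.floats(4.0, 24.0),
        dur=st.floats(0.25, 2.0),
        t_frac=st.floats(0.01, 0.99),
    )
    def test_matches_ode_oracle(self, cl, v, n_doses, tau, dur, t_frac):
        """Closed-form superposition equals brute-force ODE integration."""
        if tau <= dur:
            tau = dur + 1.0
        ind = pk.IndividualParams(cl=cl, v=v)
        doses = [(i * tau, 25.0, dur) for i in range(n_doses)]
        t = t_frac * n_doses * tau
        expected = ode_concentration_1cpt(cl, v, doses, [t])[0]
        got = pk.concentration(ind, doses, t)
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    @given(scale=st.floats(0.1, 10.0))
    def test_superposition_linearity(self, scale):
        ind = pk.IndividualParams(cl=0.5, v=3.0)
        doses = [(0.0, 40.0, 1.0), (6.0, 40.0, 1.0), (12.0, 20.0, 0.5)]
        scaled = [(t0, a * scale, d) for t0, a, d in doses]
        t = np.linspace(0.2, 20.0, 23)
        np.testing.assert_allclose(
            pk.concentration(ind, scaled, t),
            scale * pk.concentration(ind, doses, t),
            rtol=1e-12,
        )


class TestSteadyState:
    def test_agrees_with_long_superposition(self, final_params):
        ind = pk.typical_params(subject(0.95, 100.0), final_params)
        tau, dur, amount = 24.0, 1.0, 19.0
        # the tail missed by truncating the superposition decays like
        # e^(-k n tau): ~22 half-lives leaves < 1e-6 of the accumulation
        n = int(np.ceil(22 * ind.t_half / tau)) + 1
        doses = [(i * tau, amount, dur) for i in range(n)]
        for s in (dur, 6.0, tau):
            ss = pk.steady_state_conc(ind, amount, tau, dur, s)
            sup = pk.concentration(ind, doses, (n - 1) * tau + s)
            assert ss == pytest.approx(sup, rel=1e-6)

    def test_accumulation_ratio_two_at_half_life_interval(self):
        # bolus limit, tau = t_half: accumulation factor 1/(1 - 1/2) = 2
        ind = pk.IndividualParams(cl=math.log(2.0), v=1.0)  # k = ln 2, t_half = 1
        tau, dur = 1.0, 1e-7
        single = pk.concentration(ind, [(0.0, 5.0, dur)], dur)
        ss_peak = pk.steady_state_conc(ind, 5.0, tau, dur, dur)
        assert ss_peak / single == pytest.approx(2.0, rel=1e-4)

    def test_infinite_interval_is_single_dose(self):
        ind = pk.IndividualParams(cl=0.5, v=3.0)
        ss = pk.steady_state_conc(ind, 30.0, 5000.0, 1.0, 8.0)
        single = pk.concentration(ind, [(0.0, 30.0, 1.0)], 8.0)
        assert ss == pytest.approx(single, rel=1e-9)

    def test_interval_must_exceed_infusion(self):
        ind = pk.IndividualParams(cl=0.5, v=3.0)
        with pytest.raises(ValueError):
            pk.steady_state_conc(ind, 10.0, 1.0, 1.0, 0.5)


class TestTwoCompartment:
    def test_collapses_to_one_compartment_as_q_vanishes(self):
        ind = pk.IndividualParams(cl=0.5, v=3.0)
        doses = [(0.0, 40.0, 1.0), (8.0, 40.0, 1.0)]
        t = np.linspace(0.5, 16.0, 12)
        c2 = pk.concentration_2cpt(ind, q=1e-9, v2=5.0, doses=doses, t=t)
        c1 = pk.concentration(ind, doses, t)
        np.testing.assert_allclose(c2, c1, rtol=1e-6)

    def test_zero_before_dosing(self):
        ind = pk.IndividualParams(cl=0.5, v=3.0)
        assert pk.concentration_2cpt(ind, 0.3, 5.0, [(2.0, 10.0, 1.0)], 1.0) == 0.0

    @given(
        cl=st.floats(0.1, 5.0),
        v1=st.floats(1.0, 30.0),
        q=st.floats(0.05, 5.0),
        v2=st.floats(1.0, 50.0),
        t_frac=st.floats(0.05, 0.95),
    )
    def test_matches_ode_oracle(self, cl, v1, q, v2, t_frac):
        doses = [(0.0, 100.0, 1.0), (12.0, 100.0, 1.0)]
        t = t_frac * 24.0
        expected = ode_concentration_2cpt(cl, v1, q, v2, doses, [t])[0]
        got = pk.concentration_2cpt(
            pk.IndividualParams(cl=cl, v=v1), q, v2, doses, t
        )
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)


class TestCreatinineClearance:
    def test_schwartz_term_infant(self):
        # height 52 cm, SCR 18.25 umol/L = 0.2064 mg/dL, k = 0.45
        s = subject(4.0, 18.25, height=52.0, age=100.0, gestational_age=39.0)
        expected = 0.45 * 52.0 / (18.25 / 88.4)
        assert pk.clcr(s, "schwartz") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(113.4, abs=0.5)

    def test_schwartz_inverse_in_creatinine(self):
        s1 = subject(4.0, 18.25, height=52.0, age=100.0)
        s2 = subject(4.0, 36.5, height=52.0, age=100.0)
        assert pk.clcr(s1, "schwartz") == pytest.approx(2 * pk.clcr(s2, "schwartz"))

    def test_schwartz_preterm_constant(self):
        term = subject(4.0, 18.25, height=52.0, age=100.0, gestational_age=40.0)
        preterm = subject(4.0, 18.25, height=52.0, age=100.0, gestational_age=29.0)
        assert pk.clcr(preterm, "schwartz") / pk.clcr(term, "schwartz") == pytest.approx(0.33 / 0.45)

    def test_schwartz_requires_height(self):
        with pytest.raises(ValueError):
            pk.clcr(subject(4.0, 18.25), "schwartz")

    def test_other_methods_positive_and_sex_adjusted(self):
        m = subject(4.0, 18.25, height=52.0, age=100.0, sex="male")
        f = subject(4.0, 18.25, height=52.0, age=100.0, sex="female")
        for method in ("cockcroft_gault", "mdrd4"):
            assert pk.clcr(m, method) > 0
            assert pk.clcr(f, method) < pk.clcr(m, method)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            pk.clcr(subject(4.0, 18.25), "jelliffe")
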