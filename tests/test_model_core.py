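"""Structural and covariate model: worked examples, invariants, numerics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import levocarb as lc
from levocarb import model_core as mc
from levocarb._num import erlang_exp_conv


class TestCovariateModel:
    def test_patient_clearance_worked_example(self, ld_model):
        """A 70-kg patient at Hoehn & Yahr 3 receiving 95 mg carbidopa has a
        levodopa CL/F of 34 L/h: 1.31 L/min × 60 × (1 − 0.0616·(3 − 1.53))
        / (1 + 95/86.7)."""
        cov = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=3, cd_dose=95)
        p = lc.individual_parameters(ld_model, cov)
        cl_lh = p.cl_f * 60.0
        assert cl_lh == pytest.approx(
            1.31 * 60 * (1 - 0.0616 * (3 - 1.53)) / (1 + 95 / 86.7), rel=1e-12
        )
        assert round(cl_lh) == 34

    def test_reference_covariates_reproduce_typical_values(self, cd_model):
        """With every covariate at its centring value the realised
        parameters equal the typical values exactly."""
        model = cd_model.copy()
        # integer covariates cannot sit at their non-integer pooled means,
        # so drop those effects and pin the continuous ones at reference
        cov = lc.SubjectCovariates(weight=70.0, age=48.7, sex=0, hy=0, cd_dose=0)
        model.covariate_effects = [
            e for e in model.covariate_effects
            if e.covariate not in ("hy", "sex")
        ]
        p = lc.individual_parameters(model, cov)
        assert p.cl_f == pytest.approx(model.theta["cl_f"], rel=1e-14)
        assert p.vc_f == pytest.approx(model.theta["vc_f"], rel=1e-14)
        assert p.mtt2 == pytest.approx(model.theta["mtt2"], rel=1e-14)

    def test_allometric_scaling_factor(self, ld_model):
        cov56 = lc.SubjectCovariates(weight=56, age=48.7, sex=0, hy=0, cd_dose=0)
        cov70 = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=0, cd_dose=0)
        p56 = lc.individual_parameters(ld_model, cov56)
        p70 = lc.individual_parameters(ld_model, cov70)
        assert p56.cl_f / p70.cl_f == pytest.approx((56 / 70) ** 0.75, rel=1e-12)
        assert p56.vc_f / p70.vc_f == pytest.approx(56 / 70, rel=1e-12)

    def test_covariate_neutrality_at_reference(self, ld_model, cd_model):
        """Every effect evaluates to factor 1 exactly at its reference."""
        for model in (ld_model, cd_model):
            for eff in model.covariate_effects:
                ref = eff.reference if eff.kind != "interaction" else 0.0
                assert eff.factor(ref) == pytest.approx(1.0, abs=1e-15)

    def test_sign_violating_linear_effect_names_covariate(self, ld_model):
        model = ld_model.copy()
        model.covariate_effects = list(model.covariate_effects) + [
            mc.CovariateEffect("vc_f", "age", "linear", -0.5, 48.7)
        ]
        cov = lc.SubjectCovariates(weight=70, age=80, sex=0, hy=0, cd_dose=0)
        with pytest.raises(ValueError, match="age"):
            lc.individual_parameters(model, cov)

    def test_random_effect_scales(self, cd_model):
        cov = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=0, cd_dose=0)
        model = cd_model.copy()
        model.covariate_effects = [
            e for e in model.covariate_effects if e.kind == "allometric"
        ]
        eta = {"cl_f": 0.3, "fa1": -0.5, "mtt1": 0.1}
        p = lc.individual_parameters(model, cov, eta)
        assert p.cl_f == pytest.approx(model.theta["cl_f"] * math.exp(0.3))
        from scipy.special import expit, logit

        assert p.fa1 == pytest.approx(expit(logit(model.theta["fa1"]) - 0.5))


class TestTerminalSlope:
    def test_carbidopa_half_life(self):
        """CL/F 1.05 L/min over 168 L gives a 111-minute half-life."""
        p = mc.PKParameters(cl_f=1.05, vc_f=168.0, mtt1=34.6, mtt2=121.0,
                            fa1=0.57)
        lam = lc.terminal_slope(p, 1)
        assert lam == pytest.approx(1.05 / 168.0, rel=1e-14)
        assert math.log(2) / lam == pytest.approx(111, abs=0.5)

    def test_two_compartment_roots_match_polynomial(self):
        p = mc.PKParameters(cl_f=1.31, vc_f=45.4, mtt1=16.1, mtt2=86.2,
                            fa1=0.749, q_f=0.667, vp_f=44.9)
        k10, k12, k21 = 1.31 / 45.4, 0.667 / 45.4, 0.667 / 44.9
        roots = np.sort(np.roots([1.0, -(k10 + k12 + k21), k10 * k21]))
        lam_z = lc.terminal_slope(p, 2)
        assert lam_z == pytest.approx(roots[0], rel=1e-9)
        # product and sum identities
        assert roots[0] * roots[1] == pytest.approx(k10 * k21, rel=1e-12)
        assert roots[0] + roots[1] == pytest.approx(k10 + k12 + k21, rel=1e-12)

    def test_vanishing_intercompartmental_flow_reduces_to_one_compartment(
        self, cd_model, ld_model
    ):
        """As q -> 0 the peripheral compartment decouples: its eigenvalue
        (q/vp) carries vanishing amplitude and the concentration profile
        converges to the one-compartment solution with slope cl/vc."""
        from levocarb._num import disposition_terms

        p2 = mc.PKParameters(cl_f=1.0, vc_f=50.0, mtt1=10.0, mtt2=60.0,
                             fa1=0.5, c0=0.0, q_f=1e-9, vp_f=40.0)
        p1 = mc.PKParameters(cl_f=1.0, vc_f=50.0, mtt1=10.0, mtt2=60.0,
                             fa1=0.5, c0=0.0)
        lams, coefs = disposition_terms(p2.cl_f, p2.vc_f, p2.q_f, p2.vp_f)
        # the dominant (full-amplitude) exponent is cl/vc
        dominant = lams[..., np.argmax(coefs)]
        assert dominant == pytest.approx(1.0 / 50.0, rel=1e-6)
        model2 = ld_model.copy()
        model2.transit = mc.TransitConfig(5, 6)
        model1 = cd_model.copy()
        model1.transit = mc.TransitConfig(5, 6)
        t = np.linspace(5, 720, 25)
        c2 = lc.predict_concentration(model2, p2, [(0.0, 100.0)], t)
        c1 = lc.predict_concentration(model1, p1, [(0.0, 100.0)], t)
        np.testing.assert_allclose(c2, c1, rtol=1e-6)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            mc.PKParameters(cl_f=-1.0, vc_f=50.0, mtt1=10, mtt2=60, fa1=0.5)


class TestTransitInput:
    def test_zero_at_time_zero(self):
        assert lc.transit_input_rate(0.0, 100, 0.7, 16.1, 5) == 0.0

    @pytest.mark.parametrize("n,mtt,frac", [(5, 16.1, 0.749), (10, 121.0, 0.43),
                                            (1, 30.0, 0.5)])
    def test_integral_recovers_dose_fraction(self, n, mtt, frac):
        val, _ = quad(lambda s: lc.transit_input_rate(s, 100.0, frac, mtt, n),
                      0, np.inf)
        assert val == pytest.approx(100.0 * frac, rel=1e-8)

    def test_peak_time_is_n_over_ktr(self):
        n, mtt = 5, 16.1
        ktr = (n + 1) / mtt
        grid = np.linspace(1e-3, 5 * mtt, 20001)
        rates = lc.transit_input_rate(grid, 100.0, 0.7, mtt, n)
        assert grid[np.argmax(rates)] == pytest.approx(n / ktr, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            lc.transit_input_rate(-1.0, 100, 0.5, 16.1, 5)


@st.composite
def _conv_params(draw):
    m = draw(st.integers(min_value=1, max_value=12))
    ktr = 10 ** draw(st.floats(min_value=-2.0, max_value=1.0))
    lam = 10 ** draw(st.floats(min_value=-3.0, max_value=0.5))
    tau = 10 ** draw(st.floats(min_value=-0.5, max_value=3.0))
    return m, ktr, lam, tau


class TestConvolutionKernel:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(_conv_params())
    def test_matches_quadrature(self, params):
        """The closed-form Erlang-by-exponential convolution agrees with
        direct numerical integration wherever the value is non-negligible."""
        from scipy.stats import gamma as gdist

        m, ktr, lam, tau = params
        g = gdist(a=m, scale=1 / ktr)
        pts = sorted({min(tau * 0.999, float(p))
                      for p in g.ppf([1e-9, 0.05, 0.5, 0.95, 1 - 1e-9])}
                     | {tau * 0.9, tau * 0.999})
        ref = quad(lambda s: g.pdf(s) * np.exp(-lam * (tau - s)), 0, tau,
                   limit=300, points=pts)[0]
        got = float(erlang_exp_conv(np.array([tau]), m, ktr, lam)[0])
        if ref > 1e-10:
            assert got == pytest.approx(ref, rel=5e-5)

    def test_bounded_between_zero_and_one(self, rng):
        tau = rng.uniform(0, 1000, size=200)
        out = erlang_exp_conv(tau, 6, 0.4, 0.05)
        assert np.all(out >= 0) and np.all(out <= 1 + 1e-12)


@pytest.fixture()
def typical_ld(ld_model):
    cov = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=3, cd_dose=95)
    return lc.individual_parameters(ld_model, cov)


class TestPrediction:
    def test_zero_dose_zero_baseline_gives_zero(self, ld_model, typical_ld):
        p = mc.PKParameters(cl_f=typical_ld.cl_f, vc_f=typical_ld.vc_f,
                            mtt1=typical_ld.mtt1, mtt2=typical_ld.mtt2,
                            fa1=typical_ld.fa1, c0=0.0,
                            q_f=typical_ld.q_f, vp_f=typical_ld.vp_f)
        t = np.linspace(0, 720, 20)
        conc = lc.predict_concentration(ld_model, p, [(0.0, 0.0)], t)
        assert np.all(conc == 0.0)

    def test_linearity_in_dose(self, ld_model, typical_ld):
        p = mc.PKParameters(cl_f=typical_ld.cl_f, vc_f=typical_ld.vc_f,
                            mtt1=typical_ld.mtt1, mtt2=typical_ld.mtt2,
                            fa1=typical_ld.fa1, c0=0.0,
                            q_f=typical_ld.q_f, vp_f=typical_ld.vp_f)
        t = np.linspace(5, 720, 30)
        c1 = lc.predict_concentration(ld_model, p, [(0.0, 100.0)], t)
        c2 = lc.predict_concentration(ld_model, p, [(0.0, 200.0)], t)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_multidose_superposition(self, ld_model, typical_ld):
        p = mc.PKParameters(cl_f=typical_ld.cl_f, vc_f=typical_ld.vc_f,
                            mtt1=typical_ld.mtt1, mtt2=typical_ld.mtt2,
                            fa1=typical_ld.fa1, c0=0.0,
                            q_f=typical_ld.q_f, vp_f=typical_ld.vp_f)
        t = np.linspace(0, 900, 61)
        multi = lc.predict_concentration(
            ld_model, p, [(0.0, 75.0), (144.0, 45.0), (288.0, 45.0)], t)
        single = sum(
            lc.predict_concentration(ld_model, p, [(t0, a)], t)
            for t0, a in [(0.0, 75.0), (144.0, 45.0), (288.0, 45.0)]
        )
        np.testing.assert_allclose(multi, single, rtol=1e-10, atol=1e-14)

    def test_identical_chains_collapse_to_single_chain(self, ld_model):
        """Two chains with the same (mtt, n) and fa1 = 1/2 behave as one
        chain receiving the whole dose."""
        model = ld_model.copy()
        model.transit = mc.TransitConfig(5, 5)
        p = mc.PKParameters(cl_f=1.31, vc_f=45.4, mtt1=40.0, mtt2=40.0,
                            fa1=0.5, c0=0.0, q_f=0.667, vp_f=44.9)
        t = np.linspace(5, 720, 40)
        both = lc.predict_concentration(model, p, [(0.0, 100.0)], t)
        # single chain: put the whole dose through chain 1 (fa1 -> 1 limit)
        p_one = mc.PKParameters(cl_f=1.31, vc_f=45.4, mtt1=40.0, mtt2=40.0,
                                fa1=1 - 1e-12, c0=0.0, q_f=0.667, vp_f=44.9)
        one = lc.predict_concentration(model, p_one, [(0.0, 100.0)], t)
        np.testing.assert_allclose(both, one, rtol=1e-9)

    def test_analytic_agrees_with_ode(self, ld_model, cd_model):
        for model, kwargs in (
            (ld_model, dict(q_f=0.667, vp_f=44.9, cl_f=1.31, vc_f=45.4,
                            mtt1=16.1, mtt2=86.2, fa1=0.749, c0=0.12)),
            (cd_model, dict(cl_f=1.05, vc_f=168.0, mtt1=34.6, mtt2=121.0,
                            fa1=0.57, c0=0.0256)),
        ):
            p = mc.PKParameters(**kwargs)
            t = np.array([1, 5, 10, 20, 40, 80, 160, 320, 640, 1280.0])
            ca = lc.predict_concentration(model, p, [(0.0, 100.0)], t)
            co = lc.predict_concentration(model, p, [(0.0, 100.0)], t,
                                          method="ode")
            np.testing.assert_allclose(ca, co, rtol=5e-6)

    def test_mass_balance_at_24_hours(self, ld_model):
        """Input + remaining + eliminated accounts for the full absorbed
        dose at every output time, and the 24-h budget closes within 0.1%."""
        cov = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=0, cd_dose=0)
        p = lc.individual_parameters(ld_model, cov)
        t = np.linspace(30, 1440, 30)
        sol = mc.predict_amounts(ld_model, p, [(0.0, 100.0)], t)
        total = sol["states"][:, :-1].sum(axis=1) + sol["eliminated"]
        np.testing.assert_allclose(total, 100.0 * p.f_rel, rtol=1e-6)
        assert sol["eliminated"][-1] + sol["states"][-1, :-1].sum() == \
            pytest.approx(100.0 * p.f_rel, rel=1e-3)

    def test_pre_dose_baseline_back_extrapolates(self, cd_model):
        p = mc.PKParameters(cl_f=1.05, vc_f=168.0, mtt1=34.6, mtt2=121.0,
                            fa1=0.57, c0=0.0256)
        conc = lc.predict_concentration(cd_model, p, [(0.0, 25.0)],
                                        np.array([-30.0]))
        lam = p.lambda_z
        assert conc[0] == pytest.approx(0.0256 * math.exp(lam * 30.0), rel=1e-12)

    def test_unsorted_times_rejected(self, cd_model):
        p = mc.PKParameters(cl_f=1.05, vc_f=168.0, mtt1=34.6, mtt2=121.0,
                            fa1=0.57)
        with pytest.raises(ValueError):
            lc.predict_concentration(cd_model, p, [(0, 25)], [10.0, 5.0])


class TestModelFiles:
    def test_packaged_models_reproduce_reference_table(self, ld_model, cd_model):
        assert ld_model.theta["cl_f"] == 1.31
        assert ld_model.theta["vp_f"] == 44.9
        assert cd_model.n_disposition_compartments == 1
        assert (ld_model.transit.n1, ld_model.transit.n2) == (5, 6)
        assert (cd_model.transit.n1, cd_model.transit.n2) == (3, 10)
        assert ld_model.sigma.shared_fraction == 0.285
        re = lc.load_packaged_model("reference_ld", variant="reestimated")
        assert re.theta["cl_f"] == 1.21
        effs = {(e.parameter, e.covariate): e for e in re.covariate_effects
                if e.kind == "linear"}
        assert effs[("cl_f", "hy")].coefficient == -0.0967
        assert ("f_rel", "age") not in effs

    def test_round_trip(self, tmp_path, ld_model):
        path = tmp_path / "model.yaml"
        mc.save_model(ld_model, path)
        back = mc.load_model(path)
        assert back.theta == ld_model.theta
        assert back.transit == ld_model.transit
        assert back.covariate_effects == ld_model.covariate_effects
        assert back.omega == ld_model.omega
        assert back.sigma == ld_model.sigma
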