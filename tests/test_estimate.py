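"""Likelihood, Laplace estimation, LRT and SIR."""

import copy
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import levocarb as lc
from levocarb import estimate as est
from levocarb import popsim
from levocarb.model_core import OmegaEntry


def _one_subject_dataset(model, cov_row, times, dose, dv, drug="carbidopa",
                         lod=0.0):
    dvid = popsim.DRUG_DVID[drug]
    rows = [{"ID": 1, "TIME": 0.0, "AMT": dose, "DV": np.nan, "EVID": 1,
             "MDV": 1, "DVID": dvid, "BLQ": 0, "LOD": lod, **cov_row}]
    for t, v in zip(times, dv):
        rows.append(rows[0] | {"TIME": float(t), "AMT": np.nan, "DV": float(v),
                               "EVID": 0, "MDV": 0})
    return popsim.PKDataset(pd.DataFrame(rows))


_COV = {"WT": 70.0, "AGE": 48.7, "SEX": 0, "HY": 0, "CDOSE": 25.0,
        "STUDY": "s"}


class TestIndividualNll:
    def test_single_observation_closed_form(self, cd_model):
        """Zero residual at one observation: nll is the two Gaussian
        normalisation terms ½log(2πσ²) + ½log|2πΩ|."""
        model = cd_model.copy()
        model.covariate_effects = [e for e in model.covariate_effects
                                   if e.kind == "allometric"]
        model.omega = {"cl_f": OmegaEntry(sd=0.2)}
        cov = lc.SubjectCovariates(weight=70, age=48.7, sex=0, hy=0, cd_dose=0)
        p = lc.individual_parameters(model, cov)
        t = np.array([60.0])
        f = lc.predict_concentration(model, p, [(0.0, 25.0)], t)
        ds = _one_subject_dataset(model, _COV, t, 25.0, f)
        sigma = float(model.sigma.sd(f, patient=False)[0])
        expected = 0.5 * np.log(2 * np.pi * sigma**2) \
            + 0.5 * np.log(2 * np.pi * 0.2**2)
        assert est.individual_nll(model, ds, {"cl_f": 0.0}) == \
            pytest.approx(expected, rel=1e-10)

    def test_uncorrelated_pair_equals_sum_of_univariate(self, ld_model, cd_model):
        ld0 = ld_model.copy()
        cd0 = cd_model.copy()
        from dataclasses import replace

        ld0.sigma = replace(ld0.sigma, shared_fraction=0.0)
        cd0.sigma = replace(cd0.sigma, shared_fraction=0.0)
        d = lc.load_packaged_design("study1")
        d.n_subjects = 1
        ds = lc.sample_population(d, ld0, cd0, seed=3)
        eta = {}
        joint = est.individual_nll((ld0, cd0), ds, eta)
        separate = est.individual_nll(ld0, ds, eta) + \
            est.individual_nll(cd0, ds, eta)
        assert joint == pytest.approx(separate, rel=1e-10)

    def test_matches_dense_multivariate_normal(self, ld_model, cd_model):
        """Three paired LD/CD observations against a direct 6x6
        multivariate-normal density with the shared-error correlation."""
        ld0, cd0 = ld_model.copy(), cd_model.copy()
        ld0.omega, cd0.omega = {}, {}
        d = lc.load_packaged_design("study1")
        d.n_subjects = 1
        import copy as _c

        d = _c.deepcopy(d)
        d.sampling_times = [30.0, 120.0, 300.0]
        ds = lc.sample_population(d, ld0, cd0, seed=9)
        from levocarb import diagnose

        pred = diagnose.typical_predictions(ds, ld0, cd0)
        obs = ds.observations().sort_values(["DVID", "TIME"])
        f = pred.loc[obs.index].to_numpy(dtype=float)
        y = obs["DV"].to_numpy(dtype=float)
        sd = np.where(obs["DVID"] == 1, ld0.sigma.sd(f, False),
                      cd0.sigma.sd(f, False))
        rho = ld0.sigma.shared_fraction
        cov = np.diag(sd**2).astype(float)
        for i in range(3):  # pair (ld_i, cd_i)
            cov[i, i + 3] = cov[i + 3, i] = rho * sd[i] * sd[i + 3]
        expected = -stats.multivariate_normal(mean=f, cov=cov).logpdf(y)
        got = est.individual_nll((ld0, cd0), ds, None)
        assert got == pytest.approx(expected, rel=1e-9)


class TestLaplace:
    def test_zero_iiv_reduces_to_pooled_gaussian_likelihood(self, cd_model,
                                                            study1, ld_model):
        d = copy.deepcopy(study1)
        d.n_subjects = 4
        ds = lc.sample_population(d, ld_model, cd_model, seed=11)
        model = cd_model.copy()
        model.omega = {}
        ofv = est.evaluate_ofv(ds, model)
        from levocarb import diagnose

        pred = diagnose.typical_predictions(ds, model, model)
        obs = ds.observations("carbidopa")
        f = pred.loc[obs.index].to_numpy(dtype=float)
        y = obs["DV"].to_numpy(dtype=float)
        sd = np.maximum(model.sigma.sd(f, False), 1e-10)
        direct = -2 * np.sum(stats.norm.logpdf(y, loc=f, scale=sd))
        assert ofv == pytest.approx(direct, rel=1e-9)

    def test_laplace_close_to_exact_marginal_one_eta(self, cd_model, ld_model):
        """On a one-random-effect model the Laplace OFV is within 1% of the
        exact marginal −2·log-likelihood computed by adaptive quadrature."""
        model = cd_model.copy()
        model.theta["c0"] = 0.0
        model.omega = {"cl_f": OmegaEntry(sd=0.25)}
        d = lc.load_packaged_design("study1")
        d = copy.deepcopy(d)
        d.n_subjects = 3
        gen_ld = ld_model.copy()
        ds = lc.sample_population(d, gen_ld, model, seed=19)
        ofv_laplace = est.evaluate_ofv(ds, model)

        total = 0.0
        for sid in range(1, 4):
            sub = popsim.PKDataset(ds.df[ds.df["ID"] == sid].copy(),
                                   validate=False)

            def integrand(e):
                return np.exp(-est.individual_nll(model, sub, {"cl_f": e}))

            marg, _ = quad(integrand, -2.0, 2.0, limit=200)
            total += -2.0 * np.log(marg)
        assert ofv_laplace == pytest.approx(total, rel=0.01)

    def test_fit_is_deterministic(self, small_patient_dataset, cd_model):
        model = cd_model.copy()
        free = est.FreeSpec(theta=["cl_f"], omega=["cl_f"])
        settings = est.FitSettings(outer_maxiter=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = est.fit_population(small_patient_dataset, model, free=free,
                                    settings=settings)
            f2 = est.fit_population(small_patient_dataset, model, free=free,
                                    settings=settings)
        assert f1.ofv == f2.ofv
        assert f1.theta_hat["cl_f"] == f2.theta_hat["cl_f"]

    def test_extra_parameter_never_increases_ofv(self, small_patient_dataset,
                                                 cd_model):
        model = cd_model.copy()
        settings = est.FitSettings(outer_maxiter=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = est.fit_population(
                small_patient_dataset, model,
                free=est.FreeSpec(theta=["cl_f"]), settings=settings)
            big = est.fit_population(
                small_patient_dataset, model,
                free=est.FreeSpec(theta=["cl_f", "vc_f"]), settings=settings)
        assert big.ofv <= small.ofv + 1e-3

    def test_shrinkage_grows_as_sampling_thins(self, ld_model, cd_model):
        """Eta shrinkage is small for dense sampling and increases
        monotonically as the schedule is thinned."""
        schedules = [
            [-30, 10, 20, 30, 40, 50, 60, 80, 100, 120, 150, 180, 240, 300,
             360, 480, 600, 720, 1440],
            [30, 120, 360, 720],
            [120, 720],
        ]
        shr = []
        for times in schedules:
            d = lc.load_packaged_design("study1")
            d = copy.deepcopy(d)
            d.sampling_times = [float(t) for t in times]
            d.n_subjects = 40
            model = cd_model.copy()
            model.theta["c0"] = 0.0
            model.omega = {"cl_f": OmegaEntry(sd=0.209),
                           "f_rel": OmegaEntry(sd=0.481)}
            ds = lc.sample_population(d, ld_model, model, seed=31)
            ebes = est.compute_ebes(ds, model)
            w = model.omega["cl_f"].sd
            shr.append(100 * (1 - ebes["cl_f"].std(ddof=1) / w))
        assert shr[0] < 12.0
        assert shr[0] < shr[1] < shr[2]


class TestLrt:
    def test_reference_threshold(self):
        assert est.lrt(100.0, 103.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_zero_delta(self):
        assert est.lrt(50.0, 50.0, 1) == 1.0

    def test_one_percent_threshold(self):
        assert est.lrt(0.0, 6.63, 1) == pytest.approx(0.01, abs=2e-4)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning):
            assert est.lrt(10.0, 8.0, 1) == 1.0

    def test_two_df(self):
        assert est.lrt(0.0, 5.99, 2) == pytest.approx(0.05, abs=1e-3)


class TestSir:
    def _gaussian(self, p=3, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((p, p))
        cov = A @ A.T + np.eye(p)
        mu = rng.uniform(-2, 2, p)
        icov = np.linalg.inv(cov)
        return mu, cov, lambda th: float((th - mu) @ icov @ (th - mu))

    def test_gaussian_target_recovers_analytic_interval(self):
        mu, cov, ofv = self._gaussian()
        res = est.run_sir(mu, cov, ofv, m_samples=2000, n_resamples=1000,
                          seed=7)
        sd = np.sqrt(np.diag(cov))
        for j in range(3):
            assert abs(res.ci_lo.iloc[j] - (mu[j] - 1.96 * sd[j])) < 0.2 * sd[j]
            assert abs(res.ci_hi.iloc[j] - (mu[j] + 1.96 * sd[j])) < 0.2 * sd[j]
        assert res.ess == pytest.approx(2000, rel=1e-6)

    def test_uniform_weights_full_resample_is_permutation(self):
        mu, cov, ofv = self._gaussian(seed=1)
        res = est.run_sir(mu, cov, ofv, m_samples=300, n_resamples=300, seed=2)
        # same draws, just reordered
        rng = np.random.default_rng(2)
        draws = rng.multivariate_normal(mu, cov, size=300)
        assert np.allclose(np.sort(res.samples.values, axis=0),
                           np.sort(draws, axis=0))

    def test_fixed_seed_reproducible(self):
        mu, cov, ofv = self._gaussian(seed=3)
        a = est.run_sir(mu, cov, ofv, 500, 200, seed=9)
        b = est.run_sir(mu, cov, ofv, 500, 200, seed=9)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_poor_proposal_warns_on_low_ess(self):
        mu, cov, _ = self._gaussian(seed=4)
        shifted = mu + 8 * np.sqrt(np.diag(cov))
        icov = np.linalg.inv(cov)

        def ofv(th):
            return float(20 * (th - shifted) @ icov @ (th - shifted))

        with pytest.warns(UserWarning, match="effective sample size"):
            est.run_sir(mu, cov, ofv, 300, 50, seed=5)

    def test_interval_contains_median(self):
        mu, cov, ofv = self._gaussian(seed=6)
        res = est.run_sir(mu, cov, ofv, 500, 300, seed=11)
        assert (res.ci_lo <= res.median).all()
        assert (res.median <= res.ci_hi).all()
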