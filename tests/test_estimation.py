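import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from nanomsc_pkpd.estimate import (
    FitResult,
    ObservationRecord,
    PDLikelihood,
    _agq_animal,
    _laplace_animal,
    apply_modified_m3,
    covariance_from_hessian,
    fit_pk_layer,
    hessian_fd,
    individual_joint_nll,
    nll_pooled_proportional,
    profile_parameter,
    rse_from_hessian,
    sir_uncertainty,
)
from nanomsc_pkpd.synthetic import generate_pd_study, generate_pk_study


class TestPooledLikelihood:
    def test_single_record_closed_form(self):
        # y = f = sigma = 1: the only surviving term is log(2*pi)
        assert nll_pooled_proportional([1.0], [1.0], 1.0) == \
            pytest.approx(math.log(2.0 * math.pi))

    def test_proportional_scale_invariance_of_residual(self):
        y = np.array([1.0, 2.0, 3.0])
        f = np.array([1.1, 1.9, 3.3])
        a = nll_pooled_proportional(y, f, 0.4)
        b = nll_pooled_proportional(2 * y, 2 * f, 0.4)
        # doubling y and f shifts only the log-variance terms, by log(4) each
        assert b - a == pytest.approx(len(y) * math.log(4.0), rel=1e-12)

    def test_matches_per_record_summation_oracle(self):
        rng = np.random.default_rng(42)
        f = rng.uniform(0.5, 50.0, 10)
        y = f * (1 + rng.normal(0, 0.3, 10))
        sig = rng.uniform(0.2, 0.8, 10)
        total = nll_pooled_proportional(y, f, sig)
        brute = sum(
            math.log(2 * math.pi * (s * fi) ** 2) + (yi - fi) ** 2 / (s * fi) ** 2
            for yi, fi, s in zip(y, f, sig))
        assert total == pytest.approx(brute, rel=1e-12)

    def test_nonpositive_prediction_identified(self):
        with pytest.raises(ValueError, match="record 1"):
            nll_pooled_proportional([1.0, 2.0], [1.0, -1.0], 0.3)


class TestHessianMachinery:
    def test_quadratic_hessian_recovered(self):
        A = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])

        def f(x):
            return float(x @ A @ x)

        H = hessian_fd(f, np.array([0.3, -0.2, 1.0]))
        assert np.allclose(H, 2 * A, rtol=2e-4, atol=1e-6)

    def test_rse_from_curvature(self):
        # OFV = (x - m)^2 / s^2 on log scale: SE(log) = s * sqrt(2)
        H = np.array([[2.0 / 0.01]])  # s = 0.1
        rse = rse_from_hessian({"CL": 1.0}, H, ["CL"])
        assert rse["CL"] == pytest.approx(10.0, rel=1e-10)

    def test_indefinite_hessian_gives_nan_not_failure(self):
        H = np.array([[1.0, 0.0], [0.0, -1.0]])
        cov = covariance_from_hessian(H)
        assert np.isfinite(cov[0, 0]) and np.isnan(cov[1, 1])


class TestModifiedM3:
    @staticmethod
    def _study(rows):
        return pd.DataFrame(rows, columns=["ID", "ARM", "TIME", "TYPE", "DV"]) \
            .assign(CENS=0, ULIM=np.nan)

    def test_no_dropout_attaches_limits_only(self):
        rows = [("a", "control", t, "bioluminescence", v)
                for t, v in zip([0, 84, 168], [1.0, 2.0, 3.0])]
        out = apply_modified_m3(self._study(rows))
        assert out.CENS.sum() == 0
        assert (out.ULIM == 3.0).all()

    def test_missing_scheduled_times_materialized(self):
        sched = [0, 84, 168, 252, 336, 420, 504, 588]
        rows = [("a", "control", t, "bioluminescence", 1.0 + t / 100)
                for t in sched]
        rows += [("b", "control", t, "bioluminescence", 2.0 + t / 100)
                 for t in sched[:5]]  # b drops after its 5th sample
        out = apply_modified_m3(self._study(rows))
        b = out[out.ID == "b"]
        assert int(b.CENS.sum()) == 3
        assert b[b.CENS == 1].TIME.tolist() == [420.0, 504.0, 588.0]
        assert np.allclose(b.ULIM, 2.0 + 336 / 100)

    def test_maximum_itself_stays_continuous(self):
        rows = [("a", "control", t, "bioluminescence", v)
                for t, v in zip([0, 84, 168], [1.0, 5.0, 2.0])]
        out = apply_modified_m3(self._study(rows), schedule=[0, 84, 168, 252])
        row_max = out[(out.ID == "a") & (out.DV == 5.0)]
        assert (row_max.CENS == 0).all()
        assert int(out.CENS.sum()) == 1  # only the never-observed 252 h

    def test_record_validation(self):
        with pytest.raises(ValueError):
            ObservationRecord("a", "control", 0.0, "bioluminescence", -1.0)
        with pytest.raises(ValueError):
            ObservationRecord("a", "control", 0.0, "bioluminescence",
                              float("nan"), CENS=1, ULIM=float("nan"))


class TestIndividualJointNLL:
    @staticmethod
    def _records(y, cens, ulim):
        return pd.DataFrame({"TIME": np.arange(len(y), dtype=float),
                             "DV": y, "CENS": cens, "ULIM": ulim})

    def test_censored_far_below_prediction_contributes_nothing(self):
        # upper limit many error-SDs below the prediction: exceedance
        # probability ~1, so the record contributes nothing
        rec = self._records([np.nan], [1], [1.0])
        nll = individual_joint_nll(lambda eta: np.array([100.0]), rec,
                                   eta=0.0, sigma=0.01, omega=0.0)
        assert nll == pytest.approx(0.0, abs=1e-10)

    def test_censored_at_prediction_is_log_half(self):
        rec = self._records([np.nan], [1], [50.0])
        nll = individual_joint_nll(lambda eta: np.array([50.0]), rec,
                                   eta=0.0, sigma=0.3, omega=0.0)
        assert nll == pytest.approx(-2.0 * math.log(0.5), rel=1e-12)

    def test_matches_quadrature_oracle(self):
        # continuous records against the normal density and a censored one
        # against the integrated upper tail, on a 3-record fixture
        f = np.array([10.0, 20.0, 30.0])
        y = np.array([12.0, 17.0, np.nan])
        cens = np.array([0, 0, 1])
        ulim = np.array([np.nan, np.nan, 35.0])
        sigma, eta, omega = 0.4, 0.3, 0.8
        rec = self._records(y, cens, ulim)
        nll = individual_joint_nll(lambda e: f, rec, eta, sigma, omega)

        expected = 0.0
        for yi, fi in zip(y[:2], f[:2]):
            expected += -2.0 * math.log(
                norm.pdf(yi, loc=fi, scale=sigma * fi))
        tail, _ = quad(lambda u: norm.pdf(u, loc=f[2], scale=sigma * f[2]),
                       ulim[2], np.inf)
        expected += -2.0 * math.log(tail)
        expected += -2.0 * math.log(norm.pdf(eta, scale=omega))
        assert nll == pytest.approx(expected, rel=1e-8)


class TestLaplaceAndAGQ:
    @staticmethod
    def _gaussian_gfun(y, s, omega):
        """Joint -2 log density of y_j ~ N(eta, s^2) with eta ~ N(0, omega^2):
        the marginal is available in closed form."""
        y = np.asarray(y, dtype=float)

        def g(eta):
            return float(np.sum(np.log(2 * np.pi * s**2)
                                + (y - eta) ** 2 / s**2)
                         + math.log(2 * np.pi * omega**2) + eta**2 / omega**2)
        return g

    @staticmethod
    def _gaussian_marginal(y, s, omega):
        y = np.asarray(y, dtype=float)
        n = y.size
        # y_j = eta + e_j; joint normal with cov = omega^2 J + s^2 I
        cov = omega**2 * np.ones((n, n)) + s**2 * np.eye(n)
        dev = y
        _, logdet = np.linalg.slogdet(cov)
        return float(n * math.log(2 * math.pi) + logdet
                     + dev @ np.linalg.solve(cov, dev))

    def test_linear_gaussian_closed_form(self):
        y = [1.2, 0.7, 1.9, 0.4]
        g = self._gaussian_gfun(y, s=0.5, omega=1.3)
        exact = self._gaussian_marginal(y, 0.5, 1.3)
        lap, mode = _laplace_animal(g, omega=1.3, h=1e-5)
        agq = _agq_animal(g, omega=1.3, n_nodes=32)
        # Laplace is exact for a Gaussian joint density
        assert lap == pytest.approx(exact, abs=1e-6)
        assert agq == pytest.approx(exact, abs=1e-6)

    def test_omega_zero_reduces_to_fixed_effects(self):
        y = [1.2, 0.7]
        gfix = self._gaussian_gfun(y, 0.5, 1.0)

        def data_only(eta):
            return gfix(eta) - (math.log(2 * np.pi * 1.0) + eta**2)

        lap, mode = _laplace_animal(data_only, omega=0.0)
        assert mode == 0.0
        assert lap == pytest.approx(data_only(0.0))

    def test_surface_path_agrees_with_exact_path(self, params_dyn, pd_truth):
        obs, _ = generate_pd_study(params_dyn, seed=5, n_per_arm=2)
        m3 = apply_modified_m3(obs)
        lik_s = PDLikelihood(m3, base_params=params_dyn, method="surface")
        lik_e = PDLikelihood(m3, base_params=params_dyn, method="exact",
                             rtol=1e-10, atol=1e-12)
        assert lik_s.ofv(pd_truth) == pytest.approx(lik_e.ofv(pd_truth), abs=1.0)

    def test_sentinel_censored_record_changes_nothing(self, params_dyn, pd_truth):
        # a censored record whose limit is trivially exceeded (many
        # error-SDs below any plausible prediction) leaves the OFV unchanged
        obs, _ = generate_pd_study(params_dyn, seed=5, n_per_arm=2,
                                   regimens={"control": None})
        m3 = apply_modified_m3(obs)
        th = dict(pd_truth, eps_CTR=0.05)
        lik0 = PDLikelihood(m3, base_params=params_dyn)
        extra = m3.iloc[[0]].copy()
        extra["TIME"] = 84.0
        extra["CENS"] = 1
        extra["DV"] = np.nan
        extra["ULIM"] = 1e-6
        lik1 = PDLikelihood(pd.concat([m3, extra], ignore_index=True),
                            base_params=params_dyn)
        assert lik1.ofv(th) == pytest.approx(lik0.ofv(th), abs=1e-6)


class TestPKLayerFit:
    def test_noise_free_self_consistency(self, params):
        data = generate_pk_study(params, seed=0,
                                 sigmas={(a, t): 0.0
                                         for a in ("ptx_solution",)
                                         for t in ("plasma", "lung")},
                                 arms=("ptx_solution",))
        res = fit_pk_layer(data, "bottom", n_starts=1, polish=True,
                           compute_covariance=False)
        for name, truth in [("CL_PTX", 0.909), ("CLD_PTX", 0.336),
                            ("V_PTXcentral", 6.64)]:
            assert res.estimates[name] == pytest.approx(truth, rel=1e-4)

    def test_missing_lower_layer_rejected(self, pk_study):
        with pytest.raises(ValueError, match="lower-layer"):
            fit_pk_layer(pk_study, "middle")

    def test_middle_and_top_fit_run_and_fix_lower(self, pk_study):
        bottom = fit_pk_layer(pk_study, "bottom", n_starts=1, polish=False,
                              compute_covariance=False)
        middle = fit_pk_layer(pk_study, "middle", fixed_lower=[bottom],
                              n_starts=1, polish=False,
                              compute_covariance=False)
        assert "CL_PTX" in middle.fixed
        top = fit_pk_layer(pk_study, "top", fixed_lower=[bottom, middle],
                           n_starts=1, polish=False, compute_covariance=False)
        assert "CL_NP" in top.fixed
        assert top.metadata["arm"] == "nano_msc"
        # lower-layer results are untouched by the upper fits
        refit = fit_pk_layer(pk_study, "bottom", n_starts=1, polish=False,
                             compute_covariance=False)
        assert refit.estimates == bottom.estimates

    def test_covariance_and_rse_reported(self, params):
        data = generate_pk_study(params, seed=4, arms=("ptx_solution",))
        res = fit_pk_layer(data, "bottom", n_starts=1, polish=False)
        assert res.cov is not None
        assert all(np.isfinite(v) or np.isnan(v) for v in res.rse.values())


class TestSIR:
    @staticmethod
    def _gaussian_fit(n=3):
        # objective = d' P d plays the OFV (-2 log L), so the implied
        # parameter covariance is 2 * inv(H) = 2 * inv(2P) = inv(P)
        mu = np.log(np.array([1.0, 2.0, 0.5])[:n])
        prec = np.diag([50.0, 200.0, 80.0][:n])
        cov = np.linalg.inv(prec)

        def objective(x):
            d = x - mu
            return float(d @ prec @ d)

        fit = FitResult(estimates={f"p{i}": float(np.exp(m))
                                   for i, m in enumerate(mu)},
                        ofv=0.0, param_names=[f"p{i}" for i in range(n)],
                        cov=cov)
        return fit, objective, mu, cov

    def test_gaussian_surface_matches_wald(self):
        fit, objective, mu, cov = self._gaussian_fit()
        # resample well below m so the without-replacement draw does not
        # under-disperse the tails (standard SIR practice: n <= m/5)
        tab = sir_uncertainty(fit, objective, m=2000, n=400, seed=1)
        for i, row in tab.iterrows():
            se = math.sqrt(cov[i, i])
            wald_lo = math.exp(mu[i] - 1.96 * se)
            wald_hi = math.exp(mu[i] + 1.96 * se)
            assert row.ci_lo == pytest.approx(wald_lo, rel=0.05)
            assert row.ci_hi == pytest.approx(wald_hi, rel=0.05)

    def test_seed_reproducibility(self):
        fit, objective, _, _ = self._gaussian_fit()
        a = sir_uncertainty(fit, objective, m=500, n=100, seed=9)
        b = sir_uncertainty(fit, objective, m=500, n=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_weights_rejected(self):
        fit, _, mu, _ = self._gaussian_fit()

        def spiky(x):
            return 0.0 if np.allclose(x, mu) else 1e8

        with pytest.raises(RuntimeError, match="effective sample size"):
            sir_uncertainty(fit, spiky, m=200, n=50, seed=0)

    def test_profile_utility(self):
        fit, objective, mu, _ = self._gaussian_fit()
        grid = [0.8, 1.0, 1.25]
        prof = profile_parameter(objective, mu, 0, grid)
        assert prof.ofv.idxmin() == 1
        assert prof.value.tolist() == grid
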