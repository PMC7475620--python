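"""Shared random-effect joint model: likelihood oracles and fitting."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from trajsurv.data import CohortArrays, CovariateVector, filter_eligible
from trajsurv.srem import (
    SREMParams,
    _pack,
    _unpack,
    empirical_bayes,
    fit_srem,
    marginal_loglik,
    subject_loglik_given_b,
    trajectory_mean,
    two_stage_init,
)
from trajsurv.weibull import WeibullPH, event_loglik


def simple_params(assoc=(0.0, 0.0)):
    return SREMParams(
        beta=np.array([4.8, 0.3, -0.2, -0.01, -0.08]),
        re_cov=np.array([[0.4, -0.02], [-0.02, 0.01]]),
        resid_var=0.2,
        hazard=WeibullPH(1.2, 3.0, np.array([-0.5, -0.3, -0.02])),
        assoc=np.array(assoc),
    )


class TestTrajectoryMean:
    def test_zero_everything(self):
        p = simple_params()
        p.beta = np.zeros(5)
        assert trajectory_mean(p, CovariateVector(1, 1, 50.0), (0.0, 0.0), 7.0) == 0.0

    def test_random_intercept_shift(self):
        p = simple_params()
        p.beta = np.zeros(5)
        assert trajectory_mean(p, CovariateVector(0, 0, 1.0), (1.0, 0.0), 3.0) == 1.0

    def test_population_decline_arithmetic(self):
        # intercept 4.825, slope -0.079/year: population mean at 10 years
        p = simple_params()
        p.beta = np.array([4.825, 0.0, 0.0, 0.0, -0.079])
        val = trajectory_mean(p, CovariateVector(0, 0, 1e-9), (0.0, 0.0), 10.0)
        assert val == pytest.approx(4.825 - 0.79, abs=1e-12)


class TestSubjectLoglikGivenB:
    def test_zero_residual_censored_reduces_to_normal_constants(self):
        p = simple_params()
        p.beta = np.zeros(5)
        p.resid_var = 1.0
        p.hazard = WeibullPH(1.0, 1e12)  # negligible hazard: Lambda ~ 0
        k = 4
        times = np.linspace(0, 3, k)
        markers = np.zeros(k)
        ll = subject_loglik_given_b(
            p, times, markers, CovariateVector(0, 0, 1e-9), 3.0, 0, np.zeros(2)
        )
        assert ll == pytest.approx(k * np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-6)

    def test_no_association_makes_survival_b_free(self):
        p = simple_params(assoc=(0.0, 0.0))
        cov = CovariateVector(1, 0, 40.0)
        times, markers = np.array([0.0, 1.0]), np.array([4.5, 4.3])
        lls = [
            subject_loglik_given_b(p, times, markers, cov, 2.0, 1, np.array(b))
            for b in [(0.0, 0.0), (1.0, 0.5), (-2.0, 0.1)]
        ]
        surv = event_loglik(p.hazard, cov, 2.0, 1)
        longis = [ll - surv for ll in lls]
        # survival term is constant; only the Gaussian part moves
        for ll, longi in zip(lls, longis):
            assert ll == pytest.approx(longi + surv)

    def test_matches_generic_density_recomputation(self):
        p = simple_params(assoc=(-0.8, -3.0))
        cov = CovariateVector(0, 1, 33.0)
        times = np.array([0.0, 0.6, 1.4])
        markers = np.array([4.9, 4.6, 4.8])
        b = np.array([0.3, -0.05])
        T, delta = 2.5, 1
        expected = norm.logpdf(
            markers,
            loc=trajectory_mean(p, cov, b, times),
            scale=np.sqrt(p.resid_var),
        ).sum() + event_loglik(
            p.hazard, cov, T, delta, extra_log_factor=p.assoc @ b
        )
        got = subject_loglik_given_b(p, times, markers, cov, T, delta, b)
        assert got == pytest.approx(expected, rel=1e-12)


class TestMarginalLoglik:
    def test_factorizes_without_association(self, srem_cohort_small):
        """With alpha4=alpha5=0 the joint likelihood is LMM + Weibull PH."""
        cfg, cohort = srem_cohort_small
        ds = cohort.dataset
        p = simple_params(assoc=(0.0, 0.0))
        arrays = CohortArrays.from_dataset(ds)
        # longitudinal marginal via the exact multivariate normal
        longi = 0.0
        for sid in ds.subjects["subject_id"]:
            m = ds.measurements_for(sid)
            covv = ds.covariates_for(sid).as_array()
            t = m["time"].to_numpy()
            mean = p.beta[0] + covv @ p.beta[1:4] + p.beta[4] * t
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ p.re_cov @ Z.T + p.resid_var * np.eye(len(t))
            longi += multivariate_normal.logpdf(m["marker"].to_numpy(), mean=mean, cov=V)
        surv = event_loglik(p.hazard, arrays.X, arrays.T, arrays.delta).sum()
        assert marginal_loglik(p, ds) == pytest.approx(longi + surv, abs=1e-8)

    def test_matches_monte_carlo(self, srem_cohort_small):
        """Adaptive quadrature agrees with plain MC integration (1e5 draws)."""
        cfg, cohort = srem_cohort_small
        ds = cohort.dataset
        p = cfg.params
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(np.zeros(2), p.re_cov, size=100_000)
        total_mc, var_terms = 0.0, 0.0
        for sid in ds.subjects["subject_id"]:
            m = ds.measurements_for(sid)
            row = ds.subjects[ds.subjects["subject_id"] == sid].iloc[0]
            ll = subject_loglik_given_b(
                p,
                m["time"].to_numpy(),
                m["marker"].to_numpy(),
                ds.covariates_for(sid),
                row["event_time"],
                row["event"],
                draws,
            )
            mx = ll.max()
            w = np.exp(ll - mx)
            total_mc += mx + np.log(w.mean())
            # delta-method SE of log-mean
            var_terms += w.var() / (len(w) * w.mean() ** 2)
        se = np.sqrt(var_terms)
        assert marginal_loglik(p, ds, n_nodes=25) == pytest.approx(total_mc, abs=3 * se)

    def test_node_count_convergence(self, srem_cohort_small):
        cfg, cohort = srem_cohort_small
        p = cfg.params
        v9 = marginal_loglik(p, cohort.dataset, n_nodes=9)
        v15 = marginal_loglik(p, cohort.dataset, n_nodes=15)
        v25 = marginal_loglik(p, cohort.dataset, n_nodes=25)
        assert abs(v15 - v25) <= abs(v9 - v15) + 1e-12

    def test_invariant_to_row_permutation(self, srem_cohort_small):
        cfg, cohort = srem_cohort_small
        ds = cohort.dataset
        rng = np.random.default_rng(1)
        shuffled = ds.measurements.sample(frac=1.0, random_state=2).reset_index(drop=True)
        sub_shuffled = ds.subjects.sample(frac=1.0, random_state=3).reset_index(drop=True)
        from trajsurv.data import JointDataset

        ds2 = JointDataset(sub_shuffled, shuffled, ds.transform)
        assert marginal_loglik(cfg.params, ds2) == pytest.approx(
            marginal_loglik(cfg.params, ds), rel=1e-12
        )


class TestEmpiricalBayes:
    def test_prior_mode_without_data(self):
        p = simple_params(assoc=(-1.0, -3.0))
        mode, curv = empirical_bayes(
            p, [], [], CovariateVector(0, 0, 30.0), s=None, condition_on_survival=False
        )
        assert mode == pytest.approx([0.0, 0.0], abs=1e-12)
        assert np.allclose(curv, np.linalg.inv(p.re_cov))

    def test_small_noise_interpolates_observation(self):
        p = simple_params()
        p.resid_var = 1e-8
        cov = CovariateVector(0, 0, 30.0)
        y_obs = 5.6
        mode, _ = empirical_bayes(p, [0.0], [y_obs], cov, s=None, condition_on_survival=False)
        fitted = trajectory_mean(p, cov, mode, 0.0)
        assert fitted == pytest.approx(y_obs, abs=1e-3)

    def test_matches_grid_search(self, srem_cohort_small):
        cfg, cohort = srem_cohort_small
        ds = cohort.dataset
        p = cfg.params
        sid = ds.subjects["subject_id"].iloc[0]
        m = ds.measurements_for(sid)
        cov = ds.covariates_for(sid)
        s = float(ds.subjects["event_time"].iloc[0])
        mode, _ = empirical_bayes(
            p, m["time"].to_numpy(), m["marker"].to_numpy(), cov, s=s
        )
        # 41x41 lattice around the prior scale
        grid0 = np.linspace(-2.0, 2.0, 41)
        grid1 = np.linspace(-0.3, 0.3, 41)
        keep = m["time"].to_numpy() <= s

        def post(b):
            ll = subject_loglik_given_b(
                p, m["time"].to_numpy()[keep], m["marker"].to_numpy()[keep], cov, s, 0, b
            )
            return ll + multivariate_normal.logpdf(b, mean=np.zeros(2), cov=p.re_cov)

        vals = np.array([[post(np.array([a, c])) for c in grid1] for a in grid0])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        assert mode[0] == pytest.approx(grid0[i], abs=(grid0[1] - grid0[0]))
        assert mode[1] == pytest.approx(grid1[j], abs=(grid1[1] - grid1[0]))


class TestFit:
    def test_constrained_fit_matches_separate_models(self, srem_cohort_small):
        """alpha fixed at 0: joint MLE = separate LMM and Weibull fits."""
        from trajsurv.simulate import default_srem_config, simulate_srem_cohort
        from trajsurv.weibull import fit_weibull_ph

        cfg = default_srem_config(n_subjects=150)
        ds = filter_eligible(simulate_srem_cohort(cfg, 77).dataset, 1).dataset
        fit = fit_srem(ds, fix_assoc=True)
        arrays = CohortArrays.from_dataset(ds)
        wb, wb_ll = fit_weibull_ph(arrays.T, arrays.delta, arrays.X)
        assert fit.params.hazard.shape == pytest.approx(wb.shape, rel=2e-2)
        assert fit.params.hazard.scale == pytest.approx(wb.scale, rel=5e-2)
        # survival part of the factorized loglik matches the separate fit
        surv_ll = event_loglik(fit.params.hazard, arrays.X, arrays.T, arrays.delta).sum()
        assert surv_ll == pytest.approx(wb_ll, abs=0.05)

    def test_init_at_truth_does_not_degrade(self, srem_cohort_small):
        from trajsurv.simulate import default_srem_config, simulate_srem_cohort

        cfg = default_srem_config(n_subjects=120)
        ds = filter_eligible(simulate_srem_cohort(cfg, 55).dataset, 1).dataset
        ll_truth = marginal_loglik(cfg.params, ds)
        fit = fit_srem(ds, init=cfg.params)
        assert fit.loglik >= ll_truth - 1e-6

    def test_pack_unpack_round_trip(self):
        p = simple_params(assoc=(-1.0, -6.4))
        q = _unpack(_pack(p))
        assert np.allclose(q.beta, p.beta)
        assert np.allclose(q.re_cov, p.re_cov)
        assert q.resid_var == pytest.approx(p.resid_var)
        assert np.allclose(q.assoc, p.assoc)

    def test_two_stage_init_is_sane(self, srem_cohort_small):
        cfg, cohort = srem_cohort_small
        init = two_stage_init(cohort.dataset)
        assert init.resid_var > 0
        assert np.linalg.eigvalsh(init.re_cov).min() > 0


def test_association_sign_recovered(srem_replicates):
    """Data generated with negative random-effect loadings yields negative
    fitted loadings in nearly all replicates."""
    truth, fits = srem_replicates
    names = fits[0].param_names
    i4 = list(names).index("assoc_b0")
    signs = [f.theta[i4] < 0 for f in fits]
    assert sum(signs) >= 18
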