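"""Joint latent class model: closed-form likelihood, classification,
score test, parameter counting, BIC and class-number selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from trajsurv.data import CohortArrays, CovariateVector, filter_eligible
from trajsurv.jlcm import (
    ClassPosterior,
    JLCMParams,
    ScoreTestResult,
    _pack,
    _unpack,
    bic,
    canonicalize,
    class_longitudinal_loglik,
    class_membership_probs,
    class_survival_curves,
    class_survival_loglik,
    classification_quality,
    conditional_independence_score_test,
    count_parameters,
    fit_jlcm,
    jlcm_marginal_loglik,
    posterior_class_probs,
    score_test_pvalue,
    select_num_classes,
)
from trajsurv.weibull import WeibullPH, event_loglik

from .conftest import two_class_params


def three_class_params():
    from trajsurv.simulate import default_jlcm_params

    return default_jlcm_params()


class TestMembership:
    def test_uniform_when_all_zero(self):
        p = three_class_params()
        p.membership[:] = 0.0
        probs = class_membership_probs(p, CovariateVector(1, 1, 44.0))
        assert np.allclose(probs, 1 / 3)

    def test_two_class_symmetry(self):
        p = two_class_params()
        p.membership[:] = 0.0
        assert np.allclose(class_membership_probs(p, CovariateVector(0, 0, 30.0)), 0.5)

    def test_reported_coefficients_profile(self):
        """Male, non-addicted, age 40 under the published membership logits:
        eta = (1.211 - 0.070*40, 4.563 - 0.118*40, 0)."""
        p = three_class_params()
        probs = class_membership_probs(p, CovariateVector(0, 0, 40.0))
        eta = np.array([1.211 - 0.070 * 40, 4.563 - 0.118 * 40, 0.0])
        expected = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(probs, expected, atol=1e-12)
        assert probs == pytest.approx([0.0991, 0.4152, 0.4857], abs=2e-4)

    def test_simplex(self):
        p = three_class_params()
        rng = np.random.default_rng(0)
        X = np.column_stack(
            [rng.integers(0, 2, 50), rng.integers(0, 2, 50), rng.normal(38, 8, 50)]
        )
        probs = class_membership_probs(p, X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()


class TestClassLongitudinalLoglik:
    def test_single_measurement_scalar_normal(self):
        p = two_class_params()
        t, y = 1.5, 4.0
        B = p.re_cov
        var = B[0, 0] + 2 * t * B[0, 1] + t**2 * B[1, 1] + p.resid_var
        mean = p.traj_intercepts[0] + p.traj_slopes[0] * t
        expected = -0.5 * (np.log(2 * np.pi * var) + (y - mean) ** 2 / var)
        got = class_longitudinal_loglik(p, [t], [y], CovariateVector(0, 0, 1e-9), 0)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_diagonal_limit_reduces_to_independent_gaussians(self):
        from scipy.stats import norm

        p = two_class_params()
        p.re_cov = np.eye(2) * 1e-12
        cov = CovariateVector(1, 0, 35.0)
        t = np.array([0.0, 1.0, 2.0])
        y = np.array([5.0, 4.7, 4.6])
        mean = p.traj_intercepts[1] + cov.as_array() @ p.traj_common + p.traj_slopes[1] * t
        expected = norm.logpdf(y, mean, np.sqrt(p.resid_var)).sum()
        assert class_longitudinal_loglik(p, t, y, cov, 1) == pytest.approx(
            expected, abs=1e-6
        )

    def test_matches_gauss_hermite_integration(self):
        """Closed form equals numerical integration of the conditional
        likelihood over the random effects."""
        p = two_class_params()
        cov = CovariateVector(0, 1, 42.0)
        t = np.array([0.0, 0.7, 1.3, 2.2])
        y = np.array([3.9, 3.7, 3.2, 3.0])
        x, w = np.polynomial.hermite.hermgauss(80)
        L = np.linalg.cholesky(p.re_cov)
        total = 0.0
        mean0 = p.traj_intercepts[0] + cov.as_array() @ p.traj_common
        for i, xi in enumerate(x):
            for j, xj in enumerate(w):
                b = np.sqrt(2.0) * L @ np.array([xi, x[j]])
                resid = y - (mean0 + b[0] + (p.traj_slopes[0] + b[1]) * t)
                ll = -0.5 * len(t) * np.log(2 * np.pi * p.resid_var) - (
                    resid**2
                ).sum() / (2 * p.resid_var)
                total += w[i] * w[j] * np.exp(ll) / np.pi
        assert class_longitudinal_loglik(p, t, y, cov, 0) == pytest.approx(
            np.log(total), abs=1e-6
        )


class TestClassSurvival:
    class _Rec:
        def __init__(self, T, d):
            self.event_time, self.event = T, d

    def test_reference_class_matches_plain_event_loglik(self):
        p = two_class_params()
        cov = CovariateVector(1, 0, 40.0)
        rec = self._Rec(3.0, 1)
        assert class_survival_loglik(p, rec, cov, 1) == pytest.approx(
            event_loglik(p.hazard, cov, 3.0, 1)
        )

    def test_log2_factor_doubles_cumhaz(self):
        p = two_class_params()
        p.class_log_hazard = np.array([np.log(2.0), 0.0])
        cov = CovariateVector(0, 0, 30.0)
        rec = self._Rec(4.0, 0)
        assert class_survival_loglik(p, rec, cov, 0) == pytest.approx(
            2.0 * class_survival_loglik(p, rec, cov, 1)
        )


class TestMarginalLoglik:
    def test_single_class_equals_srem_without_association(self, srem_cohort_small):
        from trajsurv.srem import SREMParams, marginal_loglik

        cfg, cohort = srem_cohort_small
        ds = cohort.dataset
        sp = cfg.params
        sp0 = SREMParams(
            beta=sp.beta, re_cov=sp.re_cov, resid_var=sp.resid_var,
            hazard=sp.hazard, assoc=np.zeros(2),
        )
        jp = JLCMParams(
            n_classes=1, membership=np.zeros((0, 4)),
            traj_intercepts=[sp.beta[0]], traj_slopes=[sp.beta[4]],
            traj_common=sp.beta[1:4], re_cov=sp.re_cov, resid_var=sp.resid_var,
            hazard=sp.hazard, class_log_hazard=[0.0],
        )
        assert jlcm_marginal_loglik(jp, ds) == pytest.approx(
            marginal_loglik(sp0, ds), abs=1e-6
        )

    def test_label_permutation_invariance(self, srem_cohort_small):
        _, cohort = srem_cohort_small
        ds = cohort.dataset
        p = three_class_params()
        base = jlcm_marginal_loglik(p, ds)
        canon = canonicalize(p)
        assert jlcm_marginal_loglik(canon, ds) == pytest.approx(base, rel=1e-10)
        assert np.all(np.diff(canon.class_log_hazard) <= 1e-12)

    def test_degenerate_membership_selects_single_class(self, srem_cohort_small):
        _, cohort = srem_cohort_small
        ds = cohort.dataset
        p = three_class_params()
        p.membership[0, :] = [50.0, 0.0, 0.0, 0.0]  # class 1 certain
        p.membership[1, :] = 0.0
        arrays = CohortArrays.from_dataset(ds)
        total = 0.0
        for i, sid in enumerate(arrays.ids):
            m = ds.measurements_for(sid)
            cov = ds.covariates_for(sid)

            class _Rec:
                event_time, event = arrays.T[i], arrays.delta[i]

            total += class_longitudinal_loglik(
                p, m["time"].to_numpy(), m["marker"].to_numpy(), cov, 0
            ) + class_survival_loglik(p, _Rec, cov, 0)
        assert jlcm_marginal_loglik(p, ds) == pytest.approx(total, abs=1e-8)


class TestCountingAndBIC:
    @pytest.mark.parametrize("G, expected", [(1, 14), (2, 21), (3, 28), (4, 35)])
    def test_parameter_counts(self, G, expected):
        assert count_parameters(G) == expected

    def test_count_matches_packed_length(self):
        for params, G in [(two_class_params(), 2), (three_class_params(), 3)]:
            assert len(_pack(params)) == count_parameters(G)

    @pytest.mark.parametrize(
        "loglik, P, n, expected",
        [(-1547.86, 14, 213, 3170.77), (-1505.32, 28, 213, 3160.76), (0.0, 0, 5, 0.0)],
    )
    def test_bic_values(self, loglik, P, n, expected):
        assert bic(loglik, P, n) == pytest.approx(expected, abs=0.05)


class TestScoreTestMapping:
    @pytest.mark.parametrize(
        "stat, expected_p",
        [(1.089, 0.5801), (2.092, 0.3513), (0.0, 1.0)],
    )
    def test_chi2_upper_tail(self, stat, expected_p):
        assert score_test_pvalue(stat, df=2) == pytest.approx(expected_p, abs=1e-4)

    def test_result_invariant(self):
        r = ScoreTestResult(statistic=1.089, df=2, p_value=score_test_pvalue(1.089))
        assert r.p_value == pytest.approx(chi2.sf(r.statistic, r.df))


class TestPosteriors:
    def test_single_class_certain(self, srem_cohort_small):
        _, cohort = srem_cohort_small
        p = two_class_params()
        jp = JLCMParams(
            n_classes=1, membership=np.zeros((0, 4)),
            traj_intercepts=p.traj_intercepts[:1], traj_slopes=p.traj_slopes[:1],
            traj_common=p.traj_common, re_cov=p.re_cov, resid_var=p.resid_var,
            hazard=p.hazard, class_log_hazard=[0.0],
        )
        posts = posterior_class_probs(jp, cohort.dataset)
        assert all(np.allclose(q.probabilities, [1.0]) for q in posts)

    def test_classification_quality_arithmetic(self):
        posts = [
            ClassPosterior("a", np.array([0.8, 0.2]), 0),
            ClassPosterior("b", np.array([0.9, 0.1]), 0),
            ClassPosterior("c", np.array([0.3, 0.7]), 1),
        ]
        q = classification_quality(posts)
        assert q.loc[q["class"] == 1, "mean_max_posterior"].iloc[0] == pytest.approx(0.85)
        assert q["proportion_pct"].sum() == pytest.approx(100.0)

    def test_degenerate_posteriors_give_unit_quality(self):
        posts = [ClassPosterior(i, np.array([1.0, 0.0]), 0) for i in range(5)]
        q = classification_quality(posts)
        assert q.loc[q["class"] == 1, "mean_max_posterior"].iloc[0] == 1.0
        assert np.isnan(q.loc[q["class"] == 2, "mean_max_posterior"].iloc[0])


class TestSelection:
    def _mk(self, G, loglik, p_value, n=213):
        from trajsurv._optim import FitResult

        fit = FitResult(
            params=None, loglik=loglik, n_params=count_parameters(G), n_subjects=n,
            converged=True, iterations=1, param_names=[], theta=np.array([]),
            cov=None, standard_errors=None, model_tag="JLCM",
        )
        return (G, fit, ScoreTestResult(0.0 if p_value > 0.5 else 20.0, 2, p_value))

    def test_reported_decision_pattern(self):
        """Lowest BIC has its independence assumption rejected; the next
        candidate with a tenable assumption wins."""
        candidates = [self._mk(2, -1519.09, 1e-4), self._mk(3, -1505.32, 0.5801)]
        sel = select_num_classes(candidates)
        assert sel.chosen_G == 3
        assert not sel.ci_rejected_everywhere

    def test_single_candidate(self):
        sel = select_num_classes([self._mk(2, -1000.0, 0.9)])
        assert sel.chosen_G == 2

    def test_pure_bic_when_no_rejections(self):
        candidates = [self._mk(1, -1547.86, 0.9), self._mk(2, -1519.09, 0.8), self._mk(3, -1505.32, 0.7)]
        assert select_num_classes(candidates).chosen_G == 2

    def test_all_rejected_falls_back_with_warning(self):
        candidates = [self._mk(1, -1547.86, 1e-4), self._mk(2, -1519.09, 1e-4)]
        with pytest.warns(UserWarning, match="rejected"):
            sel = select_num_classes(candidates)
        assert sel.chosen_G == 2
        assert sel.ci_rejected_everywhere


class TestSurvivalCurves:
    def test_start_at_one_and_order_by_hazard(self):
        p = three_class_params()
        t = np.linspace(0, 12, 25)
        curves = class_survival_curves(p, CovariateVector(0, 0, 38.0), t)
        assert np.allclose(curves[:, 0], 1.0)
        assert np.all(np.diff(curves, axis=1) <= 1e-12)
        # higher class log-hazard -> uniformly lower survival after t=0
        assert np.all(curves[0, 1:] < curves[1, 1:])
        assert np.all(curves[1, 1:] < curves[2, 1:])

    def test_pointwise_match_with_survival_prob(self):
        from trajsurv.weibull import survival_prob

        p = two_class_params()
        cov = CovariateVector(1, 1, 45.0)
        t = np.array([0.0, 2.0, 7.5])
        curves = class_survival_curves(p, cov, t)
        for g in range(2):
            expected = survival_prob(p.hazard, cov, t, extra_log_factor=p.class_log_hazard[g])
            assert np.allclose(curves[g], expected)


class TestFitJLCM:
    def test_single_class_fit_factorizes(self):
        from trajsurv.simulate import default_srem_config, simulate_srem_cohort
        from trajsurv.weibull import fit_weibull_ph

        cfg = default_srem_config(n_subjects=150)
        cfg.params.assoc[:] = 0.0
        ds = filter_eligible(simulate_srem_cohort(cfg, 21).dataset, 1).dataset
        fit = fit_jlcm(ds, 1, n_starts=1, seed=0)
        arrays = CohortArrays.from_dataset(ds)
        wb, wb_ll = fit_weibull_ph(arrays.T, arrays.delta, arrays.X)
        surv_ll = event_loglik(fit.params.hazard, arrays.X, arrays.T, arrays.delta).sum()
        assert fit.n_params == 14
        assert surv_ll == pytest.approx(wb_ll, abs=0.05)

    def test_fitted_loglik_dominates_truth(self, jlcm_replicates):
        from trajsurv.jlcm import jlcm_marginal_loglik

        truth_theta, fits = jlcm_replicates
        params = _unpack(truth_theta, 2)
        ok = 0
        for fit, data, _ in fits:
            ok += fit.loglik >= jlcm_marginal_loglik(params, data) - 1e-6
        assert ok >= 18  # MLE property, allowing for rare local-optimum misses

    def test_posterior_classification_accuracy(self, jlcm_replicates):
        _, fits = jlcm_replicates
        fit, data, truth = fits[0]
        posts = posterior_class_probs(fit.params, data)
        tr = truth.set_index("subject_id")["latent_class"]
        acc = np.mean([(q.assigned_class + 1) == tr.loc[q.subject_id] for q in posts])
        assert acc >= 0.90

    def test_canonical_order_high_risk_first(self, jlcm_replicates):
        _, fits = jlcm_replicates
        for fit, _, _ in fits[:5]:
            xi = fit.params.class_log_hazard
            assert np.all(np.diff(xi) <= 1e-12)
            assert xi[-1] == 0.0


def test_score_test_power_under_shared_association():
    """Cohorts generated with strong random-effect loadings: the
    conditional-independence test on a 1-class fit should reject."""
    from trajsurv.simulate import default_srem_config, simulate_srem_cohort

    cfg = default_srem_config(n_subjects=150)
    rejections = 0
    n_rep = 30
    for rep in range(n_rep):
        cohort = simulate_srem_cohort(cfg, 7000 + rep)
        data = filter_eligible(cohort.dataset, 1).dataset
        fit = fit_jlcm(data, 1, n_starts=1, seed=rep, compute_se=False)
        test = conditional_independence_score_test(fit, data)
        rejections += test.p_value < 0.05
    assert rejections / n_rep >= 0.8
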