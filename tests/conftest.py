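"""Shared fixtures: small hand-built datasets plus session-scoped simulation
fit batteries reused across module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from trajsurv.data import JointDataset, filter_eligible, transform_marker  # noqa: E402


def make_dataset(subject_rows, measurement_rows, transform="fourth_root"):
    subjects = pd.DataFrame(
        subject_rows, columns=["subject_id", "event_time", "event", "sex", "addiction", "age"]
    )
    meas = pd.DataFrame(measurement_rows, columns=["subject_id", "time", "marker_raw"])
    meas["marker"] = transform_marker(meas["marker_raw"].to_numpy(), transform)
    return JointDataset(subjects, meas[["subject_id", "time", "marker_raw", "marker"]], transform)


@pytest.fixture
def tiny_dataset():
    """Three subjects with 1, 2 and 5 measurements."""
    subjects = [
        ("A", 2.5, 1, 0, 0, 35.0),
        ("B", 6.0, 0, 1, 0, 42.0),
        ("C", 10.0, 0, 0, 1, 29.0),
    ]
    meas = [("A", 0.0, 350.0)]
    meas += [("B", 0.0, 500.0), ("B", 1.0, 420.0)]
    meas += [("C", float(t) * 0.8, 600.0 - 30.0 * t) for t in range(5)]
    return make_dataset(subjects, meas)


@pytest.fixture(scope="session")
def srem_cohort_small():
    """A 10-subject cohort from the shared-random-effect generator."""
    from trajsurv.simulate import default_srem_config, simulate_srem_cohort

    cfg = default_srem_config(n_subjects=10)
    return cfg, simulate_srem_cohort(cfg, 3)


@pytest.fixture(scope="session")
def srem_replicates():
    """20 replicate SREM fits on n=500 cohorts from the default truth.

    Fitting keeps every subject (min_measurements=1: all have a baseline
    visit) so the maximum likelihood estimator is unbiased by design.
    Returns (true theta, list of FitResults).
    """
    from trajsurv.simulate import default_srem_config, simulate_srem_cohort
    from trajsurv.srem import _pack, fit_srem

    cfg = default_srem_config(n_subjects=500)
    truth = _pack(cfg.params)
    fits = []
    for rep in range(20):
        cohort = simulate_srem_cohort(cfg, 100 + rep)
        data = filter_eligible(cohort.dataset, 1).dataset
        fits.append(fit_srem(data))
    return truth, fits


def two_class_params():
    """A well-separated 2-class truth used for JLCM recovery.

    Designed so every parameter is comfortably estimable at n=600: the
    declining class stays far above the zero floor of the transformed
    marker over the whole follow-up window, and the hazard sex effect is
    moderate so that cohorts always contain events in both sexes (no
    monotone-likelihood divergence).
    """
    from trajsurv.jlcm import JLCMParams
    from trajsurv.weibull import WeibullPH

    return JLCMParams(
        n_classes=2,
        membership=np.array([[-0.5, 0.0, 0.0, 0.0]]),
        traj_intercepts=np.array([4.5, 5.5]),
        traj_slopes=np.array([-0.25, -0.02]),
        traj_common=np.array([0.204, -0.176, -0.016]),
        re_cov=np.array([[0.16, -0.008], [-0.008, 0.004]]),
        resid_var=0.10,
        hazard=WeibullPH(shape=1.1, scale=40.0, coefficients=np.array([-1.0, -0.341, 0.021])),
        class_log_hazard=np.array([1.6, 0.0]),
    )


@pytest.fixture(scope="session")
def jlcm_replicates():
    """20 replicate 2-class JLCM fits on n=600 separated cohorts."""
    from trajsurv.jlcm import _pack, fit_jlcm
    from trajsurv.simulate import SimulationConfig, simulate_jlcm_cohort

    params = two_class_params()
    truth = _pack(params)
    fits = []
    truths_cls = []
    for rep in range(20):
        cfg = SimulationConfig(generator="JLCM", params=params, n_subjects=600)
        cohort = simulate_jlcm_cohort(cfg, 200 + rep)
        data = filter_eligible(cohort.dataset, 1).dataset
        fits.append((fit_jlcm(data, 2, n_starts=2, seed=rep), data, cohort.truth))
        truths_cls.append(cohort.truth)
    return truth, fits


@pytest.fixture(scope="session")
def null_score_tests():
    """Score tests on 200 single-class null cohorts (no residual association)."""
    from trajsurv.jlcm import conditional_independence_score_test, fit_jlcm
    from trajsurv.simulate import default_srem_config, simulate_srem_cohort

    cfg = default_srem_config(n_subjects=150)
    cfg.params.assoc[:] = 0.0  # conditional independence holds (G=1, no loadings)
    pvals = []
    for rep in range(200):
        cohort = simulate_srem_cohort(cfg, 300 + rep)
        data = filter_eligible(cohort.dataset, 1).dataset
        fit = fit_jlcm(data, 1, n_starts=1, seed=rep, compute_se=False)
        test = conditional_independence_score_test(fit, data)
        pvals.append(test.p_value)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def selection_battery():
    """G = 1..4 JLCM fits on 20 separated 3-class cohorts (n=600).

    Returns a list of dicts per cohort: dataset, truth table, and
    {G: FitResult}.  Reused by BIC-selection, nested-loglik and AUC
    comparison checks.
    """
    from trajsurv.jlcm import fit_jlcm
    from trajsurv.simulate import separated_jlcm_config, simulate_jlcm_cohort

    out = []
    for rep in range(20):
        cfg = separated_jlcm_config(n_subjects=600)
        cohort = simulate_jlcm_cohort(cfg, 500 + rep)
        data = filter_eligible(cohort.dataset, 1).dataset
        fits = {
            G: fit_jlcm(
                data, G, n_starts=3, seed=rep, compute_se=False,
                polish=False, presolve_maxiter=300,
            )
            for G in (1, 2, 3, 4)
        }
        out.append({"data": data, "truth": cohort.truth, "fits": fits, "config": cfg})
    return out
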