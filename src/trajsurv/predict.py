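"""Individual dynamic risk prediction.

For a subject who is event-free at a landmark time s, the dynamic risk is
the probability of the event in the window (s, s+t], conditional on the
biomarker history up to s and on survival to s.

JLCM: closed form — a posterior-weighted mixture of class-conditional
window risks, the weights combining the prior membership, the class
longitudinal likelihood of the history and class survival to s.

SREM: the window risk averaged over the posterior of the random effects
given the history and survival to s, computed by adaptive Gauss-Hermite
quadrature (default) or plugged in at the posterior mode (fast option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import CohortArrays, JointDataset
from .jlcm import JLCMParams, _longi_loglik_matrix, _membership_logits
from .srem import SREMParams, _Kernel
from .weibull import _cov_array

DEFAULT_LANDMARKS = np.arange(1.0, 8.0 + 1e-9, 0.5)  # 15 landmark times (years)
DEFAULT_WINDOW = 3.0  # years


@dataclass(frozen=True)
class DynamicPrediction:
    subject_id: object
    landmark: float
    window: float
    risk: float
    model_tag: str
    n_history: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.risk <= 1.0 + 1e-12):
            raise ValueError("risk must lie in [0, 1]")


def _restrict_history(times, markers, s):
    times = np.asarray(times, dtype=float)
    markers = np.asarray(markers, dtype=float)
    keep = times <= s
    return times[keep], markers[keep]


def _single_subject_arrays(times, markers, covariates, T, delta) -> CohortArrays:
    times = np.asarray(times, dtype=float)
    markers = np.asarray(markers, dtype=float)
    return CohortArrays(
        ids=np.array(["_"]),
        k=np.array([float(len(times))]),
        St=np.array([times.sum()]),
        Stt=np.array([(times**2).sum()]),
        Sy=np.array([markers.sum()]),
        Sty=np.array([(times * markers).sum()]),
        Syy=np.array([(markers**2).sum()]),
        X=np.atleast_2d(_cov_array(covariates)),
        T=np.array([float(T)]),
        delta=np.array([float(delta)]),
    )


# ---------------------------------------------------------------------------
# JLCM


def _jlcm_risks(params: JLCMParams, arrays: CohortArrays, s: float, t: float) -> np.ndarray:
    """Vectorized window risks for every subject row in ``arrays``.

    Risk-set membership (alive at s) is the caller's responsibility; arrays
    must hold measurement statistics restricted to times <= s.
    """
    if t < 0 or s < 0:
        raise ValueError("landmark and window must be non-negative")
    hz = params.hazard
    lp = arrays.X @ hz.coefficients  # (n,)
    xi = params.class_log_hazard  # (G,)
    Lam_s = np.power(s / hz.scale, hz.shape) * np.exp(lp[:, None] + xi[None, :])
    Lam_st = np.power((s + t) / hz.scale, hz.shape) * np.exp(lp[:, None] + xi[None, :])
    logS_s = -Lam_s
    eta = _membership_logits(params, arrays.X)
    logpi = eta - logsumexp(eta, axis=1, keepdims=True)
    logfY = _longi_loglik_matrix(params, arrays)
    logw = logpi + logfY + logS_s
    logw = logw - logsumexp(logw, axis=1, keepdims=True)
    cond_risk = 1.0 - np.exp(-(Lam_st - Lam_s))  # [S_g(s) - S_g(s+t)] / S_g(s)
    return np.clip((np.exp(logw) * cond_risk).sum(axis=1), 0.0, 1.0)


def jlcm_dynamic_risk(params: JLCMParams, times, markers, covariates, s: float, t: float) -> float:
    """Closed-form dynamic risk under the latent class model.

    Weights w_g(s) combine prior membership, the longitudinal likelihood of
    the history up to s, and class-specific survival to s; the risk is the
    weighted average of class-conditional window risks.  An empty history is
    allowed (weights reduce to pi_g * S_g(s)).
    """
    times, markers = _restrict_history(times, markers, s)
    arrays = _single_subject_arrays(times, markers, covariates, T=max(s, 1e-12), delta=0)
    return float(_jlcm_risks(params, arrays, s, t)[0])


# ---------------------------------------------------------------------------
# SREM


def _srem_kernel_at_landmark(params: SREMParams, arrays: CohortArrays, horizon: float) -> _Kernel:
    """Posterior kernel of b given measurement stats and survival to ``horizon``.

    Longitudinal residual statistics + N(0,B) prior + the censored-at-horizon
    survival term -Lambda0(horizon)*exp(alpha'x)*exp(assoc.b).
    """
    beta = params.beta
    a = beta[0] + arrays.X @ beta[1:4]
    c = beta[4]
    Sr = arrays.Sy - a * arrays.k - c * arrays.St
    Str = arrays.Sty - a * arrays.St - c * arrays.Stt
    hz = params.hazard
    lp = arrays.X @ hz.coefficients
    if horizon > 0:
        logLw = hz.shape * (np.log(horizon) - np.log(hz.scale)) + lp
    else:
        logLw = np.full(arrays.n, -np.inf)
    return _Kernel(
        Sr=Sr,
        Str=Str,
        k=arrays.k,
        St=arrays.St,
        Stt=arrays.Stt,
        sigma2=params.resid_var,
        B=params.re_cov,
        assoc=params.assoc,
        d=np.zeros(arrays.n),
        logLw=logLw,
        const=np.zeros(arrays.n),
    )


def _srem_risks(
    params: SREMParams,
    arrays: CohortArrays,
    s: float,
    t: float,
    method: str = "quadrature",
    n_nodes: int = 9,
) -> np.ndarray:
    """Vectorized SREM window risks: 1 - E[S(s+t|b)/S(s|b) | history, T > s]."""
    if t < 0 or s < 0:
        raise ValueError("landmark and window must be non-negative")
    if t == 0:
        return np.zeros(arrays.n)
    kern_s = _srem_kernel_at_landmark(params, arrays, horizon=s)
    if method == "posterior_mode":
        mode, _ = kern_s.modes()
        hz = params.hazard
        lp = arrays.X @ hz.coefficients + params.assoc @ mode.T
        dLam = (np.power((s + t) / hz.scale, hz.shape) - np.power(s / hz.scale, hz.shape)) * np.exp(lp)
        return np.clip(1.0 - np.exp(-dLam), 0.0, 1.0)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    kern_st = _srem_kernel_at_landmark(params, arrays, horizon=s + t)
    logD, modes = kern_s.log_integrals(n_nodes=n_nodes)
    logN, _ = kern_st.log_integrals(n_nodes=n_nodes, b_init=modes)
    return np.clip(1.0 - np.exp(logN - logD), 0.0, 1.0)


def srem_dynamic_risk(
    params: SREMParams,
    times,
    markers,
    covariates,
    s: float,
    t: float,
    method: str = "quadrature",
    n_nodes: int = 9,
) -> float:
    """Dynamic risk under the shared random-effect model.

    The posterior of b conditions on both the marker history up to s and on
    being event-free at s.  ``method='quadrature'`` (default) integrates the
    window risk over that posterior with adaptive Gauss-Hermite nodes;
    ``method='posterior_mode'`` plugs in the posterior mode.
    """
    times, markers = _restrict_history(times, markers, s)
    arrays = _single_subject_arrays(times, markers, covariates, T=max(s, 1e-12), delta=0)
    return float(_srem_risks(params, arrays, s, t, method=method, n_nodes=n_nodes)[0])


# ---------------------------------------------------------------------------
# batched predictions


def batch_dynamic_predictions(
    fit_or_params,
    dataset: JointDataset,
    landmarks=DEFAULT_LANDMARKS,
    window: float = DEFAULT_WINDOW,
    method: str = "quadrature",
    n_nodes: int = 9,
) -> pd.DataFrame:
    """One risk per (subject alive at s) x landmark, as a tidy DataFrame.

    Subjects whose event/censoring time is <= s are excluded at that
    landmark (an event at exactly s leaves the risk set; a measurement at
    exactly s is part of the history).  Landmarks with an empty risk set are
    skipped with a warning.
    """
    params = getattr(fit_or_params, "params", fit_or_params)
    if isinstance(params, JLCMParams):
        tag = "JLCM"
    elif isinstance(params, SREMParams):
        tag = "SREM"
    else:
        raise TypeError("expected a fitted SREM or JLCM (FitResult or params)")
    rows = []
    for s in np.asarray(landmarks, dtype=float):
        alive = dataset.subjects["event_time"] > s
        if not alive.any():
            warnings.warn(f"no subjects at risk at landmark s={s}; skipped", stacklevel=2)
            continue
        sub = JointDataset(
            dataset.subjects[alive],
            dataset.measurements[
                dataset.measurements["subject_id"].isin(dataset.subjects.loc[alive, "subject_id"])
            ],
            transform=dataset.transform,
        )
        arrays = CohortArrays.from_dataset(sub, max_time=s)
        if tag == "JLCM":
            risks = _jlcm_risks(params, arrays, s, window)
        else:
            risks = _srem_risks(params, arrays, s, window, method=method, n_nodes=n_nodes)
        for sid, r, k in zip(arrays.ids, risks, arrays.k):
            rows.append(
                {
                    "subject_id": sid,
                    "model": tag,
                    "s": s,
                    "t": window,
                    "risk": float(r),
                    "n_history": int(k),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "model", "s", "t", "risk", "n_history"])
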