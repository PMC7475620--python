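"""Shared random-effect joint model (SREM).

The longitudinal sub-model is a linear mixed model on the transformed
biomarker,

    Y_i(t) = beta0 + beta1*sex + beta2*addiction + beta3*age
             + b_i0 + (beta4 + b_i1) * t + eps,   (b_i0, b_i1) ~ N(0, B),

and the survival sub-model is a Weibull proportional-hazards model whose
log hazard is shifted by the same random effects,

    lambda_i(t) = lambda0(t) exp(alpha1*sex + alpha2*addiction + alpha3*age
                                 + alpha4*b_i0 + alpha5*b_i1).

Because the association term is constant in time, the conditional
log-likelihood given b is (quadratic in b) + (linear in b) - (convex
exponential of a linear form), hence strictly concave: each subject's
posterior mode is found by a globally safe damped Newton, and the marginal
likelihood is evaluated by adaptive Gauss-Hermite quadrature centered and
scaled at that mode.  With alpha4 = alpha5 = 0 the log-integrand is exactly
quadratic and the quadrature is exact for any node count.

All per-subject quantities reduce to the sufficient statistics in
:class:`trajsurv.data.CohortArrays`, so a likelihood evaluation is a handful
of vectorized array operations regardless of cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from ._optim import FitResult, covariance_from_hessian, marquardt_maximize
from .data import CohortArrays, JointDataset
from .weibull import WeibullPH, _cov_array, fit_weibull_ph

LOG2PI = np.log(2.0 * np.pi)
_EXP_CLIP = 700.0

PARAM_NAMES_SREM = [
    "beta_intercept",
    "beta_sex",
    "beta_addiction",
    "beta_age",
    "beta_time",
    "log_chol_b00",
    "chol_b10",
    "log_chol_b11",
    "log_resid_sd",
    "log_weibull_shape",
    "log_weibull_scale",
    "alpha_sex",
    "alpha_addiction",
    "alpha_age",
    "assoc_b0",
    "assoc_b1",
]

N_PARAMS_SREM = len(PARAM_NAMES_SREM)


@dataclass
class SREMParams:
    """Parameters of the shared random-effect joint model.

    ``beta`` is ordered (intercept, sex, addiction, age, time-slope) on the
    transformed-marker scale; ``re_cov`` is the 2x2 covariance B of the
    random intercept and slope; ``assoc`` holds (alpha4, alpha5), the
    log-hazard loadings of (b0, b1).
    """

    beta: np.ndarray
    re_cov: np.ndarray
    resid_var: float
    hazard: WeibullPH
    assoc: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        self.assoc = np.asarray(self.assoc, dtype=float)
        if self.beta.shape != (5,):
            raise ValueError("beta must have 5 entries (intercept, sex, addiction, age, time)")
        if self.re_cov.shape != (2, 2) or np.linalg.eigvalsh(self.re_cov).min() <= 0:
            raise ValueError("re_cov must be 2x2 positive definite")
        if not self.resid_var > 0:
            raise ValueError("resid_var must be positive")


def _pack(params: SREMParams) -> np.ndarray:
    L = np.linalg.cholesky(params.re_cov)
    return np.concatenate(
        [
            params.beta,
            [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])],
            [0.5 * np.log(params.resid_var)],
            [np.log(params.hazard.shape), np.log(params.hazard.scale)],
            params.hazard.coefficients,
            params.assoc,
        ]
    )


def _unpack(theta: np.ndarray) -> SREMParams:
    theta = np.asarray(theta, dtype=float)
    L = np.array([[np.exp(theta[5]), 0.0], [theta[6], np.exp(theta[7])]])
    return SREMParams(
        beta=theta[:5],
        re_cov=L @ L.T,
        resid_var=float(np.exp(2 * theta[8])),
        hazard=WeibullPH(
            shape=float(np.exp(theta[9])),
            scale=float(np.exp(theta[10])),
            coefficients=theta[11:14],
        ),
        assoc=theta[14:16],
    )


def trajectory_mean(params: SREMParams, covariates, b, t):
    """Subject mean trajectory m(t) given random effects b = (b0, b1)."""
    x = _cov_array(covariates)
    b = np.asarray(b, dtype=float)
    base = params.beta[0] + x @ params.beta[1:4]
    return base + b[..., 0] + (params.beta[4] + b[..., 1]) * np.asarray(t, dtype=float)


def subject_loglik_given_b(params: SREMParams, times, markers, covariates, event_time, event, b):
    """Conditional log-likelihood of one subject's data given b.

    Sum of Gaussian log-densities of the measurement residuals (variance
    sigma^2) plus the Weibull PH event contribution with log-hazard offset
    alpha4*b0 + alpha5*b1.  ``b`` may be (2,) or a stack (..., 2); the prior
    on b is *not* included.
    """
    times = np.asarray(times, dtype=float)
    markers = np.asarray(markers, dtype=float)
    b = np.asarray(b, dtype=float)
    mean = trajectory_mean(params, covariates, b[..., None, :], times)
    resid = markers - mean
    s2 = params.resid_var
    longi = (-0.5 * (LOG2PI + np.log(s2)) - resid**2 / (2 * s2)).sum(axis=-1)
    from .weibull import event_loglik

    elf = params.assoc[0] * b[..., 0] + params.assoc[1] * b[..., 1]
    surv = event_loglik(params.hazard, covariates, event_time, event, extra_log_factor=elf)
    return longi + surv


@lru_cache(maxsize=None)
def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Hermite grid in 2D: nodes (Q, 2), log-weights (Q,)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.array([[a, c] for a in x for c in x])
    logw = np.array([np.log(wa) + np.log(wc) for wa in w for wc in w])
    return z, logw


class _Kernel:
    """Vectorized per-subject log-integrand h(b) = conditional loglik + log prior.

    Parameterized by quadratic longitudinal coefficients, a linear
    association term d*(a.b) and a convex survival term -Lw*exp(a.b), plus
    the N(0,B) prior.  Shapes: all coefficient arrays (n,).
    """

    def __init__(self, Sr, Str, k, St, Stt, sigma2, B, assoc, d, logLw, const):
        self.Sr, self.Str = Sr, Str
        self.k, self.St, self.Stt = k, St, Stt
        self.sigma2 = sigma2
        self.Binv = np.linalg.inv(B)
        self.logdetB = float(np.linalg.slogdet(B)[1])
        self.a = np.asarray(assoc, dtype=float)
        self.d = d
        self.logLw = logLw  # log(Lambda0(T) * exp(alpha'x)); -inf allowed (no survival term)
        self.const = const
        self.n = len(Sr)

    def h(self, b):
        """b: (n, 2) or (n, Q, 2) -> h values (n,) or (n, Q)."""
        b0, b1 = b[..., 0], b[..., 1]
        extra = b.ndim - 2  # broadcasting axes beyond subject
        def _e(x):
            return x.reshape(x.shape + (1,) * extra) if extra else x
        s2 = self.sigma2
        lin = (_e(self.Sr) * b0 + _e(self.Str) * b1) / s2
        quad = (_e(self.k) * b0**2 + 2 * _e(self.St) * b0 * b1 + _e(self.Stt) * b1**2) / (2 * s2)
        ab = self.a[0] * b0 + self.a[1] * b1
        lam = np.exp(np.clip(_e(self.logLw) + ab, None, _EXP_CLIP))
        prior = 0.5 * (
            self.Binv[0, 0] * b0**2 + 2 * self.Binv[0, 1] * b0 * b1 + self.Binv[1, 1] * b1**2
        )
        return _e(self.const) + lin - quad + _e(self.d) * ab - lam - prior - LOG2PI - 0.5 * self.logdetB

    def _grad_hess(self, b):
        b0, b1 = b[..., 0], b[..., 1]
        s2 = self.sigma2
        ab = self.a[0] * b0 + self.a[1] * b1
        lam = np.exp(np.clip(self.logLw + ab, None, _EXP_CLIP))
        g0 = (self.Sr - self.k * b0 - self.St * b1) / s2 + (self.d - lam) * self.a[0] - (
            self.Binv[0, 0] * b0 + self.Binv[0, 1] * b1
        )
        g1 = (self.Str - self.St * b0 - self.Stt * b1) / s2 + (self.d - lam) * self.a[1] - (
            self.Binv[0, 1] * b0 + self.Binv[1, 1] * b1
        )
        H00 = -self.k / s2 - self.Binv[0, 0] - lam * self.a[0] ** 2
        H01 = -self.St / s2 - self.Binv[0, 1] - lam * self.a[0] * self.a[1]
        H11 = -self.Stt / s2 - self.Binv[1, 1] - lam * self.a[1] ** 2
        return np.stack([g0, g1], axis=-1), (H00, H01, H11)

    def modes(self, b_init: np.ndarray | None = None, max_iter: int = 60, tol: float = 1e-10):
        """Damped Newton posterior modes for all subjects simultaneously."""
        if b_init is None or not np.all(np.isfinite(b_init)):
            b = np.zeros((self.n, 2))
        else:
            b = b_init.copy()
        hb = self.h(b)
        for _ in range(max_iter):
            g, (H00, H01, H11) = self._grad_hess(b)
            det = H00 * H11 - H01**2
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                step0 = -(H11 * g[:, 0] - H01 * g[:, 1]) / det
                step1 = -(-H01 * g[:, 0] + H00 * g[:, 1]) / det
            step = np.nan_to_num(np.stack([step0, step1], axis=-1), nan=0.0, posinf=0.0, neginf=0.0)
            scale = np.ones(self.n)
            for _half in range(25):
                b_new = b + scale[:, None] * step
                h_new = self.h(b_new)
                bad = h_new < hb - 1e-12
                if not bad.any():
                    break
                scale[bad] *= 0.5
            moved = np.max(np.abs(scale[:, None] * step))
            b, hb = b_new, np.maximum(h_new, hb)
            if moved < tol:
                break
        g, (H00, H01, H11) = self._grad_hess(b)
        return b, (H00, H01, H11)

    def log_integrals(self, n_nodes: int = 9, b_init: np.ndarray | None = None):
        """log integral of exp(h(b)) db per subject, by adaptive Gauss-Hermite."""
        mode, (H00, H01, H11) = self.modes(b_init=b_init)
        # Sigma = (-H)^{-1}; Cholesky of 2x2 in closed form
        det = H00 * H11 - H01**2
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            S00, S01, S11 = -H11 / det, H01 / det, -H00 / det
            L00 = np.sqrt(S00)
            L10 = S01 / L00
            L11 = np.sqrt(np.maximum(S11 - L10**2, 1e-300))
        z, logw = _gh_nodes(n_nodes)
        # b_q = mode + sqrt(2) * L z
        bq = np.empty((self.n, len(z), 2))
        bq[:, :, 0] = mode[:, None, 0] + np.sqrt(2.0) * L00[:, None] * z[None, :, 0]
        bq[:, :, 1] = mode[:, None, 1] + np.sqrt(2.0) * (
            L10[:, None] * z[None, :, 0] + L11[:, None] * z[None, :, 1]
        )
        hq = self.h(bq)
        zz = (z**2).sum(axis=1)
        logdetL = np.log(L00) + np.log(L11)
        vals = logsumexp(logw[None, :] + zz[None, :] + hq, axis=1)
        return np.log(2.0) + logdetL + vals, mode


def _kernel_for_loglik(params: SREMParams, arrays: CohortArrays) -> _Kernel:
    beta = params.beta
    a = beta[0] + arrays.X @ beta[1:4]
    c = beta[4]
    Sr = arrays.Sy - a * arrays.k - c * arrays.St
    Str = arrays.Sty - a * arrays.St - c * arrays.Stt
    Srr = (
        arrays.Syy
        - 2 * a * arrays.Sy
        - 2 * c * arrays.Sty
        + a**2 * arrays.k
        + 2 * a * c * arrays.St
        + c**2 * arrays.Stt
    )
    s2 = params.resid_var
    hz = params.hazard
    lp = arrays.X @ hz.coefficients
    logLam0 = hz.shape * (np.log(arrays.T) - np.log(hz.scale))
    log_h0 = np.log(hz.shape / hz.scale) + (hz.shape - 1.0) * (np.log(arrays.T) - np.log(hz.scale))
    const = (
        -0.5 * arrays.k * (LOG2PI + np.log(s2))
        - Srr / (2 * s2)
        + arrays.delta * (log_h0 + lp)
    )
    return _Kernel(
        Sr=Sr,
        Str=Str,
        k=arrays.k,
        St=arrays.St,
        Stt=arrays.Stt,
        sigma2=s2,
        B=params.re_cov,
        assoc=params.assoc,
        d=arrays.delta,
        logLw=logLam0 + lp,
        const=const,
    )


def marginal_loglik(
    params: SREMParams,
    data: JointDataset | CohortArrays,
    n_nodes: int = 9,
    _mode_cache: dict | None = None,
) -> float:
    """Marginal log-likelihood: sum_i log int exp(loglik_i(b)) N(b; 0, B) db.

    Adaptive Gauss-Hermite quadrature with ``n_nodes`` per dimension,
    centered at each subject's conditional mode.  Deterministic for a fixed
    node count.
    """
    arrays = data if isinstance(data, CohortArrays) else CohortArrays.from_dataset(data)
    kern = _kernel_for_loglik(params, arrays)
    b_init = None if _mode_cache is None else _mode_cache.get("modes")
    vals, modes = kern.log_integrals(n_nodes=n_nodes, b_init=b_init)
    if _mode_cache is not None and np.all(np.isfinite(modes)):
        _mode_cache["modes"] = modes
    total = vals.sum()
    return float(total) if np.isfinite(total) else -np.inf


def empirical_bayes(
    params: SREMParams,
    times,
    markers,
    covariates,
    s: float | None = None,
    condition_on_survival: bool = True,
):
    """Posterior mode and curvature of b given one subject's history up to s.

    The posterior combines the measurement likelihood (restricted to times
    <= s when ``s`` is given), the prior N(0, B) and — when
    ``condition_on_survival`` — the probability of remaining event-free to
    s.  Returns (mode (2,), curvature (2,2)) with curvature the negative
    Hessian of the log-posterior at the mode (positive definite).
    """
    times = np.asarray(times, dtype=float)
    markers = np.asarray(markers, dtype=float)
    if s is not None:
        keep = times <= s
        times, markers = times[keep], markers[keep]
    x = _cov_array(covariates)
    beta = params.beta
    a = beta[0] + x @ beta[1:4]
    resid = markers - a - beta[4] * times
    Sr = np.array([resid.sum()])
    Str = np.array([(times * resid).sum()])
    k = np.array([float(len(times))])
    St = np.array([times.sum()])
    Stt = np.array([(times**2).sum()])
    if condition_on_survival and s is not None and s > 0:
        hz = params.hazard
        logLw = np.array([hz.shape * (np.log(s) - np.log(hz.scale)) + x @ hz.coefficients])
    else:
        logLw = np.array([-np.inf])
    kern = _Kernel(
        Sr=Sr,
        Str=Str,
        k=k,
        St=St,
        Stt=Stt,
        sigma2=params.resid_var,
        B=params.re_cov,
        assoc=params.assoc,
        d=np.zeros(1),
        logLw=logLw,
        const=np.zeros(1),
    )
    mode, (H00, H01, H11) = kern.modes()
    curvature = -np.array([[H00[0], H01[0]], [H01[0], H11[0]]])
    return mode[0], curvature


def two_stage_init(dataset: JointDataset) -> SREMParams:
    """Default initialization: pooled OLS for the longitudinal part, per-subject
    lines for the variance components, covariates-only Weibull PH for the
    survival part, association at zero."""
    meas = dataset.measurements.merge(
        dataset.subjects[["subject_id", "sex", "addiction", "age"]], on="subject_id"
    )
    D = np.column_stack(
        [
            np.ones(len(meas)),
            meas["sex"],
            meas["addiction"],
            meas["age"],
            meas["time"],
        ]
    )
    beta, *_ = np.linalg.lstsq(D, meas["marker"].to_numpy(), rcond=None)

    arrays = CohortArrays.from_dataset(dataset)
    denom = arrays.k * arrays.Stt - arrays.St**2
    ok = (arrays.k >= 2) & (denom > 1e-10)
    slope = np.where(ok, (arrays.k * arrays.Sty - arrays.St * arrays.Sy) / np.where(ok, denom, 1.0), beta[4])
    inter = np.where(arrays.k > 0, (arrays.Sy - slope * arrays.St) / np.maximum(arrays.k, 1.0), beta[0])
    b0 = inter - (beta[0] + arrays.X @ beta[1:4])
    b1 = slope - beta[4]
    B = np.cov(np.vstack([b0[ok], b1[ok]])) if ok.sum() >= 3 else np.diag([0.3, 0.01])
    w, V = np.linalg.eigh(B)
    B = (V * np.maximum(w, 1e-4)) @ V.T
    # pooled residual variance around the per-subject lines
    rss = (
        arrays.Syy
        - 2 * inter * arrays.Sy
        - 2 * slope * arrays.Sty
        + inter**2 * arrays.k
        + 2 * inter * slope * arrays.St
        + slope**2 * arrays.Stt
    )
    dof = np.maximum(arrays.k[ok].sum() - 2 * ok.sum(), 1.0)
    s2 = max(float(rss[ok].sum() / dof), 1e-3)
    hz, _ = fit_weibull_ph(arrays.T, arrays.delta, arrays.X)
    return SREMParams(beta=beta, re_cov=B, resid_var=s2, hazard=hz, assoc=np.zeros(2))


def fit_srem(
    dataset: JointDataset,
    init: SREMParams | None = None,
    n_nodes: int = 9,
    fix_assoc: bool = False,
    max_iter: int = 25,
    presolve_maxiter: int = 400,
) -> FitResult:
    """Maximum-likelihood SREM fit.

    ``fix_assoc`` constrains alpha4 = alpha5 = 0, in which case the joint
    likelihood factorizes into a linear mixed model and a Weibull PH model.
    Non-convergence is flagged on the result, not raised.
    """
    arrays = CohortArrays.from_dataset(dataset)
    if init is None:
        init = two_stage_init(dataset)
    theta0 = _pack(init)
    free = np.arange(N_PARAMS_SREM)
    if fix_assoc:
        free = free[:-2]
        theta0 = theta0.copy()
        theta0[-2:] = 0.0
    cache: dict = {}

    def make_f(nodes):
        def f(sub_theta):
            theta = theta0.copy()
            theta[free] = sub_theta
            try:
                return marginal_loglik(_unpack(theta), arrays, n_nodes=nodes, _mode_cache=cache)
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf

        return f

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # coarse-node presolve locates the optimum cheaply; the adaptive
        # quadrature is node-insensitive near the mode, so the fine-node
        # phase only has to polish
        coarse = min(5, n_nodes)
        start = theta0[free]
        if coarse < n_nodes:
            from scipy import optimize as _opt

            pre = _opt.minimize(
                lambda x: -make_f(coarse)(x),
                start,
                method="L-BFGS-B",
                options={"maxiter": presolve_maxiter, "maxcor": 25},
            )
            start = pre.x
            presolve_maxiter = 80
        res = marquardt_maximize(
            make_f(n_nodes), start, max_iter=max_iter, presolve_maxiter=presolve_maxiter
        )
    theta = theta0.copy()
    theta[free] = res.theta
    cov_sub, se_sub = covariance_from_hessian(res.hessian)
    cov = None
    se = None
    if cov_sub is not None:
        cov = np.zeros((N_PARAMS_SREM, N_PARAMS_SREM))
        cov[np.ix_(free, free)] = cov_sub
        se = np.zeros(N_PARAMS_SREM)
        se[free] = se_sub
    return FitResult(
        params=_unpack(theta),
        loglik=res.fmax,
        n_params=len(free),
        n_subjects=arrays.n,
        converged=res.converged,
        iterations=res.iterations,
        param_names=PARAM_NAMES_SREM,
        theta=theta,
        cov=cov,
        standard_errors=se,
        model_tag="SREM",
    )
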