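"""Joint latent class model (JLCM).

The population is a finite mixture of G latent classes.  Class membership
follows a multinomial logistic model on baseline covariates (last class is
the reference); within class g the biomarker follows a linear mixed model
with class-specific intercept and time slope (covariate effects and the
random-effect covariance B are common across classes); the hazard is
Weibull proportional hazards with common covariate effects and a
class-specific proportional factor xi_g (xi_G = 0).  Conditional on class,
the biomarker and the event time are independent, so each class-conditional
likelihood is available in closed form (the random effects integrate out of
the longitudinal normal analytically) and the mixture log-likelihood is
exact — no numerical integration.

The conditional-independence assumption is testable: the score test adds
random-effect loadings gamma to the within-class hazard and tests gamma = 0
with an efficient (Rao) score statistic, chi-square with df = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from ._optim import FitResult, covariance_from_hessian, marquardt_maximize, num_gradient
from .data import CohortArrays, JointDataset
from .weibull import WeibullPH, _cov_array, fit_weibull_ph

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class JLCMParams:
    """Parameters of the joint latent class model.

    ``membership``: (G-1, 4) rows (intercept, sex, addiction, age) of the
    multinomial logit, class G reference.  ``traj_intercepts`` /
    ``traj_slopes``: length G.  ``traj_common``: (sex, addiction, age)
    effects shared across classes.  ``class_log_hazard``: length G with the
    last entry 0 (proportional class-specific baselines).
    """

    n_classes: int
    membership: np.ndarray
    traj_intercepts: np.ndarray
    traj_slopes: np.ndarray
    traj_common: np.ndarray
    re_cov: np.ndarray
    resid_var: float
    hazard: WeibullPH
    class_log_hazard: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        G = self.n_classes
        self.membership = np.asarray(self.membership, dtype=float).reshape(G - 1, 4)
        self.traj_intercepts = np.asarray(self.traj_intercepts, dtype=float)
        self.traj_slopes = np.asarray(self.traj_slopes, dtype=float)
        self.traj_common = np.asarray(self.traj_common, dtype=float)
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        self.class_log_hazard = np.asarray(self.class_log_hazard, dtype=float)
        if G < 1:
            raise ValueError("n_classes must be >= 1")
        if self.traj_intercepts.shape != (G,) or self.traj_slopes.shape != (G,):
            raise ValueError("traj_intercepts and traj_slopes must have length G")
        if self.class_log_hazard.shape != (G,) or abs(self.class_log_hazard[-1]) > 1e-12:
            raise ValueError("class_log_hazard must have length G with reference entry 0")
        if np.linalg.eigvalsh(self.re_cov).min() <= 0:
            raise ValueError("re_cov must be positive definite")
        if not self.resid_var > 0:
            raise ValueError("resid_var must be positive")


@dataclass
class ClassPosterior:
    subject_id: object
    probabilities: np.ndarray
    assigned_class: int  # 0-based index

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-10 or (p < 0).any():
            raise ValueError("posterior probabilities must form a simplex")
        self.probabilities = p


class ScoreTestResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def count_parameters(
    G: int,
    n_membership_cov: int = 3,
    n_long_cov: int = 3,
    n_surv_cov: int = 3,
) -> int:
    """Free-parameter count of the default JLCM structure.

    Per non-reference class: (1 + membership covariates) logit coefficients
    plus one proportional log-hazard factor; per class: trajectory intercept
    and slope; shared: common longitudinal covariate effects, 3 free entries
    of B, residual variance, 2 Weibull parameters, survival covariate
    effects.  Default structure gives 14 + 7*(G-1).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    return (
        (1 + n_membership_cov) * (G - 1)
        + 2 * G
        + n_long_cov
        + 3
        + 1
        + 2
        + n_surv_cov
        + (G - 1)
    )


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian information criterion: -2*loglik + P*log(n); lower is better."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * (np.log(n_subjects) if n_params else 0.0)


# ---------------------------------------------------------------------------
# likelihood machinery


def _membership_logits(params: JLCMParams, X: np.ndarray) -> np.ndarray:
    """(n, G) logits with the reference class fixed at 0."""
    X = np.atleast_2d(X)
    G = params.n_classes
    eta = np.zeros((X.shape[0], G))
    for g in range(G - 1):
        m = params.membership[g]
        eta[:, g] = m[0] + X @ m[1:]
    return eta


def class_membership_probs(params: JLCMParams, covariates) -> np.ndarray:
    """Multinomial-logistic prior class probabilities pi_g(x); sums to 1."""
    x = _cov_array(covariates)
    single = x.ndim == 1
    eta = _membership_logits(params, np.atleast_2d(x))
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    return p[0] if single else p


def _longi_loglik_matrix(params: JLCMParams, arrays: CohortArrays) -> np.ndarray:
    """(n, G) class-conditional longitudinal log-likelihoods, closed form.

    The marginal covariance of a subject's measurement vector is
    V = Z B Z' + sigma^2 I (Z columns 1 and t); by Woodbury/determinant
    lemmas everything reduces to the 2x2 matrix M = sigma^2 B^{-1} + Z'Z,
    which depends on the subject only — the class moves only the mean.
    """
    G = params.n_classes
    s2 = params.resid_var
    B = params.re_cov
    Binv = np.linalg.inv(B)
    # subject-level pieces
    M00 = s2 * Binv[0, 0] + arrays.k
    M01 = s2 * Binv[0, 1] + arrays.St
    M11 = s2 * Binv[1, 1] + arrays.Stt
    detM = M00 * M11 - M01**2
    # log det V = k log s2 + log det(M) - log det(s2 * Binv)
    logdet_s2Binv = 2 * np.log(s2) + float(np.linalg.slogdet(Binv)[1])
    logdetV = arrays.k * np.log(s2) + np.log(detM) - logdet_s2Binv

    xcommon = arrays.X @ params.traj_common  # (n,)
    out = np.empty((arrays.n, G))
    for g in range(G):
        a = params.traj_intercepts[g] + xcommon
        c = params.traj_slopes[g]
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
        # u' M^{-1} u with u = (Sr, Str)
        quadM = (M11 * Sr**2 - 2 * M01 * Sr * Str + M00 * Str**2) / detM
        Q = (Srr - quadM) / s2
        out[:, g] = -0.5 * (arrays.k * LOG2PI + logdetV + Q)
    return out


def class_longitudinal_loglik(params: JLCMParams, times, markers, covariates, g: int) -> float:
    """Closed-form log-density of one subject's measurements given class g."""
    times = np.asarray(times, dtype=float)
    markers = np.asarray(markers, dtype=float)
    x = _cov_array(covariates)
    mean = (
        params.traj_intercepts[g]
        + x @ params.traj_common
        + params.traj_slopes[g] * times
    )
    Z = np.column_stack([np.ones_like(times), times])
    V = Z @ params.re_cov @ Z.T + params.resid_var * np.eye(len(times))
    resid = markers - mean
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular longitudinal covariance")
    return float(
        -0.5 * (len(times) * LOG2PI + logdet + resid @ np.linalg.solve(V, resid))
    )


def _surv_loglik_matrix(params: JLCMParams, arrays: CohortArrays) -> np.ndarray:
    """(n, G) class-conditional Weibull PH log-likelihood contributions."""
    hz = params.hazard
    lp = arrays.X @ hz.coefficients
    logT = np.log(arrays.T)
    log_h0 = np.log(hz.shape / hz.scale) + (hz.shape - 1.0) * (logT - np.log(hz.scale))
    logLam0 = hz.shape * (logT - np.log(hz.scale))
    xi = params.class_log_hazard
    return arrays.delta[:, None] * (log_h0[:, None] + lp[:, None] + xi[None, :]) - np.exp(
        logLam0[:, None] + lp[:, None] + xi[None, :]
    )


def class_survival_loglik(params: JLCMParams, survival_record, covariates, g: int) -> float:
    """Event log-likelihood for class g: PH with extra log factor xi_g."""
    from .weibull import event_loglik

    return float(
        event_loglik(
            params.hazard,
            covariates,
            survival_record.event_time,
            survival_record.event,
            extra_log_factor=params.class_log_hazard[g],
        )
    )


def _joint_log_terms(params: JLCMParams, arrays: CohortArrays) -> np.ndarray:
    """(n, G): log pi_ig + log f_Y(i|g) + log f_T(i|g)."""
    eta = _membership_logits(params, arrays.X)
    logpi = eta - logsumexp(eta, axis=1, keepdims=True)
    return logpi + _longi_loglik_matrix(params, arrays) + _surv_loglik_matrix(params, arrays)


def jlcm_marginal_loglik(params: JLCMParams, data: JointDataset | CohortArrays) -> float:
    """Exact mixture log-likelihood (log-sum-exp over classes)."""
    arrays = data if isinstance(data, CohortArrays) else CohortArrays.from_dataset(data)
    return float(logsumexp(_joint_log_terms(params, arrays), axis=1).sum())


def posterior_class_probs(
    params: JLCMParams, data: JointDataset | CohortArrays
) -> list[ClassPosterior]:
    """P(c_i = g | Y_i, T_i, delta_i, x_i), normalized per subject."""
    arrays = data if isinstance(data, CohortArrays) else CohortArrays.from_dataset(data)
    terms = _joint_log_terms(params, arrays)
    logpost = terms - logsumexp(terms, axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return [
        ClassPosterior(sid, p, int(np.argmax(p))) for sid, p in zip(arrays.ids, post)
    ]


def classification_quality(posteriors: Sequence[ClassPosterior]) -> pd.DataFrame:
    """Per-class mean maximal posterior probability and class proportions (%).

    Classes with no assigned subjects get NaN quality and 0 proportion.
    """
    if not posteriors:
        raise ValueError("no posteriors supplied")
    G = len(posteriors[0].probabilities)
    assigned = np.array([p.assigned_class for p in posteriors])
    maxp = np.array([p.probabilities[p.assigned_class] for p in posteriors])
    rows = []
    for g in range(G):
        mask = assigned == g
        rows.append(
            {
                "class": g + 1,
                "n_assigned": int(mask.sum()),
                "proportion_pct": 100.0 * mask.mean(),
                "mean_max_posterior": float(maxp[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def class_survival_curves(params: JLCMParams, covariates, times) -> np.ndarray:
    """(G, len(times)) class-specific survival curves for a covariate profile."""
    from .weibull import survival_prob

    times = np.asarray(times, dtype=float)
    return np.vstack(
        [
            survival_prob(params.hazard, covariates, times, extra_log_factor=xi)
            for xi in params.class_log_hazard
        ]
    )


# ---------------------------------------------------------------------------
# packing and fitting


def _param_names(G: int) -> list[str]:
    names = []
    for g in range(G - 1):
        names += [
            f"memb{g + 1}_intercept",
            f"memb{g + 1}_sex",
            f"memb{g + 1}_addiction",
            f"memb{g + 1}_age",
        ]
    names += [f"traj_intercept_c{g + 1}" for g in range(G)]
    names += [f"traj_slope_c{g + 1}" for g in range(G)]
    names += ["traj_sex", "traj_addiction", "traj_age"]
    names += ["log_chol_b00", "chol_b10", "log_chol_b11", "log_resid_sd"]
    names += ["log_weibull_shape", "log_weibull_scale"]
    names += ["alpha_sex", "alpha_addiction", "alpha_age"]
    names += [f"class_log_hazard_c{g + 1}" for g in range(G - 1)]
    return names


def _pack(params: JLCMParams) -> np.ndarray:
    L = np.linalg.cholesky(params.re_cov)
    return np.concatenate(
        [
            params.membership.ravel(),
            params.traj_intercepts,
            params.traj_slopes,
            params.traj_common,
            [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), 0.5 * np.log(params.resid_var)],
            [np.log(params.hazard.shape), np.log(params.hazard.scale)],
            params.hazard.coefficients,
            params.class_log_hazard[:-1],
        ]
    )


def _unpack(theta: np.ndarray, G: int) -> JLCMParams:
    theta = np.asarray(theta, dtype=float)
    i = 0
    membership = theta[i : i + 4 * (G - 1)].reshape(G - 1, 4)
    i += 4 * (G - 1)
    intercepts = theta[i : i + G]
    i += G
    slopes = theta[i : i + G]
    i += G
    common = theta[i : i + 3]
    i += 3
    L = np.array([[np.exp(theta[i]), 0.0], [theta[i + 1], np.exp(theta[i + 2])]])
    s2 = float(np.exp(2 * theta[i + 3]))
    i += 4
    hz = WeibullPH(
        shape=float(np.exp(theta[i])),
        scale=float(np.exp(theta[i + 1])),
        coefficients=theta[i + 2 : i + 5],
    )
    i += 5
    xi = np.concatenate([theta[i : i + G - 1], [0.0]])
    return JLCMParams(
        n_classes=G,
        membership=membership,
        traj_intercepts=intercepts,
        traj_slopes=slopes,
        traj_common=common,
        re_cov=L @ L.T,
        resid_var=s2,
        hazard=hz,
        class_log_hazard=xi,
    )


def canonicalize(params: JLCMParams) -> JLCMParams:
    """Reorder classes by descending class log-hazard (highest risk first).

    The reference class (xi = 0) moves with the permutation; the common
    baseline absorbs the new reference's factor through the Weibull scale
    so that xi_G = 0 is preserved and the likelihood is unchanged.
    """
    G = params.n_classes
    if G == 1:
        return params
    order = np.argsort(-params.class_log_hazard, kind="stable")
    xi = params.class_log_hazard[order]
    shift = xi[-1]
    xi = xi - shift
    # absorb the shift into the baseline scale: Lambda0'(t) = Lambda0(t)*e^shift
    new_scale = params.hazard.scale * np.exp(-shift / params.hazard.shape)
    # membership logits under the new reference class
    eta_full = np.vstack([params.membership, np.zeros((1, 4))])  # (G, 4)
    eta_perm = eta_full[order]
    membership = eta_perm[:-1] - eta_perm[-1]
    return JLCMParams(
        n_classes=G,
        membership=membership,
        traj_intercepts=params.traj_intercepts[order],
        traj_slopes=params.traj_slopes[order],
        traj_common=params.traj_common,
        re_cov=params.re_cov,
        resid_var=params.resid_var,
        hazard=replace(params.hazard, scale=float(new_scale)),
        class_log_hazard=xi,
    )


def _subject_slopes(arrays: CohortArrays, fallback: float) -> tuple[np.ndarray, np.ndarray]:
    denom = arrays.k * arrays.Stt - arrays.St**2
    ok = (arrays.k >= 2) & (denom > 1e-10)
    slope = np.where(ok, (arrays.k * arrays.Sty - arrays.St * arrays.Sy) / np.where(ok, denom, 1.0), fallback)
    inter = np.where(arrays.k > 0, (arrays.Sy - slope * arrays.St) / np.maximum(arrays.k, 1.0), np.nan)
    return inter, slope


def _start_features(dataset: JointDataset, arrays: CohortArrays):
    """Per-subject trajectory features for structured starts.

    Per-subject OLS slopes from 2-3 close visits are wildly noisy, so they
    are shrunk toward the pooled slope with precision weights and winsorized
    before clustering.
    """
    from .srem import two_stage_init

    base = two_stage_init(dataset)
    beta = base.beta
    inter_i, slope_i = _subject_slopes(arrays, beta[4])
    inter_f = np.where(np.isfinite(inter_i), inter_i, np.nanmean(inter_i))
    denom = np.maximum(arrays.k * arrays.Stt - arrays.St**2, 0.0)
    lam = np.median(denom[denom > 0]) if (denom > 0).any() else 1.0
    slope_s = (denom * slope_i + lam * beta[4]) / np.maximum(denom + lam, 1e-12)
    feats = np.column_stack([inter_f, slope_s])
    lo, hi = np.percentile(feats, [2, 98], axis=0)
    feats = np.clip(feats, lo, hi)
    return base, inter_f, slope_s, feats


def _grouping_candidates(feats: np.ndarray, G: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Distinct structured partitions: 2D k-means on (level, slope), level
    quantile bands, and slope quantile bands."""
    groups = []
    std = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
    from scipy.cluster.vq import kmeans2

    _, km = kmeans2(std, G, minit="++", seed=rng, iter=20)
    groups.append(km)
    for col in (0, 1):
        qs = np.quantile(feats[:, col], np.linspace(0, 1, G + 1))
        groups.append(np.clip(np.searchsorted(qs[1:-1], feats[:, col], side="right"), 0, G - 1))
    return groups


def _initial_params(
    dataset: JointDataset,
    arrays: CohortArrays,
    G: int,
    rng: np.random.Generator,
    jitter: float,
    group: np.ndarray | None = None,
    features=None,
) -> JLCMParams:
    """Data-driven start from a subject partition (k-means by default)."""
    base, inter_f, slope_s, feats = (
        features if features is not None else _start_features(dataset, arrays)
    )
    beta = base.beta
    if group is None:
        if G > 1:
            group = _grouping_candidates(feats, G, rng)[0]
        else:
            group = np.zeros(arrays.n, dtype=int)
    # order groups by mean slope (steepest decline = highest risk = first)
    if G > 1:
        order = np.argsort(
            [slope_s[group == g].mean() if (group == g).any() else np.inf for g in range(G)]
        )
        group = np.argsort(order)[group]
    intercepts = np.empty(G)
    slopes = np.empty(G)
    xi = np.empty(G)
    memb_int = np.empty(G - 1)
    covadj = arrays.X @ beta[1:4]
    for g in range(G):
        m = group == g
        if m.sum() == 0:
            intercepts[g], slopes[g] = beta[0], beta[4]
            xi[g] = 0.0
            continue
        intercepts[g] = np.nanmean(inter_f[m] - covadj[m]) if np.isfinite(inter_f[m]).any() else beta[0]
        slopes[g] = slope_s[m].mean()
        rate = (arrays.delta[m].sum() + 0.5) / max(arrays.T[m].sum(), 1e-6)
        xi[g] = np.log(rate)
    xi = xi - xi[-1]
    for g in range(G - 1):
        n_g = max((group == g).sum(), 1)
        n_ref = max((group == G - 1).sum(), 1)
        memb_int[g] = np.log(n_g / n_ref)
    membership = np.zeros((G - 1, 4))
    membership[:, 0] = memb_int
    # random-effect covariance from *within-group* deviations: the pooled
    # (single-class) estimate absorbs the between-class variance and lets
    # random effects wash out the class structure
    if G > 1:
        dev0 = inter_f - covadj - intercepts[group]
        dev1 = slope_s - slopes[group]
        B0 = np.cov(np.vstack([dev0, dev1]))
        w, V = np.linalg.eigh(B0)
        re_cov = (V * np.maximum(w, 1e-4)) @ V.T
    else:
        re_cov = base.re_cov
    params = JLCMParams(
        n_classes=G,
        membership=membership,
        traj_intercepts=intercepts,
        traj_slopes=slopes,
        traj_common=beta[1:4],
        re_cov=re_cov,
        resid_var=base.resid_var,
        hazard=base.hazard,
        class_log_hazard=np.concatenate([xi[:-1], [0.0]]),
    )
    if jitter > 0:
        th = _pack(params)
        scale = jitter * (1.0 + np.abs(th))
        # jitter only the class-specific blocks
        mask = np.zeros_like(th)
        mask[: 4 * (G - 1)] = 1.0
        mask[4 * (G - 1) : 4 * (G - 1) + 2 * G] = 1.0
        if G > 1:
            mask[-(G - 1) :] = 1.0
        th = th + mask * rng.normal(scale=scale)
        params = _unpack(th, G)
    return params


def fit_jlcm(
    dataset: JointDataset,
    G: int,
    n_starts: int = 10,
    seed: int = 0,
    init: JLCMParams | None = None,
    max_iter: int = 25,
    presolve_maxiter: int = 400,
    compute_se: bool = True,
    polish: bool = True,
) -> FitResult:
    """Maximum-likelihood JLCM fit with multiple structured starts.

    Candidate starts partition subjects by k-means on per-subject
    (level, slope) features, by level quantiles and by slope quantiles;
    further starts jitter the class-specific blocks (seeded).  Each start
    gets a short quasi-Newton run; the most promising are optimized fully
    and the best local maximum is reported with classes in canonical order
    (descending class log-hazard).  If every start fails to converge the
    best flagged result is still returned.
    """
    arrays = CohortArrays.from_dataset(dataset)
    rng = np.random.default_rng(seed)
    starts: list[JLCMParams] = []
    if init is not None:
        starts.append(init)
    n_data_starts = max(n_starts - len(starts), 0)
    if n_data_starts > 0:
        features = _start_features(dataset, arrays)
        if G == 1:
            starts.append(_initial_params(dataset, arrays, G, rng, 0.0, features=features))
        else:
            groups = _grouping_candidates(features[3], G, rng)
            for group in groups[:n_data_starts]:
                starts.append(
                    _initial_params(dataset, arrays, G, rng, 0.0, group=group, features=features)
                )
            while len(starts) < n_starts:
                starts.append(
                    _initial_params(
                        dataset, arrays, G, rng, jitter=0.15,
                        group=groups[len(starts) % len(groups)], features=features,
                    )
                )
    if G == 1 and init is None:
        starts = starts[:1]  # single-class likelihood is unimodal in practice

    def f(theta):
        try:
            return jlcm_marginal_loglik(_unpack(theta, G), arrays)
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if len(starts) > 1:
            # short-run ranking: cheap quasi-Newton pass per start
            from scipy import optimize as _opt

            short = []
            for p0 in starts:
                pre = _opt.minimize(
                    lambda x: -f(x), _pack(p0), method="L-BFGS-B",
                    options={"maxiter": 60, "maxcor": 25},
                )
                short.append((-pre.fun, pre.x))
            short.sort(key=lambda t: -t[0])
            n_final = max(2, len(starts) // 4) if polish else 1
            finalists = [x for _, x in short[:n_final]]
        else:
            finalists = [_pack(starts[0])]
        for x0 in finalists:
            if polish:
                res = marquardt_maximize(
                    f, x0, max_iter=max_iter, presolve_maxiter=presolve_maxiter
                )
            else:
                # quasi-Newton only: adequate when only the maximized
                # log-likelihood is needed (e.g. BIC enumeration)
                from scipy import optimize as _opt
                from ._optim import OptimResult

                pre = _opt.minimize(
                    lambda x: -f(x), x0, method="L-BFGS-B",
                    options={"maxiter": presolve_maxiter, "maxcor": 25},
                )
                res = OptimResult(
                    theta=pre.x, fmax=-pre.fun, converged=bool(pre.success),
                    iterations=int(pre.nit), gradient=pre.jac, hessian=None,
                )
            if best is None or res.fmax > best.fmax:
                best = res
    params = canonicalize(_unpack(best.theta, G))
    theta = _pack(params)
    cov = se = None
    if compute_se:
        from ._optim import num_hessian

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H = num_hessian(f, theta)
        cov, se = covariance_from_hessian(H)
    return FitResult(
        params=params,
        loglik=best.fmax,
        n_params=count_parameters(G),
        n_subjects=arrays.n,
        converged=best.converged,
        iterations=best.iterations,
        param_names=_param_names(G),
        theta=theta,
        cov=cov,
        standard_errors=se,
        model_tag="JLCM",
    )


# ---------------------------------------------------------------------------
# conditional-independence score test


def _blups(params: JLCMParams, arrays: CohortArrays) -> np.ndarray:
    """(n, G, 2) empirical-Bayes means E[b | Y_i, c_i = g]."""
    s2 = params.resid_var
    B = params.re_cov
    Binv = np.linalg.inv(B)
    M00 = s2 * Binv[0, 0] + arrays.k
    M01 = s2 * Binv[0, 1] + arrays.St
    M11 = s2 * Binv[1, 1] + arrays.Stt
    detM = M00 * M11 - M01**2
    xcommon = arrays.X @ params.traj_common
    G = params.n_classes
    out = np.empty((arrays.n, G, 2))
    for g in range(G):
        a = params.traj_intercepts[g] + xcommon
        c = params.traj_slopes[g]
        Sr = arrays.Sy - a * arrays.k - c * arrays.St
        Str = arrays.Sty - a * arrays.St - c * arrays.Stt
        # Z'V^{-1} r = (u - Z'Z M^{-1} u) / s2; then E[b|Y,g] = B Z'V^{-1} r
        Minv_u0 = (M11 * Sr - M01 * Str) / detM
        Minv_u1 = (-M01 * Sr + M00 * Str) / detM
        v0 = (Sr - (arrays.k * Minv_u0 + arrays.St * Minv_u1)) / s2
        v1 = (Str - (arrays.St * Minv_u0 + arrays.Stt * Minv_u1)) / s2
        out[:, g, 0] = B[0, 0] * v0 + B[0, 1] * v1
        out[:, g, 1] = B[1, 0] * v0 + B[1, 1] * v1
    return out


def _gamma_scores(params: JLCMParams, arrays: CohortArrays) -> np.ndarray:
    """(n, 2) per-subject scores of the hazard random-effect loadings at gamma=0.

    d/dgamma log L_i = sum_g w_ig * (delta_i - Lambda_ig(T_i)) * E[b | Y_i, g],
    with w_ig the posterior class probabilities: the product of each class's
    martingale residual with its empirical-Bayes random-effect mean.
    """
    terms = _joint_log_terms(params, arrays)
    w = np.exp(terms - logsumexp(terms, axis=1, keepdims=True))
    hz = params.hazard
    lp = arrays.X @ hz.coefficients
    logLam0 = hz.shape * (np.log(arrays.T) - np.log(hz.scale))
    Lam = np.exp(logLam0[:, None] + lp[:, None] + params.class_log_hazard[None, :])
    mart = arrays.delta[:, None] - Lam  # (n, G)
    blup = _blups(params, arrays)  # (n, G, 2)
    return np.einsum("ng,ng,ngj->nj", w, mart, blup)


def _theta_scores(params: JLCMParams, arrays: CohortArrays, rel_step: float = 1e-5) -> np.ndarray:
    """(n, P) numerically differenced per-subject scores of the model parameters.

    Central differences, falling back to one-sided steps when a perturbed
    parameter vector is invalid (a fit on the boundary — e.g. slope
    variance at its floor — can make the covariance numerically singular
    on one side).
    """
    G = params.n_classes
    theta = _pack(params)
    P = len(theta)

    def _terms(th):
        try:
            return logsumexp(_joint_log_terms(_unpack(th, G), arrays), axis=1)
        except (ValueError, np.linalg.LinAlgError):
            return None

    f0 = None
    out = np.empty((arrays.n, P))
    for j in range(P):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        lp, lm = _terms(tp), _terms(tm)
        if lp is not None and lm is not None:
            out[:, j] = (lp - lm) / (2 * h)
            continue
        if f0 is None:
            f0 = _terms(theta)
            if f0 is None:
                raise np.linalg.LinAlgError("invalid parameters in score computation")
        if lp is not None:
            out[:, j] = (lp - f0) / h
        elif lm is not None:
            out[:, j] = (f0 - lm) / h
        else:
            out[:, j] = 0.0
    return out


def conditional_independence_score_test(
    fit: FitResult, data: JointDataset | CohortArrays
) -> ScoreTestResult:
    """Efficient score test of conditional independence given the latent classes.

    H0: the random effects carry no residual information about the hazard
    within classes (their hazard loadings gamma are zero).  The statistic is
    U' V^{-1} U with U the total gamma-score at the fitted null model and V
    the empirical efficient information (outer-product information with the
    estimated-parameter block projected out); chi-square reference with
    df = 2 (one per random effect).
    """
    params: JLCMParams = fit.params
    arrays = data if isinstance(data, CohortArrays) else CohortArrays.from_dataset(data)
    u = _gamma_scores(params, arrays)  # (n, 2)
    s = _theta_scores(params, arrays)  # (n, P)
    U = u.sum(axis=0)
    J_gg = u.T @ u
    J_gt = u.T @ s
    J_tt = s.T @ s
    # pseudo-inverses guard against rank deficiency at degenerate fits
    # (e.g. a nearly empty class leaves its block of the information flat)
    V = J_gg - J_gt @ np.linalg.pinv(J_tt, rcond=1e-10) @ J_gt.T
    # outer-product information is biased low in small samples; apply the
    # standard n/(n - k) degrees-of-freedom correction (k = estimated
    # parameters + tested loadings)
    n, k = arrays.n, s.shape[1] + u.shape[1]
    if n > k:
        V = V * (n / (n - k))
    Vinv = np.linalg.pinv(V, rcond=1e-10)
    if not np.all(np.isfinite(Vinv)):
        raise np.linalg.LinAlgError(
            "singular information matrix in conditional-independence score test"
        )
    stat = float(U @ Vinv @ U)
    if stat < 0:
        stat = 0.0
    df = 2
    return ScoreTestResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def score_test_pvalue(statistic: float, df: int = 2) -> float:
    """Upper-tail chi-square probability of a score statistic."""
    if statistic < 0:
        raise ValueError("score statistic must be non-negative")
    return float(chi2.sf(statistic, df))


# ---------------------------------------------------------------------------
# class-number selection


class SelectionResult(NamedTuple):
    chosen_G: int
    trace: pd.DataFrame
    ci_rejected_everywhere: bool


def select_num_classes(
    candidates: Sequence[tuple[int, FitResult, ScoreTestResult]],
    alpha: float = 0.05,
) -> SelectionResult:
    """Choose the class number: lowest BIC among candidates whose
    conditional-independence test is not rejected (p >= alpha); if every
    candidate is rejected, fall back to the overall BIC minimum with a
    warning flag.  The trace records every candidate's BIC and p-value.
    """
    if not candidates:
        raise ValueError("no candidate fits supplied")
    rows = []
    for G, fit, test in candidates:
        rows.append(
            {
                "G": G,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": bic(fit.loglik, fit.n_params, fit.n_subjects),
                "score_stat": test.statistic if test is not None else np.nan,
                "score_p": test.p_value if test is not None else np.nan,
                "converged": fit.converged,
            }
        )
    trace = pd.DataFrame(rows)
    ok = trace["score_p"] >= alpha
    if ok.any():
        chosen = int(trace.loc[ok, "bic"].idxmin())
        rejected = False
    else:
        chosen = int(trace["bic"].idxmin())
        rejected = True
        warnings.warn(
            "conditional independence rejected for every candidate; "
            "returning the BIC minimum",
            stacklevel=2,
        )
    return SelectionResult(int(trace.loc[chosen, "G"]), trace, rejected)
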