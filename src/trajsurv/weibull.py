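"""Weibull proportional-hazards machinery shared by both joint-model families.

Parameterization: baseline hazard ``lambda0(t) = (rho/sigma_w) * (t/sigma_w)**(rho-1)``
so the baseline cumulative hazard is ``Lambda0(t) = (t/sigma_w)**rho`` — shape
``rho`` dimensionless, scale ``sigma_w`` in years.  (Rate parameterizations
``lambda0(t) = rho * lam**rho * t**(rho-1)`` convert via ``lam = 1/sigma_w``.)
The log hazard is shifted by a covariate linear predictor plus an
``extra_log_factor`` that houses the shared-random-effect association term
(alpha4*b0 + alpha5*b1) in one family and the latent-class factor xi_g in the
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .data import CovariateVector


def _cov_array(covariates) -> np.ndarray:
    if isinstance(covariates, CovariateVector):
        return covariates.as_array()
    return np.asarray(covariates, dtype=float)


@dataclass
class WeibullPH:
    """Weibull proportional-hazards model with a free additive log-hazard offset."""

    shape: float  # rho > 0
    scale: float  # sigma_w > 0 (years)
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(3))  # (sex, addiction, age)
    extra_log_factor: float = 0.0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Weibull shape and scale must be positive")
        self.coefficients = np.asarray(self.coefficients, dtype=float)


def baseline_hazard(model: WeibullPH, t):
    t = np.asarray(t, dtype=float)
    return (model.shape / model.scale) * np.power(t / model.scale, model.shape - 1.0)


def baseline_cumhaz(model: WeibullPH, t):
    """Lambda0(t) = (t/sigma_w)**rho; 0 at t=0, non-decreasing."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.power(t / model.scale, model.shape)
    return float(out) if out.ndim == 0 else out


def linear_predictor(model: WeibullPH, covariates):
    X = _cov_array(covariates)
    return X @ model.coefficients


def survival_prob(model: WeibullPH, covariates, t, extra_log_factor=None):
    """S(t) = exp(-Lambda0(t) * exp(alpha'w + extra_log_factor)), in (0, 1]."""
    elf = model.extra_log_factor if extra_log_factor is None else extra_log_factor
    lp = linear_predictor(model, covariates) + elf
    out = np.exp(-baseline_cumhaz(model, t) * np.exp(lp))
    return float(out) if np.ndim(out) == 0 else out


def event_loglik(model: WeibullPH, covariates, event_time, event, extra_log_factor=None):
    """PH likelihood contribution: event*log(lambda(T)) - Lambda(T).  Vectorized."""
    elf = model.extra_log_factor if extra_log_factor is None else extra_log_factor
    T = np.asarray(event_time, dtype=float)
    if np.any(T <= 0):
        raise ValueError("event_time must be positive")
    delta = np.asarray(event, dtype=float)
    lp = linear_predictor(model, covariates) + elf
    log_haz = np.log(baseline_hazard(model, T)) + lp
    cumhaz = baseline_cumhaz(model, T) * np.exp(lp)
    out = delta * log_haz - cumhaz
    return float(out) if np.ndim(out) == 0 else out


def martingale_residuals(model: WeibullPH, X, event_time, event, extra_log_factor=None):
    """r_i = delta_i - fitted cumulative hazard at T_i (each r_i <= 1)."""
    elf = model.extra_log_factor if extra_log_factor is None else extra_log_factor
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lp = X @ model.coefficients + elf
    cumhaz = baseline_cumhaz(model, np.asarray(event_time, dtype=float)) * np.exp(lp)
    return np.asarray(event, dtype=float) - cumhaz


def fit_weibull_ph(event_time, event, X, init: WeibullPH | None = None):
    """Maximum-likelihood Weibull PH fit (covariates only, no frailty).

    Optimizes over (log shape, log scale, coefficients) with L-BFGS-B.
    Returns (model, loglik).  Used both standalone and to initialize the
    joint fits.
    """
    T = np.asarray(event_time, dtype=float)
    delta = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]

    if init is None:
        # exponential-rate moment start, covariates at zero
        rate = max(delta.sum(), 0.5) / T.sum()
        x0 = np.concatenate([[0.0, -np.log(rate)], np.zeros(p)])
    else:
        x0 = np.concatenate(
            [[np.log(init.shape), np.log(init.scale)], np.asarray(init.coefficients, float)]
        )

    def nll(theta):
        rho, sw = np.exp(theta[0]), np.exp(theta[1])
        lp = X @ theta[2:]
        logh = np.log(rho / sw) + (rho - 1.0) * np.log(T / sw) + lp
        cum = np.power(T / sw, rho) * np.exp(lp)
        return -(delta * logh - cum).sum()

    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    model = WeibullPH(
        shape=float(np.exp(res.x[0])), scale=float(np.exp(res.x[1])), coefficients=res.x[2:]
    )
    return model, -float(res.fun)


def with_offset(model: WeibullPH, extra_log_factor: float) -> WeibullPH:
    return replace(model, extra_log_factor=extra_log_factor)
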