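"""Shared optimization utilities: numeric derivatives, a Levenberg-Marquardt
damped Newton maximizer, and the FitResult container.

Both joint likelihoods are smooth but have no convenient analytic
derivatives, so gradients and Hessians are central finite differences with
relative step sizes.  The maximizer warm-starts with L-BFGS-B (cheap
quasi-Newton phase) and finishes with damped Newton steps; convergence
requires all three of: relative log-likelihood change, parameter change, and
the scaled gradient criterion g' H^{-1} g / P below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize


def num_gradient(f: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def num_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((p, p))
    f0 = f(x)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * h[i] * h[j])
    return H


@dataclass
class OptimResult:
    theta: np.ndarray
    fmax: float
    converged: bool
    iterations: int
    gradient: np.ndarray
    hessian: np.ndarray  # Hessian of the maximized function (negative definite at a max)


def marquardt_maximize(
    f: Callable,
    x0: np.ndarray,
    max_iter: int = 30,
    tol_f: float = 1e-5,
    tol_x: float = 1e-4,
    tol_g: float = 1e-3,
    presolve_maxiter: int = 300,
) -> OptimResult:
    """Maximize ``f`` by L-BFGS-B presolve + LM-damped Newton polish."""
    x0 = np.asarray(x0, dtype=float)
    pre = optimize.minimize(
        lambda x: -f(x),
        x0,
        method="L-BFGS-B",
        options={"maxiter": presolve_maxiter, "maxcor": 25},
    )
    x = pre.x
    fx = -pre.fun
    lam = 1e-3
    converged = False
    it = 0
    p = len(x)

    def _gcrit(g, H):
        try:
            val = float(g @ np.linalg.solve(-H, g)) / p
            return val if val >= 0 else np.inf
        except np.linalg.LinAlgError:
            return np.inf

    g = num_gradient(f, x)
    H = num_hessian(f, x)
    ftol_noise = 1e-9 * (1.0 + abs(fx))
    for it in range(1, max_iter + 1):
        A = -H + lam * np.eye(p)
        # ensure the damped system is positive definite
        try:
            w = np.linalg.eigvalsh(A)
            if w.min() <= 0:
                A = A + (abs(w.min()) + 1e-6) * np.eye(p)
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            step = g / (np.abs(g).max() + 1.0)
        accepted = False
        for _ in range(12):
            x_new = x + step
            f_new = f(x_new)
            if np.isfinite(f_new) and f_new >= fx - ftol_noise:
                accepted = True
                break
            lam *= 10.0
            A = -H + lam * np.eye(p)
            step = np.linalg.solve(A, g)
        if not accepted:
            # stationary within evaluation noise: fall back to the gradient criterion
            converged = _gcrit(g, H) <= tol_g
            break
        df = f_new - fx
        dx = np.max(np.abs(x_new - x) / (1.0 + np.abs(x)))
        x, fx = x_new, f_new
        lam = max(lam / 5.0, 1e-10)
        g = num_gradient(f, x)
        H = num_hessian(f, x)
        if abs(df) <= tol_f * (1.0 + abs(fx)) and dx <= tol_x and _gcrit(g, H) <= tol_g:
            converged = True
            break
    return OptimResult(theta=x, fmax=fx, converged=converged, iterations=it, gradient=g, hessian=H)


@dataclass
class FitResult:
    """A maximized model fit with uncertainty metadata.

    ``theta`` is the unconstrained parameter vector (variance-type
    parameters on log / log-Cholesky scales); ``standard_errors`` are the
    inverse-observed-information SEs on that same scale, aligned with
    ``param_names``.
    """

    params: object
    loglik: float
    n_params: int
    n_subjects: int
    converged: bool
    iterations: int
    param_names: Sequence[str]
    theta: np.ndarray
    cov: np.ndarray | None
    standard_errors: np.ndarray | None
    model_tag: str = ""

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        i = list(self.param_names).index(name)
        z = norm.ppf(0.5 + level / 2)
        se = self.standard_errors[i]
        return float(self.theta[i] - z * se), float(self.theta[i] + z * se)

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_subjects": int(self.n_subjects),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "parameters": {
                name: {"estimate": float(t), "se": (float(s) if s is not None else None)}
                for name, t, s in zip(
                    self.param_names,
                    self.theta,
                    self.standard_errors
                    if self.standard_errors is not None
                    else [None] * len(self.theta),
                )
            },
        }


def covariance_from_hessian(H: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Inverse observed information from the log-likelihood Hessian."""
    try:
        cov = np.linalg.inv(-H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return cov, np.sqrt(np.where(diag > 0, diag, np.nan))
        return cov, np.sqrt(diag)
    except np.linalg.LinAlgError:
        return None, None
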