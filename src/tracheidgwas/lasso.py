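"""L1-penalised regression by cyclic coordinate descent.

Solves the multi-locus association objective

    min_{a0, a}  1/(2n) * sum_i (y_i - a0 - c_i'g - x_i'a)^2 + lambda * ||a||_1

where the intercept and the covariate block (population-structure principal
components) are never penalised.  Covariates are projected out first
(Frisch-Waugh), marker columns are standardised, and the penalised problem is
solved by cyclic coordinate descent with soft-thresholding (numba inner loop —
the stability-selection stage calls this tens of thousands of times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["LassoFit", "solve_lasso", "lambda_max", "kkt_violation", "standardize"]


@njit(cache=True, fastmath=False)
def _cd_sweeps(X, y, coef, r, lam, tol, max_sweeps):
    """In-place cyclic coordinate descent on standardised X (unit column var).

    ``r`` must enter as y - X @ coef.  Returns (n_sweeps, converged).
    """
    n, p = X.shape
    nlam = lam * n
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            cj = coef[j]
            rho = cj * n  # since x_j'x_j = n for unit-variance columns
            for i in range(n):
                rho += X[i, j] * r[i]
            if rho > nlam:
                new = (rho - nlam) / n
            elif rho < -nlam:
                new = (rho + nlam) / n
            else:
                new = 0.0
            delta = new - cj
            if delta != 0.0:
                coef[j] = new
                for i in range(n):
                    r[i] -= delta * X[i, j]
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return sweep + 1, True
    return max_sweeps, False


@njit(cache=True, fastmath=False)
def _cd_general(X, colnorm2_n, coef, r, lam, tol, max_sweeps):
    """Cyclic coordinate descent for arbitrary column scales.

    ``colnorm2_n[j]`` = x_j'x_j / n; ``r`` enters as y - X @ coef.
    """
    n, p = X.shape
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if colnorm2_n[j] <= 0.0:
                continue
            cj = coef[j]
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * r[i]
            rho = dot / n + colnorm2_n[j] * cj
            if rho > lam:
                new = (rho - lam) / colnorm2_n[j]
            elif rho < -lam:
                new = (rho + lam) / colnorm2_n[j]
            else:
                new = 0.0
            delta = new - cj
            if delta != 0.0:
                coef[j] = new
                for i in range(n):
                    r[i] -= delta * X[i, j]
                scaled = abs(delta) * (colnorm2_n[j] ** 0.5)
                if scaled > max_delta:
                    max_delta = scaled
        if max_delta < tol:
            return sweep + 1, True
    return max_sweeps, False


def standardize(X, drop_tol: float = 1e-12):
    """Center/scale columns to mean 0, variance 1.

    Returns (X_std, mean, sd, active) where ``active`` marks non-constant
    columns; constant columns are left centered but unscaled and excluded from
    the penalised fit by the callers.
    """
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    active = sd > drop_tol
    sd_safe = np.where(active, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd, active


def _residualize(y, X, C):
    """Project the intercept + covariate block out of y and X (Frisch-Waugh)."""
    n = len(y)
    ones = np.ones((n, 1))
    Q = ones if C is None or C.size == 0 else np.concatenate([ones, C], axis=1)
    coefs, *_ = np.linalg.lstsq(Q, np.concatenate([y[:, None], X], axis=1), rcond=None)
    fitted = Q @ coefs
    return y - fitted[:, 0], X - fitted[:, 1:], Q


@dataclass
class LassoFit:
    """Penalised coefficients on the standardised-marker scale plus the
    unpenalised intercept/covariate effects recovered afterwards."""

    coef: np.ndarray  # per marker, standardised scale
    intercept: float
    covariate_coef: np.ndarray
    lam: float
    n_sweeps: int
    converged: bool

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)


def lambda_max(y, X, C=None) -> float:
    """Smallest penalty with an all-zero marker solution: max_j |x_j'r| / n."""
    yr, Xr, _ = _residualize(np.asarray(y, float), np.asarray(X, float), C)
    Xs, _, _, active = standardize(Xr)
    if not active.any():
        return 0.0
    return float(np.abs(Xs[:, active].T @ yr).max() / len(yr))


def solve_lasso(
    y,
    X,
    lam: float,
    C=None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    warm_coef: np.ndarray | None = None,
) -> LassoFit:
    """Solve the covariate-adjusted LASSO at penalty ``lam``.

    Marker columns are standardised internally; returned marker coefficients
    are on that standardised scale (divide by the column SD for effects per
    allele-dose).  Intercept and covariates are never penalised.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("inputs must be finite")
    yr, Xr, Q = _residualize(y, X, C)
    Xs, _, sd, active = standardize(Xr)
    Xa = np.ascontiguousarray(Xs[:, active])

    coef_a = np.zeros(Xa.shape[1])
    if warm_coef is not None:
        coef_a[:] = warm_coef[active]
    r = yr - Xa @ coef_a
    sweeps, converged = _cd_sweeps(Xa, yr, coef_a, r, lam, tol, max_sweeps)

    coef = np.zeros(X.shape[1])
    coef[active] = coef_a
    # unpenalised block refit on the residual after the marker fit
    marker_part = Xs @ coef
    gamma, *_ = np.linalg.lstsq(Q, y - marker_part, rcond=None)
    return LassoFit(
        coef=coef,
        intercept=float(gamma[0]),
        covariate_coef=np.asarray(gamma[1:]),
        lam=float(lam),
        n_sweeps=int(sweeps),
        converged=bool(converged),
    )


def kkt_violation(y, X, coef, lam, C=None) -> float:
    """Max KKT residual of the penalised problem (0 at the exact solution).

    Active coordinates must satisfy x_j'r/n = lam * sign(a_j); inactive ones
    |x_j'r|/n <= lam.
    """
    yr, Xr, _ = _residualize(np.asarray(y, float), np.asarray(X, float), C)
    Xs, _, _, active = standardize(Xr)
    r = yr - Xs @ coef
    g = Xs.T @ r / len(yr)
    viol = np.where(
        coef != 0.0,
        np.abs(g - lam * np.sign(coef)),
        np.clip(np.abs(g) - lam, 0.0, None),
    )
    return float(viol[active].max()) if active.any() else 0.0
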