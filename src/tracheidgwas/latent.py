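"""Latent traits from trajectories: linear-spline coefficients and MFA summaries.

Dimension/coarseness trajectories are reduced to the four coefficients of a
two-knot truncated-linear spline

    y(t) = beta0 + beta1*t + beta2*(t - K1)+ + beta3*(t - K2)+,

fitted per family (or tree) by ordinary least squares after a shared knot pair
has been chosen per trait by total-SSE grid search.  Microfibril-angle
trajectories are reduced to three latents instead: the mean MFA of the juvenile
core (MFA_CORE), of the outer wood (MFA_OUTER), and the transition age MFA_TA
at which the fitted monotone decay curve crosses 20 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "SplineFit",
    "MfaLatent",
    "spline_basis",
    "fit_linear_spline",
    "select_knots",
    "mfa_latents",
    "latent_table",
    "mfa_latent_table",
]

LATENT_NAMES = ("beta0", "beta1", "beta2", "beta3")


def spline_basis(ages, knots) -> np.ndarray:
    """Truncated-linear design matrix with columns [1, t, (t-K1)+, (t-K2)+]."""
    ages = np.asarray(ages, dtype=float)
    k1, k2 = knots
    if not k1 < k2:
        raise ValueError(f"knots must satisfy K1 < K2, got {knots}")
    if not (ages.min() <= k1 and k2 <= ages.max()):
        raise ValueError(f"knots {knots} outside the age range [{ages.min()}, {ages.max()}]")
    return np.column_stack(
        [
            np.ones_like(ages),
            ages,
            np.clip(ages - k1, 0.0, None),
            np.clip(ages - k2, 0.0, None),
        ]
    )


@dataclass
class SplineFit:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    knots: tuple[float, float]
    sse: float
    n_points: int
    rank_deficient: bool = False

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def predict(self, ages) -> np.ndarray:
        b = np.nan_to_num(self.betas)
        return spline_basis(np.asarray(ages, float), self.knots) @ b


def fit_linear_spline(ages, values, knots) -> SplineFit:
    """OLS fit of the two-knot linear spline; exact on noise-free spline data.

    If no observations lie beyond K2 the last basis column is empty: the fit is
    flagged rank-deficient, the segment dropped and beta3 reported as NaN.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) != len(values):
        raise ValueError("ages and values must have equal length")
    if len(ages) < 4:
        raise ValueError("need at least 4 points to fit a two-knot spline")
    B = spline_basis(ages, knots)
    active = np.ptp(B, axis=0) > 0
    active[0] = True
    rank_deficient = not active.all()
    if rank_deficient:
        logger.warning("spline segment(s) without data at knots %s; dropped", (knots,))
    coef = np.full(4, np.nan)
    sol, res, rank, _ = np.linalg.lstsq(B[:, active], values, rcond=None)
    coef[active] = sol
    resid = values - B[:, active] @ sol
    return SplineFit(
        beta0=coef[0],
        beta1=coef[1],
        beta2=coef[2],
        beta3=coef[3],
        knots=tuple(knots),
        sse=float(resid @ resid),
        n_points=len(ages),
        rank_deficient=rank_deficient,
    )


def select_knots(trajectories, grid) -> tuple[int, int]:
    """Shared knot pair for a trait: minimise total SSE across trajectories.

    ``trajectories`` is an iterable of (ages, values); ``grid`` an iterable of
    integer (K1, K2) pairs with K1 < K2.  Ties break to the smaller K1, then the
    smaller K2.
    """
    grid = sorted({(int(a), int(b)) for a, b in grid})
    if not grid:
        raise ValueError("empty knot grid")
    trajs = [(np.asarray(a, float), np.asarray(v, float)) for a, v in trajectories]
    best = None
    best_sse = np.inf
    for knots in grid:
        if knots[0] >= knots[1]:
            raise ValueError(f"invalid grid pair {knots}")
        total = 0.0
        for ages, values in trajs:
            total += fit_linear_spline(ages, values, knots).sse
        if best is None or total < best_sse - 1e-12 * max(1.0, abs(best_sse)):
            best, best_sse = knots, total
    return best


def latent_table(refined: pd.DataFrame, knots, by: str = "family") -> pd.DataFrame:
    """Spline latent traits (beta0..beta3) per family (or tree) from a refined
    trajectory table with columns [by, cambial_age, value]."""
    rows = []
    for key, grp in refined.groupby(by, sort=True):
        fit = fit_linear_spline(grp["cambial_age"], grp["value"], knots)
        rows.append({by: key, **dict(zip(LATENT_NAMES, fit.betas)), "sse": fit.sse})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MFA latents
# ---------------------------------------------------------------------------


@dataclass
class MfaLatent:
    mfa_core: float
    mfa_outer: float
    mfa_ta: float
    crossed: bool
    fit_ok: bool = True
    n_used: int = 0


def _mad_screen(ages, values, fitted, n_mads: float):
    """Residual-based outlier screen: points further than ``n_mads`` robust
    SDs (1.4826*MAD) from the fitted curve are dropped."""
    resid = values - fitted
    med = np.median(resid)
    mad = np.median(np.abs(resid - med)) * 1.4826
    if mad == 0:
        return np.ones(len(ages), dtype=bool)
    keep = np.abs(resid - med) <= n_mads * mad
    if keep.sum() < 3:
        return np.ones(len(ages), dtype=bool)
    return keep


def mfa_latents(
    ages, values, threshold: float = 20.0, mad_screen: float | None = 4.0
) -> MfaLatent:
    """MFA_CORE / MFA_OUTER / MFA_TA from one tree's MFA-vs-age series.

    A monotone exponential decay ``plateau + drop*exp(-rate*(t-t0))`` is fitted
    by least squares; with ``mad_screen`` set, points further than that many
    robust SDs from the first fit are dropped and the curve refitted.  The
    transition age is the first age where the fitted curve is at or below the
    threshold, linearly interpolated between the bracketing ring ages; the core
    and outer means are taken over the observed (screened) values at ages <= /
    > MFA_TA.  Trees whose fitted curve never reaches the threshold are flagged
    ``crossed=False`` for exclusion from association mapping.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 rings for MFA latents")
    order = np.argsort(ages)
    ages, values = ages[order], values[order]

    t0 = ages[0]

    def model(t, plateau, drop, rate):
        return plateau + drop * np.exp(-rate * (t - t0))

    def _fit(a, v):
        p0 = (max(v.min(), 1e-3), max(v[0] - v.min(), 1e-3), 0.3)
        return curve_fit(
            model,
            a,
            v,
            p0=p0,
            bounds=([0.0, 0.0, 1e-4], [90.0, 90.0, 10.0]),
            maxfev=10_000,
        )[0]

    try:
        popt = _fit(ages, values)
        if mad_screen is not None:
            keep = _mad_screen(ages, values, model(ages, *popt), mad_screen)
            if not keep.all():
                ages, values = ages[keep], values[keep]
                popt = _fit(ages, values)
    except (RuntimeError, ValueError):
        logger.warning("MFA decay fit failed; tree flagged")
        return MfaLatent(np.nan, np.nan, np.nan, crossed=False, fit_ok=False, n_used=len(ages))

    fitted = model(ages, *popt)
    below = fitted <= threshold
    if not below.any():
        return MfaLatent(
            mfa_core=float(values.mean()),
            mfa_outer=np.nan,
            mfa_ta=np.nan,
            crossed=False,
            n_used=len(ages),
        )
    first = int(np.argmax(below))
    if first == 0:
        ta = float(ages[0])
    else:
        a0, a1 = ages[first - 1], ages[first]
        f0, f1 = fitted[first - 1], fitted[first]
        ta = float(a0 + (f0 - threshold) / (f0 - f1) * (a1 - a0))
    core_mask = ages <= ta
    core = float(values[core_mask].mean()) if core_mask.any() else np.nan
    outer = float(values[~core_mask].mean()) if (~core_mask).any() else np.nan
    return MfaLatent(mfa_core=core, mfa_outer=outer, mfa_ta=ta, crossed=True, n_used=len(ages))


def mfa_latent_table(
    rings: pd.DataFrame,
    threshold: float = 20.0,
    mad_screen: float | None = 4.0,
    trait: str = "MFA_Ring",
) -> pd.DataFrame:
    """Per-tree MFA latents from a long ring table; uncrossed trees flagged."""
    rows = []
    sub = rings[rings["trait"] == trait]
    for tree, grp in sub.groupby("tree_id", sort=True):
        lat = mfa_latents(grp["cambial_age"], grp["value"], threshold, mad_screen)
        rows.append(
            {
                "tree_id": tree,
                "mfa_core": lat.mfa_core,
                "mfa_outer": lat.mfa_outer,
                "mfa_ta": lat.mfa_ta,
                "crossed": lat.crossed,
                "fit_ok": lat.fit_ok,
            }
        )
    return pd.DataFrame(rows)
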