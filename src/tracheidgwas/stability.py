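"""Stability-selection LASSO association with the Buhlmann false-selection bound.

Significance of a marker is its stability selection probability (SSP): the
fraction of half-sample LASSO fits in which it enters the model.  With p
markers and an average of q markers selected per subsample, the expected number
of falsely selected markers at SSP threshold pi is bounded by

    E[V] <= q^2 / ((2*pi - 1) * p),

so the threshold and the subsample selection size can be derived from each
other for a target E[V].  At the scale of the motivating study (p = 178,101,
E[V] <= 1, q = 84) the bound gives pi = 0.52, the operating threshold used
throughout.  Population structure is handled by including the leading genotype
principal components as unpenalised covariates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lasso import _cd_sweeps, _residualize, standardize

__all__ = [
    "genotype_pcs",
    "buhlmann_threshold",
    "buhlmann_max_selected",
    "StabilitySelection",
    "StabilityResults",
]


def genotype_pcs(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal component scores of a complete genotype dosage matrix.

    Columns are centered (not scaled); the sign of each component is fixed by
    making its largest-magnitude loading positive.  ``k=0`` returns an (n, 0)
    matrix (intercept-only covariates).
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if k == 0:
        return np.empty((n, 0))
    if k >= min(n, p):
        raise ValueError(f"k={k} must be < min(n_trees, n_markers)={min(n, p)}")
    Xc = values - values.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return (U[:, :k] * S[:k]) * signs[:k]


def buhlmann_threshold(p: int, q: float, ev_max: float = 1.0) -> float:
    """Smallest SSP threshold pi with E[falsely selected] <= ev_max."""
    if not 0 < q < p:
        raise ValueError("need 0 < q < p")
    if ev_max <= 0:
        raise ValueError("ev_max must be > 0")
    ratio = q * q / (p * ev_max)
    if ratio >= 1.0:
        warnings.warn(
            "Buhlmann bound cannot reach the requested E[V]; threshold capped at 1",
            stacklevel=2,
        )
        return 1.0
    return 0.5 * (1.0 + ratio)


def buhlmann_max_selected(p: int, pi: float, ev_max: float = 1.0) -> int:
    """Inverse mode: largest per-subsample selection size q keeping E[V] <= ev_max."""
    if not 0.5 < pi <= 1.0:
        raise ValueError("pi must be in (0.5, 1]")
    return int(math.floor(math.sqrt((2.0 * pi - 1.0) * p * ev_max)))


@dataclass
class StabilityResults:
    """Per-marker inclusion frequencies and the selection they imply."""

    ssp: pd.Series  # indexed by marker id, values in [0, 1]
    pi_threshold: float
    q_target: int
    q_avg: float
    n_subsamples: int
    ev_bound: float
    full_fit_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def selected(self) -> pd.Index:
        return self.ssp.index[self.ssp >= self.pi_threshold]

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"ssp": self.ssp})
        out["selected"] = out["ssp"] >= self.pi_threshold
        if not self.full_fit_effects.empty:
            out["effect"] = self.full_fit_effects.reindex(out.index)
        return out.sort_values("ssp", ascending=False)

    def summary(self) -> str:
        return (
            "Stability-selection LASSO\n"
            f"  markers={len(self.ssp)}  subsamples={self.n_subsamples}  "
            f"q_target={self.q_target}  q_avg={self.q_avg:.2f}\n"
            f"  SSP threshold pi={self.pi_threshold:.3f}  "
            f"Buhlmann E[V] bound={self.ev_bound:.3f}\n"
            f"  selected markers: {len(self.selected)}"
        )


class StabilitySelection:
    """Multi-locus LASSO association for one latent trait.

    Parameters
    ----------
    y : array-like, shape (n,)
        Latent-trait values (per family or per tree).
    X : array-like, shape (n, p)
        Genotype dosages (0/1/2 codes or family means), complete (imputed).
    C : array-like, shape (n, k), optional
        Unpenalised covariates, typically the leading genotype PCs.
    marker_ids : sequence, optional
        Labels for the columns of X.
    n_subsamples : int
        Number of half-sample draws (size floor(n/2), without replacement).
    pi_threshold : float
        SSP significance threshold (default 0.52, the operating threshold
        consistent with E[V] <= 1 at the motivating study's marker count).
    q_target : int, optional
        Markers to select per subsample.  Default: the largest q for which the
        Buhlmann bound keeps E[V] <= ev_max at ``pi_threshold``.
    """

    def __init__(
        self,
        y,
        X,
        C=None,
        marker_ids=None,
        n_subsamples: int = 100,
        pi_threshold: float = 0.52,
        q_target: int | None = None,
        ev_max: float = 1.0,
        n_screen: int | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.C = None if C is None else np.asarray(C, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError("y and X disagree on n")
        if n < 20:
            raise ValueError("stability selection needs n >= 20")
        self.marker_ids = (
            pd.Index(marker_ids) if marker_ids is not None else pd.RangeIndex(p)
        )
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids must match the columns of X")
        self.n_subsamples = int(n_subsamples)
        self.pi_threshold = float(pi_threshold)
        self.ev_max = float(ev_max)
        if q_target is None:
            q_target = buhlmann_max_selected(p, self.pi_threshold, self.ev_max)
            q_target = max(q_target, 1)
        if q_target >= p:
            raise ValueError(f"q_target={q_target} must be < p={p}")
        self.q_target = int(q_target)
        self.n_screen = n_screen

    # -- internal: lambda calibrated so the active set has <= q_target markers,
    #    as close to it as the path allows.  The path is walked downward from
    #    lambda_max with warm starts and stops as soon as the active set would
    #    exceed q_target; a screening set (top marginal correlations) keeps the
    #    sweeps cheap, with a global KKT check guarding its validity.
    def _subsample_active(self, ys, Xs, tol=1e-6, max_sweeps=2000, path_factor=0.9):
        yr, Xr, _ = _residualize(ys, Xs, None if self.C is None else self._Cs)
        Xstd, _, _, active = standardize(Xr)
        p_all = Xstd.shape[1]
        n = Xstd.shape[0]
        if not active.any():
            return np.zeros(p_all, dtype=bool), 0
        act_idx = np.flatnonzero(active)
        grad0 = np.abs(Xstd[:, act_idx].T @ yr) / n
        lam_hi = float(grad0.max())

        # screening: coordinates that can enter while lambda >= lam_hi * floor
        n_screen = self.n_screen or max(20 * self.q_target, 200)
        n_screen = min(len(act_idx), n_screen)
        screen_local = np.argsort(grad0)[::-1][:n_screen]
        cols = act_idx[screen_local]
        Xa = np.ascontiguousarray(Xstd[:, cols])
        pa = Xa.shape[1]

        coef = np.zeros(pa)
        lam = lam_hi * (1.0 - 1e-9)
        acc_coef, acc_lam, acc_q = coef.copy(), lam, 0
        overshoot = None
        for _ in range(200):
            lam *= path_factor
            r = yr - Xa @ coef
            _cd_sweeps(Xa, yr, coef, r, lam, tol, max_sweeps)
            na = int(np.count_nonzero(coef))
            if na > self.q_target:
                overshoot = lam
                break
            acc_coef, acc_lam, acc_q = coef.copy(), lam, na
            if na == self.q_target:
                break
        # bisect the bracketing interval to land on q_target where the path
        # step jumped over it
        if overshoot is not None and acc_q < self.q_target:
            lo, hi = overshoot, acc_lam  # lo: too many actives, hi: accepted
            for _ in range(10):
                mid = math.sqrt(lo * hi)
                coef = acc_coef.copy()
                r = yr - Xa @ coef
                _cd_sweeps(Xa, yr, coef, r, mid, tol, max_sweeps)
                na = int(np.count_nonzero(coef))
                if na > self.q_target:
                    lo = mid
                else:
                    hi = mid
                    acc_coef, acc_lam, acc_q = coef.copy(), mid, na
                    if na == self.q_target:
                        break
        # guard the screen: at the accepted lambda no excluded coordinate may
        # violate KKT (only possible if the screen was too small)
        if acc_q and len(cols) < len(act_idx):
            out = np.setdiff1d(act_idx, cols, assume_unique=False)
            g_out = np.abs(Xstd[:, out].T @ (yr - Xa @ acc_coef)) / n
            if (g_out > acc_lam * (1 + 1e-6)).any():  # pragma: no cover
                warnings.warn(
                    "marker screen too small for this subsample; SSP may "
                    "slightly undercount markers outside the screen",
                    stacklevel=2,
                )
        sel_full = np.zeros(p_all, dtype=bool)
        sel_full[cols[acc_coef != 0.0]] = True
        return sel_full, acc_q

    def fit(self, seed: int = 0) -> StabilityResults:
        """Run the subsampling and return per-marker inclusion frequencies."""
        rng = np.random.default_rng(seed)
        n, p = self.X.shape
        half = n // 2
        counts = np.zeros(p)
        q_sizes = []
        for _ in range(self.n_subsamples):
            idx = rng.choice(n, size=half, replace=False)
            self._Cs = None if self.C is None else self.C[idx]
            sel, q = self._subsample_active(self.y[idx], self.X[idx])
            counts[sel] += 1.0
            q_sizes.append(q)
        ssp = pd.Series(counts / self.n_subsamples, index=self.marker_ids, name="ssp")
        q_avg = float(np.mean(q_sizes))
        ev_bound = q_avg**2 / ((2 * self.pi_threshold - 1) * p) if q_avg > 0 else 0.0

        # full-data refit (OLS on selected markers + covariates) for effects
        sel_idx = np.flatnonzero(ssp.to_numpy() >= self.pi_threshold)
        effects = pd.Series(dtype=float)
        if sel_idx.size:
            yr, Xr, _ = _residualize(self.y, self.X[:, sel_idx], self.C)
            beta, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
            effects = pd.Series(beta, index=self.marker_ids[sel_idx], name="effect")
        return StabilityResults(
            ssp=ssp,
            pi_threshold=self.pi_threshold,
            q_target=self.q_target,
            q_avg=q_avg,
            n_subsamples=self.n_subsamples,
            ev_bound=ev_bound,
            full_fit_effects=effects,
        )
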