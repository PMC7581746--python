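"""Characterisation of significant marker effects.

For each marker that survives stability selection this stage reports:

* the percentage of latent-trait variance explained (PVE), estimated with an
  adaptive LASSO (weights 1/|beta_init|^gamma) so large true effects are not
  over-shrunk the way a single-penalty LASSO shrinks them;
* genotype-class means and the classical quantitative-genetics parameters
  2a = |G_BB - G_bb| (homozygote difference), d = G_Bb - (G_BB + G_bb)/2
  (dominance deviation) and their ratio d/a, with the mode of gene action
  classified as additive (|d/a| <= 0.50), partial-to-full dominant
  (0.50 < |d/a| < 1.25) or over-dominant (|d/a| >= 1.25);
* a tie-corrected Kruskal-Wallis test across the genotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .genio import MISSING
from .lasso import _cd_general, _residualize, standardize

__all__ = [
    "GeneAction",
    "gene_action",
    "classify_mode",
    "dominance_ratio",
    "kruskal_wallis",
    "adaptive_lasso_pve",
    "association_table",
]

MODE_ADDITIVE = "additive"
MODE_DOMINANT = "partial-to-full dominant"
MODE_OVERDOMINANT = "over-dominant"
MODE_UNCLASSIFIED = "unclassified"


def classify_mode(d_over_a: float) -> str:
    """Mode of gene action from |d/a|; boundaries resolve to the lower band."""
    if np.isnan(d_over_a):
        return MODE_UNCLASSIFIED
    r = abs(d_over_a)
    if r <= 0.50:
        return MODE_ADDITIVE
    if r < 1.25:
        return MODE_DOMINANT
    return MODE_OVERDOMINANT


def dominance_ratio(two_a: float, d: float) -> float:
    """d/a from the homozygote difference 2a and dominance deviation d.

    Orientation follows the allele coding that makes a >= 0 (code-2 homozygote
    at least as large as code-0), so the sign of the ratio is the sign of d.
    """
    if two_a == 0:
        return np.nan
    return d / (two_a / 2.0)


@dataclass
class GeneAction:
    mean_aa: float  # code 0
    mean_ab: float  # code 1
    mean_bb: float  # code 2
    n_aa: int
    n_ab: int
    n_bb: int
    two_a: float
    d: float
    d_over_a: float
    mode: str


def gene_action(y, codes) -> GeneAction:
    """Genotype-class means and additive/dominance parameters for one marker.

    Requires at least one individual in each homozygote class; with an empty
    heterozygote class d (and hence d/a and the mode) is reported missing.
    The sign of d/a follows the orientation with a >= 0.
    """
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    obs = codes != MISSING
    y, codes = y[obs], codes[obs]
    groups = [y[codes == g] for g in (0, 1, 2)]
    n = [len(g) for g in groups]
    if n[0] == 0 or n[2] == 0:
        raise ValueError("both homozygote classes must be non-empty")
    m0, m2 = groups[0].mean(), groups[2].mean()
    m1 = groups[1].mean() if n[1] else np.nan
    two_a = abs(m2 - m0)
    # d is invariant under swapping the homozygote labels, so pairing it with
    # a = two_a/2 >= 0 gives the ratio in the orientation that makes a positive
    d = m1 - 0.5 * (m0 + m2) if n[1] else np.nan
    doa = dominance_ratio(two_a, d) if n[1] else np.nan
    return GeneAction(
        mean_aa=float(m0),
        mean_ab=float(m1) if n[1] else np.nan,
        mean_bb=float(m2),
        n_aa=n[0],
        n_ab=n[1],
        n_bb=n[2],
        two_a=float(two_a),
        d=float(d) if n[1] else np.nan,
        d_over_a=float(doa) if not np.isnan(doa) else np.nan,
        mode=classify_mode(doa),
    )


def kruskal_wallis(y, codes) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across genotype classes.

    Returns (H, p) with p from the chi-square approximation on (classes - 1)
    degrees of freedom; all-tied data gives H = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    obs = codes != MISSING
    y, codes = y[obs], codes[obs]
    groups = [y[codes == g] for g in (0, 1, 2) if (codes == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty genotype classes")
    N = len(y)
    ranks = rankdata(y)
    H = 0.0
    for gcode in (0, 1, 2):
        mask = codes == gcode
        if not mask.any():
            continue
        rsum = ranks[mask].sum()
        H += rsum * rsum / mask.sum()
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    # tie correction
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    denom = 1.0 - tie_term / (N**3 - N)
    if denom <= 0:
        return 0.0, 1.0
    H /= denom
    H = max(H, 0.0)
    df = len(groups) - 1
    return float(H), float(chi2.sf(H, df))


def adaptive_lasso_pve(
    y,
    X_selected,
    C=None,
    gamma: float = 1.0,
    n_folds: int = 5,
    n_lambdas: int = 50,
    weight_cap: float = 1e8,
    seed: int = 0,
) -> pd.DataFrame:
    """Adaptive-LASSO effect sizes and per-marker PVE on the selected set.

    Initial estimates come from OLS on the selected markers (ridge with a small
    penalty if the set is ill-conditioned); adaptive weights w_j =
    1/|beta_init_j|^gamma (capped) rescale the columns, the weighted problem is
    solved along a geometric lambda path with K-fold cross-validation, and the
    effects at the CV-optimal penalty give PVE_j = Var(x_j a_j) / Var(y) * 100.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_selected, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("selected set is empty")
    var_y = float(np.var(y))

    yr, Xr, _ = _residualize(y, X, None if C is None else np.asarray(C, float))
    Xs, _, sd, active = standardize(Xr)
    sd_safe = np.where(active, sd, 1.0)

    # initial estimates on the standardised scale (ridge fallback if singular)
    G = Xs.T @ Xs
    if np.linalg.matrix_rank(G) < p:
        G = G + 1e-3 * n * np.eye(p)
    beta_init = np.linalg.solve(G, Xs.T @ yr)
    w = 1.0 / np.maximum(np.abs(beta_init) ** gamma, 1.0 / weight_cap)
    w = np.minimum(w, weight_cap)

    # weighted L1 via column rescaling: beta_j = theta_j / w_j
    Xw = np.ascontiguousarray(Xs / w[None, :])
    colnorm2_n = (Xw**2).sum(axis=0) / n
    lam_hi = float(np.abs(Xw.T @ yr).max() / n) * (1 + 1e-9)
    lambdas = np.geomspace(lam_hi, lam_hi * 1e-4, n_lambdas)

    def _path_fit(Xt, yt, lams):
        """Solutions along the path (warm-started), no re-standardisation."""
        Xt = np.ascontiguousarray(Xt)
        c2 = (Xt**2).sum(axis=0) / Xt.shape[0]
        theta = np.zeros(Xt.shape[1])
        out = np.empty((len(lams), Xt.shape[1]))
        for li, lam in enumerate(lams):
            r = yt - Xt @ theta
            _cd_general(Xt, c2, theta, r, lam, 1e-7, 10_000)
            out[li] = theta
        return out

    rng = np.random.default_rng(seed)
    folds = rng.integers(0, n_folds, size=n) if n_folds > 1 else np.zeros(n, int)
    cv_err = np.zeros(n_lambdas)
    for f in range(max(n_folds, 1)):
        tr, te = folds != f, folds == f
        if te.sum() == 0 or tr.sum() < 3:
            continue
        thetas = _path_fit(Xw[tr], yr[tr], lambdas)
        resid = yr[te][None, :] - thetas @ Xw[te].T
        cv_err += (resid**2).sum(axis=1)
    best = int(np.argmin(cv_err))
    theta = _path_fit(Xw, yr, lambdas[: best + 1])[-1]

    beta_std = theta / w  # effect per SD of the (residualised) dosage
    alpha_raw = beta_std / sd_safe  # effect per allele dose
    alpha_raw[~active] = 0.0
    pve = (
        np.var(X * alpha_raw[None, :], axis=0) / var_y * 100.0
        if var_y > 0
        else np.zeros(p)
    )
    return pd.DataFrame(
        {
            "effect": alpha_raw,
            "effect_std": beta_std,
            "pve_percent": pve,
            "lambda_cv": lambdas[best],
        }
    )


def association_table(
    y,
    geno_values: np.ndarray,
    geno_codes: np.ndarray,
    marker_ids,
    selected_ids,
    ssp: pd.Series,
    C=None,
    trait: str = "",
    gamma: float = 1.0,
    seed: int = 0,
    class_y=None,
    class_codes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build a per-association report for the selected markers.

    ``geno_values`` are imputed dosages (for PVE), ``geno_codes`` the raw
    integer codes (for class means and the Kruskal-Wallis test); both are
    indexed by ``marker_ids`` columns.  When the association itself runs on
    family means, pass per-tree responses/codes via ``class_y``/``class_codes``
    so the genotype classes are populated by actual trees.
    """
    marker_ids = pd.Index(marker_ids)
    sel = marker_ids.get_indexer(pd.Index(selected_ids))
    if (sel < 0).any():
        raise KeyError("selected marker absent from marker_ids")
    if len(sel) == 0:
        return pd.DataFrame()
    if class_y is None:
        class_y, class_codes = y, geno_codes
    class_y = np.asarray(class_y, dtype=float)
    pve = adaptive_lasso_pve(y, geno_values[:, sel], C=C, gamma=gamma, seed=seed)
    rows = []
    for pos, j in enumerate(sel):
        codes_j = class_codes[:, j]
        try:
            ga = gene_action(class_y, codes_j)
            kw_h, kw_p = kruskal_wallis(class_y, codes_j)
        except ValueError:
            ga, kw_h, kw_p = None, np.nan, np.nan
        rows.append(
            {
                "trait": trait,
                "marker": marker_ids[j],
                "ssp": float(ssp.loc[marker_ids[j]]),
                "pve_percent": float(pve["pve_percent"].iloc[pos]),
                "effect": float(pve["effect"].iloc[pos]),
                "mean_AA": ga.mean_aa if ga else np.nan,
                "mean_AB": ga.mean_ab if ga else np.nan,
                "mean_BB": ga.mean_bb if ga else np.nan,
                "two_a": ga.two_a if ga else np.nan,
                "d": ga.d if ga else np.nan,
                "d_over_a": ga.d_over_a if ga else np.nan,
                "mode": ga.mode if ga else MODE_UNCLASSIFIED,
                "kw_statistic": kw_h,
                "kw_pvalue": kw_p,
            }
        )
    return pd.DataFrame(rows)
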