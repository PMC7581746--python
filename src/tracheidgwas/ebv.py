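"""Per-ring mixed model, family breeding values and refined trajectories.

The phenotype-refinement stage fits, for one trait at one cambial age, the
univariate joint-site linear mixed model

    Y_ijkl = u + S_i + B_j(i) + F_k + SF_ik + e_ijkl

with fixed site and block-within-site effects and random family (F) and
site-x-family (SF) effects.  Variance components are estimated by EM-REML on
Henderson's mixed-model equations; family effects (the EBVs) are the BLUPs at
the REML estimates.  Refined trajectories are EBV_k(age) plus the
fixed-effects-adjusted population mean at that age, which removes site and
block signal while preserving the shape of the developmental curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RingMixedModel", "RingMixedModelResults", "refine_trajectories"]

_VAR_FLOOR = 1e-10


def _design_matrices(design: pd.DataFrame):
    """Fixed-effect matrix (treatment coding) and random-effect incidence matrices."""
    site_codes, site_labels = pd.factorize(design["site"])
    block_codes, block_labels = pd.factorize(design["block"])
    fam_codes, fam_labels = pd.factorize(design["family"])
    n = len(design)

    sites_per_block = design.groupby("block")["site"].nunique()
    if (sites_per_block > 1).any():
        bad = sites_per_block[sites_per_block > 1].index.tolist()
        raise ValueError(
            f"confounded site/block design; aliased block columns: {bad}"
        )

    cols = [np.ones(n)]
    names = ["intercept"]
    for s in range(1, len(site_labels)):
        cols.append((site_codes == s).astype(float))
        names.append(f"site[{site_labels[s]}]")
    # block nested in site: drop the first block of each site
    block_site = pd.Series(site_codes).groupby(pd.Series(block_codes)).first()
    for b in range(len(block_labels)):
        first_in_site = min(
            bb for bb in range(len(block_labels)) if block_site[bb] == block_site[b]
        )
        if b != first_in_site:
            cols.append((block_codes == b).astype(float))
            names.append(f"block[{block_labels[b]}]")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, r, piv = _qr_pivot(X)
        keep = piv[:rank]
        aliased = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        raise ValueError(f"confounded fixed-effect design; aliased columns: {aliased}")

    n_fam = len(fam_labels)
    Zf = np.zeros((n, n_fam))
    Zf[np.arange(n), fam_codes] = 1.0
    # site-x-family combinations actually observed; with a single site SF is
    # confounded with F and the term is dropped
    if len(site_labels) > 1:
        sf_codes, sf_labels = pd.factorize(
            pd.Series(site_codes).astype(str) + ":" + pd.Series(fam_codes).astype(str)
        )
        Zsf = np.zeros((n, len(sf_labels)))
        Zsf[np.arange(n), sf_codes] = 1.0
    else:
        Zsf = np.zeros((n, 0))
    return X, names, Zf, list(fam_labels), Zsf


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


@dataclass
class RingMixedModelResults:
    """REML variance components, fixed effects and family EBVs for one ring."""

    sigma2_F: float
    sigma2_SF: float
    sigma2_e: float
    fixed_effects: pd.Series
    family_ebv: pd.Series
    converged: bool
    n_iter: int
    loglik: float
    n_obs: int
    trait: str = ""
    cambial_age: int | None = None

    @property
    def grand_mean(self) -> float:
        """Fixed-effects-adjusted population mean: prediction at the reference
        site/block (the intercept under treatment coding)."""
        return float(self.fixed_effects["intercept"])

    def summary(self) -> str:
        lines = [
            "Ring mixed model (Y = u + S + B(S) + F + SF + e), EM-REML",
            f"  trait={self.trait or '-'} cambial_age={self.cambial_age}",
            f"  n_obs={self.n_obs}  n_families={len(self.family_ebv)}",
            f"  converged={self.converged} after {self.n_iter} iterations "
            f"(REML loglik {self.loglik:.4f})",
            "  variance components:",
            f"    sigma2_F  (family)      = {self.sigma2_F:.6g}",
            f"    sigma2_SF (site:family) = {self.sigma2_SF:.6g}",
            f"    sigma2_e  (residual)    = {self.sigma2_e:.6g}",
            "  fixed effects:",
        ]
        for name, v in self.fixed_effects.items():
            lines.append(f"    {name:<24s} {v:+.6g}")
        return "\n".join(lines)


class RingMixedModel:
    """Univariate joint-site mixed model for one trait at one cambial age.

    Parameters
    ----------
    y : array-like
        Trait values, one per tree, aligned with ``design`` rows.
    design : DataFrame
        Columns tree_id, site, block, family; blocks nested within sites.
    """

    def __init__(self, y, design: pd.DataFrame):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != len(design):
            raise ValueError("y must be 1-D and aligned with the design table")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")
        self.design = design.reset_index(drop=True)
        if self.design["family"].nunique() < 2:
            raise ValueError("need at least 2 families")
        (self.X, self.fixed_names, self.Zf, self.family_labels, self.Zsf) = _design_matrices(
            self.design
        )

    @classmethod
    def from_rings(
        cls, rings: pd.DataFrame, design: pd.DataFrame, trait: str, cambial_age: int
    ) -> "RingMixedModel":
        sub = rings[(rings["trait"] == trait) & (rings["cambial_age"] == cambial_age)]
        merged = sub.merge(design, on="tree_id", how="inner")
        model = cls(merged["value"].to_numpy(), merged[["tree_id", "site", "block", "family"]])
        model._trait, model._age = trait, cambial_age
        return model

    def fit(self, tol: float = 1e-6, max_iter: int = 2000) -> RingMixedModelResults:
        """EM-REML for (sigma2_F, sigma2_SF, sigma2_e), then BLUPs at the estimates.

        Convergence is declared when the relative change in the REML
        log-likelihood falls below ``tol``; negative-variance iterates are
        truncated at zero (a tiny positive floor keeps the equations solvable).
        """
        y, X, Zf, Zsf = self.y, self.X, self.Zf, self.Zsf
        n, p = X.shape
        qf, qsf = Zf.shape[1], Zsf.shape[1]
        W = np.concatenate([X, Zf, Zsf], axis=1)
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)

        var_y = float(np.var(y)) or 1.0
        s2f, s2sf, s2e = 0.3 * var_y, 0.1 * var_y, 0.6 * var_y
        floor = _VAR_FLOOR * var_y
        if qsf == 0:
            s2sf = 1.0  # inert: no SF block in the equations

        sl_f = slice(p, p + qf)
        sl_sf = slice(p + qf, p + qf + qsf)
        diag_idx = np.arange(p + qf + qsf)

        loglik_prev = -np.inf
        loglik = np.nan
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            M = WtW.copy()
            M[diag_idx[sl_f], diag_idx[sl_f]] += s2e / s2f
            if qsf:
                M[diag_idx[sl_sf], diag_idx[sl_sf]] += s2e / s2sf
            try:
                from scipy.linalg import cho_factor, cho_solve

                cf = cho_factor(M)
                sol = cho_solve(cf, Wty)
                Minv = cho_solve(cf, np.eye(M.shape[0]))
                logdet_M = 2.0 * np.log(np.diag(cf[0])).sum()
            except np.linalg.LinAlgError:  # pragma: no cover - near-singular fallback
                Minv = np.linalg.pinv(M)
                sol = Minv @ Wty
                logdet_M = np.linalg.slogdet(M)[1]

            uf = sol[sl_f]
            usf = sol[sl_sf]
            ssr = yty - float(sol @ Wty)

            # REML log-likelihood from MME identities:
            # -2 lR = (n-p-q) log s2e + log|G| + log|M| + SSR/s2e  (+ const)
            q_all = qf + qsf
            loglik = -0.5 * (
                (n - p - q_all) * np.log(s2e)
                + qf * np.log(s2f)
                + (qsf * np.log(s2sf) if qsf else 0.0)
                + logdet_M
                + ssr / s2e
            )

            tr_f = float(np.trace(Minv[sl_f, sl_f]))
            s2f_new = max((float(uf @ uf) + s2e * tr_f) / qf, floor)
            if qsf:
                tr_sf = float(np.trace(Minv[sl_sf, sl_sf]))
                s2sf_new = max((float(usf @ usf) + s2e * tr_sf) / qsf, floor)
            else:
                s2sf_new = s2sf
            s2e_new = max(ssr / (n - p), floor)

            s2f, s2sf, s2e = s2f_new, s2sf_new, s2e_new
            if it > 1:
                rel = abs(loglik - loglik_prev) / (abs(loglik_prev) + 1.0)
                if rel < tol:
                    converged = True
                    break
            loglik_prev = loglik

        if not converged:
            logger.warning("EM-REML did not converge in %d iterations", max_iter)

        # final BLUP solve at the converged estimates
        M = WtW.copy()
        M[diag_idx[sl_f], diag_idx[sl_f]] += s2e / s2f
        if qsf:
            M[diag_idx[sl_sf], diag_idx[sl_sf]] += s2e / s2sf
        sol = np.linalg.solve(M, Wty)

        report = lambda v: 0.0 if v <= 2 * floor else float(v)  # noqa: E731
        return RingMixedModelResults(
            sigma2_F=report(s2f),
            sigma2_SF=report(s2sf) if qsf else 0.0,
            sigma2_e=float(s2e),
            fixed_effects=pd.Series(sol[:p], index=self.fixed_names),
            family_ebv=pd.Series(sol[sl_f], index=self.family_labels, name="ebv"),
            converged=converged,
            n_iter=it,
            loglik=float(loglik),
            n_obs=n,
            trait=getattr(self, "_trait", ""),
            cambial_age=getattr(self, "_age", None),
        )


def reml_loglik_direct(y, X, Zf, Zsf, s2f, s2sf, s2e) -> float:
    """Direct dense-V REML log-likelihood (validation helper, small n only)."""
    n, p = X.shape
    V = s2e * np.eye(n) + s2f * (Zf @ Zf.T) + s2sf * (Zsf @ Zsf.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(r @ Vi @ y)
    )


@dataclass
class RefinedTrajectories:
    """Family-level refined trajectories: EBV + adjusted grand mean per age."""

    table: pd.DataFrame  # columns: family, cambial_age, value
    variance_components: pd.DataFrame
    trait: str = ""
    dropped: list = field(default_factory=list)

    def per_tree(self, design: pd.DataFrame) -> pd.DataFrame:
        """Assign each family's refined curve to its member trees."""
        out = design[["tree_id", "family"]].merge(self.table, on="family")
        out.insert(1, "trait", self.trait)
        return out[["tree_id", "trait", "cambial_age", "value", "family"]]


def refine_trajectories(
    rings: pd.DataFrame,
    design: pd.DataFrame,
    trait: str,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> RefinedTrajectories:
    """Fit the ring mixed model at every cambial age and rebuild trajectories.

    The refined value for family k at age t is EBV_k(t) plus the
    fixed-effects-adjusted population mean at t, so site and block effects are
    removed while the developmental trend is retained.  Ages whose model cannot
    be fitted are dropped with a log entry.
    """
    ages = sorted(rings.loc[rings["trait"] == trait, "cambial_age"].unique())
    if not ages:
        raise ValueError(f"no rings found for trait {trait!r}")
    rows, vc_rows, dropped = [], [], []
    for age in ages:
        try:
            res = RingMixedModel.from_rings(rings, design, trait, age).fit(
                tol=tol, max_iter=max_iter
            )
        except ValueError as exc:
            logger.warning("age %s dropped: %s", age, exc)
            dropped.append(age)
            continue
        base = res.grand_mean
        for fam, ebv in res.family_ebv.items():
            rows.append({"family": fam, "cambial_age": age, "value": ebv + base})
        vc_rows.append(
            {
                "cambial_age": age,
                "sigma2_F": res.sigma2_F,
                "sigma2_SF": res.sigma2_SF,
                "sigma2_e": res.sigma2_e,
                "converged": res.converged,
                "n_iter": res.n_iter,
            }
        )
    return RefinedTrajectories(
        table=pd.DataFrame(rows),
        variance_components=pd.DataFrame(vc_rows),
        trait=trait,
        dropped=dropped,
    )
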