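"""End-to-end functional-mapping GWAS on a simulated (or loaded) dataset.

Chains the four analysis stages: per-ring mixed-model refinement, spline latent
traits, stability-selection LASSO with PC covariates, and effect
characterisation of the selected markers.  By default association uses family
means of the latent traits against family-mean genotype dosages, matching the
half-sib design in which the phenotyped progeny inform on the genotyped
families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effects as eff
from . import genio, latent, simulate
from .ebv import refine_trajectories
from .stability import StabilitySelection, genotype_pcs

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    latents: pd.DataFrame  # per family: beta0..beta3
    knots: tuple[int, int]
    stability: dict  # latent name -> StabilityResults
    associations: pd.DataFrame
    variance_components: pd.DataFrame
    truth: dict | None = None


def _family_means(values: np.ndarray, codes: np.ndarray, families: pd.Series):
    fam_codes, fam_labels = pd.factorize(families)
    n_fam = len(fam_labels)
    sums = np.zeros((n_fam, values.shape[1]))
    np.add.at(sums, fam_codes, values)
    counts = np.bincount(fam_codes, minlength=n_fam).astype(float)
    mean_vals = sums / counts[:, None]
    # nearest integer code per family for genotype-class summaries
    rounded = np.clip(np.rint(mean_vals), 0, 2).astype(np.int8)
    return fam_labels, mean_vals, rounded


def run_pipeline(
    cfg: simulate.SimulationConfig,
    trait: str | None = None,
    latent_names=("beta0", "beta1"),
    knot_grid=None,
    n_pcs: int = 5,
    pi_threshold: float = 0.52,
    n_subsamples: int = 100,
    seed: int = 0,
    family_mean: bool = True,
) -> PipelineResult:
    """Simulate a study under ``cfg`` and run the full analysis on it."""
    cfg.validate()
    trait = trait or next(iter(cfg.spline_means))

    design = simulate.simulate_design(cfg)
    geno = simulate.simulate_genotypes(cfg)
    rings, truth = simulate.simulate_phenotypes(cfg, geno, design)

    filtered, _ = genio.filter_markers(geno)
    imputed = genio.impute_missing(filtered)

    refined = refine_trajectories(rings, design, trait)
    ages = sorted(refined.table["cambial_age"].unique())
    if knot_grid is None:
        lo, hi = min(ages) + 1, max(ages) - 1
        knot_grid = [
            (k1, k2) for k1 in range(lo, hi) for k2 in range(k1 + 2, hi + 1)
        ]
    trajs = [
        (g["cambial_age"].to_numpy(), g["value"].to_numpy())
        for _, g in refined.table.groupby("family")
    ]
    knots = latent.select_knots(trajs, knot_grid)
    latents = latent.latent_table(refined.table, knots, by="family")

    if family_mean:
        fam_labels, Xvals, Xcodes = _family_means(
            imputed.values, filtered.codes, pd.Series(design["family"])
        )
        latents = (
            latents.set_index("family")
            .reindex(fam_labels)
            .rename_axis("family")
            .reset_index()
        )
    else:
        # per-tree mode: each tree carries its family's refined latents
        fam_index = latents.set_index("family")
        latents = (
            design[["tree_id", "family"]]
            .merge(fam_index, left_on="family", right_index=True)
            .sort_values("tree_id")
            .reset_index(drop=True)
        )
        Xvals, Xcodes = imputed.values, filtered.codes

    C = genotype_pcs(Xvals, k=n_pcs) if n_pcs > 0 else None
    marker_ids = filtered.marker_ids

    stability_results = {}
    assoc_frames = []
    rng = np.random.default_rng(seed)
    for name in latent_names:
        y = latents[name].to_numpy()
        sel = StabilitySelection(
            y,
            Xvals,
            C=C,
            marker_ids=marker_ids,
            n_subsamples=n_subsamples,
            pi_threshold=pi_threshold,
        )
        res = sel.fit(seed=int(rng.integers(2**31)))
        stability_results[name] = res
        if len(res.selected):
            if family_mean:
                # genotype classes populated by trees carrying the family latent
                fam_y = pd.Series(y, index=latents["family"])
                tree_y = fam_y.loc[design["family"]].to_numpy()
                class_y, class_codes = tree_y, filtered.codes
            else:
                class_y, class_codes = y, filtered.codes
            tab = eff.association_table(
                y,
                Xvals,
                Xcodes,
                marker_ids,
                res.selected,
                res.ssp,
                C=C,
                trait=f"{trait}.{name}",
                seed=int(rng.integers(2**31)),
                class_y=class_y,
                class_codes=class_codes,
            )
            assoc_frames.append(tab)

    associations = (
        pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame()
    )
    return PipelineResult(
        latents=latents,
        knots=knots,
        stability=stability_results,
        associations=associations,
        variance_components=refined.variance_components,
        truth=truth,
    )
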