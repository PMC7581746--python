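"""Synthetic half-sib progeny-trial data with ring-resolved tracheid phenotypes.

The generator mirrors the design the analysis pipeline assumes: open-pollinated
(half-sib) families planted on two sites in randomized blocks, genotyped
bi-allelic SNPs on the trees, and per-ring trait trajectories that follow a
two-knot linear spline in cambial age.  A sparse set of QTLs acts additively
(and optionally with dominance) on the spline *latent traits*; family, site x
family and residual variation enter as independent normal components so the
per-ring variance decomposition is exactly (sigma2_F, sigma2_SF, sigma2_e).

Everything is driven by a `SimulationConfig` and a single integer seed, and is
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "QtlEffect",
    "SimulationConfig",
    "ConfigurationError",
    "simulate_genotypes",
    "simulate_design",
    "simulate_phenotypes",
    "simulate_mfa_series",
    "spline_value",
    "write_truth",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass(frozen=True)
class QtlEffect:
    """A QTL acting on one latent trait of one phenotype.

    ``a`` is the additive effect (half the homozygote difference, trait units),
    ``d`` the dominance deviation of the heterozygote from the homozygote
    midpoint.  ``latent`` names the spline coefficient the QTL perturbs.
    """

    marker: int
    trait: str
    a: float
    d: float = 0.0
    latent: str = "beta0"


@dataclass(frozen=True)
class SimulationConfig:
    # population / design
    n_families: int = 200
    trees_per_family: int = 12  # total, split evenly across sites (6 per trial)
    n_sites: int = 2
    n_blocks_per_site: int = 4
    # genotypes
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_subpopulations: int = 1
    subpop_freq_shift: float = 0.0  # +/- shift of allele freq between subpops
    # QTL architecture (auto-placed if qtl_effects is None)
    n_qtl: int = 10
    qtl_a: float = 0.3
    qtl_d: float = 0.0
    qtl_effects: tuple[QtlEffect, ...] | None = None
    # variance components of the per-ring observation (trait-unit^2)
    sigma2_F: float = 0.25
    sigma2_SF: float = 0.10
    sigma2_e: float = 1.00
    # between-family variation of the initial slope latent (0 keeps the
    # per-ring variance decomposition exactly (sigma2_F, sigma2_SF, sigma2_e))
    beta1_family_sd: float = 0.0
    # fixed effects
    site_effects: tuple[float, ...] = (0.0, 2.0)
    block_effect_sd: float = 0.5
    # trajectory model
    n_rings: int = 15
    knots: tuple[int, int] = (4, 9)
    spline_means: dict = field(
        default_factory=lambda: {"TWr_Ring": (20.0, 1.5, -0.8, 0.3)}
    )
    noise_sd: float = 0.2
    # MFA trajectory model (exponential decay to plateau)
    mfa_pith: float = 30.0
    mfa_plateau: float = 11.0
    mfa_decay_rate: float = 0.35
    mfa_pith_sd: float = 2.0
    mfa_plateau_sd: float = 1.0
    mfa_rate_sd: float = 0.05
    mfa_noise_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_families": self.n_families,
            "trees_per_family": self.trees_per_family,
            "n_sites": self.n_sites,
            "n_blocks_per_site": self.n_blocks_per_site,
            "n_markers": self.n_markers,
            "n_rings": self.n_rings,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.qtl_effects is None and self.n_qtl > self.n_markers:
            raise ConfigurationError(
                f"n_qtl ({self.n_qtl}) exceeds n_markers ({self.n_markers})"
            )
        k1, k2 = self.knots
        if not (0 < k1 < k2 < self.n_rings):
            raise ConfigurationError(f"knots must satisfy 0 < K1 < K2 < n_rings, got {self.knots}")
        for name in ("sigma2_F", "sigma2_SF", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if len(self.site_effects) != self.n_sites:
            raise ConfigurationError("site_effects must have one entry per site")
        if self.qtl_effects is not None:
            for q in self.qtl_effects:
                if not 0 <= q.marker < self.n_markers:
                    raise ConfigurationError(f"QTL marker index {q.marker} out of range")
                if q.trait not in self.spline_means:
                    raise ConfigurationError(f"QTL assigned to unknown trait {q.trait!r}")

    # seeds for the independent stages, all < 2**31
    def _stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))

    def resolved_qtl_effects(self) -> tuple[QtlEffect, ...]:
        """QTL list: explicit if given, otherwise auto-placed on the first trait."""
        if self.qtl_effects is not None:
            return self.qtl_effects
        rng = np.random.default_rng(self._stage_seed(3))
        markers = rng.choice(self.n_markers, size=self.n_qtl, replace=False)
        trait = next(iter(self.spline_means))
        return tuple(
            QtlEffect(marker=int(m), trait=trait, a=self.qtl_a, d=self.qtl_d)
            for m in sorted(markers)
        )


def _tree_ids(cfg: SimulationConfig) -> list[str]:
    return [
        f"F{fam:04d}_T{t}"
        for fam in range(cfg.n_families)
        for t in range(cfg.trees_per_family)
    ]


def simulate_design(cfg: SimulationConfig) -> pd.DataFrame:
    """Tree -> family, site, block-within-site assignment.

    Trees of each family are spread round-robin over sites (single-tree plots);
    within a site, trees are assigned to blocks round-robin in family order.
    """
    cfg.validate()
    rows = []
    per_site_counter = [0] * cfg.n_sites
    for fam in range(cfg.n_families):
        for t in range(cfg.trees_per_family):
            site = t % cfg.n_sites
            block = per_site_counter[site] % cfg.n_blocks_per_site
            per_site_counter[site] += 1
            rows.append(
                {
                    "tree_id": f"F{fam:04d}_T{t}",
                    "site": f"S{site + 1}",
                    "block": f"S{site + 1}_B{block + 1}",
                    "family": f"F{fam:04d}",
                }
            )
    return pd.DataFrame(rows)


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Half-sib SNP genotypes for all trees, coded 0/1/2 (AA/AB/BB).

    Per marker an alternate-allele frequency is drawn uniformly from
    ``maf_range``; each family's mother is drawn under Hardy-Weinberg, each
    offspring receives one random maternal allele and one pollen allele drawn
    i.i.d. from the population frequency (open pollination).  Missing calls are
    injected completely at random at ``missing_rate``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg._stage_seed(1))
    F, T, M = cfg.n_families, cfg.trees_per_family, cfg.n_markers

    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=M)

    # optional subpopulation structure: families split evenly, frequencies
    # shifted +/- subpop_freq_shift (clipped) to give PCA something to find
    fam_subpop = np.arange(F) * cfg.n_subpopulations // F
    if cfg.n_subpopulations > 1 and cfg.subpop_freq_shift != 0.0:
        offsets = np.linspace(-1.0, 1.0, cfg.n_subpopulations) * cfg.subpop_freq_shift
        fam_freqs = np.clip(freqs[None, :] + offsets[:, None], 0.01, 0.99)
    else:
        fam_freqs = np.broadcast_to(freqs, (max(cfg.n_subpopulations, 1), M))

    pf = fam_freqs[fam_subpop]  # (F, M) per-family allele frequency
    mothers = rng.binomial(2, pf).astype(np.int8)  # (F, M)

    mat_allele = rng.random((F, T, M)) < (mothers[:, None, :] / 2.0)
    pollen = rng.random((F, T, M)) < pf[:, None, :]
    codes = (mat_allele.astype(np.int8) + pollen.astype(np.int8)).reshape(F * T, M)

    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING

    contigs = [f"MA_SYN{j:06d}g0010" for j in range(M)]
    positions = rng.integers(100, 50_000, size=M)
    ref = rng.choice(list("ACGT"), size=M)
    alt_offset = rng.integers(1, 4, size=M)
    bases = np.array(list("ACGT"))
    base_idx = np.searchsorted(bases, ref)
    alt = bases[(base_idx + alt_offset) % 4]

    meta = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions.astype(np.int64),
            "ref": ref,
            "alt": alt,
        }
    )
    geno = GenotypeMatrix(codes=codes, tree_ids=_tree_ids(cfg), meta=meta)
    geno.attrs["true_freqs"] = freqs
    geno.attrs["mother_codes"] = mothers
    return geno


def spline_value(betas, ages, knots):
    """Two-knot truncated-linear spline evaluated at ``ages``."""
    b0, b1, b2, b3 = betas
    ages = np.asarray(ages, dtype=float)
    k1, k2 = knots
    return (
        b0
        + b1 * ages
        + b2 * np.clip(ages - k1, 0.0, None)
        + b3 * np.clip(ages - k2, 0.0, None)
    )


def simulate_phenotypes(
    cfg: SimulationConfig, geno: GenotypeMatrix, design: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Ring-resolved phenotypes from the latent-trait forward model.

    Per tree the latent spline coefficients are the population means plus the
    QTL contributions ``a*(x-1) + d*1[x==1]`` on the designated coefficient plus
    a family deviation N(0, sigma2_F) on the intercept.  The observed ring value
    at cambial age t adds the site and block fixed effects, a site-x-family
    interaction N(0, sigma2_SF), a residual N(0, sigma2_e) and measurement noise
    N(0, noise_sd^2).

    Returns the long-format ring table (tree_id, trait, cambial_age, value) and
    a truth dict carrying the per-tree latent traits and the QTL list.
    """
    cfg.validate()
    if list(geno.tree_ids) != list(design["tree_id"]):
        raise ValueError("genotypes and design must cover the same trees in the same order")
    rng = np.random.default_rng(cfg._stage_seed(2))

    n_trees = len(design)
    fam_codes, fam_labels = pd.factorize(design["family"])
    site_codes, site_labels = pd.factorize(design["site"])
    block_codes, block_labels = pd.factorize(design["block"])
    n_fam, n_site, n_block = len(fam_labels), len(site_labels), len(block_labels)

    block_eff = rng.normal(0.0, cfg.block_effect_sd, size=n_block)
    site_eff = np.asarray(cfg.site_effects, dtype=float)[:n_site]

    qtls = cfg.resolved_qtl_effects()
    for q in qtls:
        if q.trait not in cfg.spline_means:
            raise ConfigurationError(f"QTL assigned to unknown trait {q.trait!r}")

    # QTL genotypes: use complete codes (missingness is an observation process)
    x = geno.codes.astype(float)
    x[geno.codes == MISSING] = np.nan

    ages = np.arange(1, cfg.n_rings + 1)
    latent_names = ("beta0", "beta1", "beta2", "beta3")
    records = []
    truth_latents = []
    for trait, means in cfg.spline_means.items():
        betas = np.tile(np.asarray(means, dtype=float), (n_trees, 1))
        # family deviation on the intercept: ring-level family variance sigma2_F
        fam_dev = rng.normal(0.0, np.sqrt(cfg.sigma2_F), size=n_fam)
        betas[:, 0] += fam_dev[fam_codes]
        if cfg.beta1_family_sd > 0:
            slope_dev = rng.normal(0.0, cfg.beta1_family_sd, size=n_fam)
            betas[:, 1] += slope_dev[fam_codes]
        for q in qtls:
            if q.trait != trait:
                continue
            xm = x[:, q.marker]
            xm = np.where(np.isnan(xm), np.nanmean(xm), xm)
            j = latent_names.index(q.latent)
            betas[:, j] += q.a * (xm - 1.0) + q.d * (xm == 1.0)

        sf_dev = rng.normal(0.0, np.sqrt(cfg.sigma2_SF), size=(n_site, n_fam))
        traj = spline_value(betas.T, ages[:, None], cfg.knots).T  # (n_trees, n_rings)
        traj = traj + site_eff[site_codes][:, None] + block_eff[block_codes][:, None]
        traj = traj + sf_dev[site_codes, fam_codes][:, None]
        traj = traj + rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=traj.shape)
        if cfg.noise_sd > 0:
            traj = traj + rng.normal(0.0, cfg.noise_sd, size=traj.shape)

        df = pd.DataFrame(traj, columns=ages)
        df.insert(0, "tree_id", design["tree_id"].to_numpy())
        long = df.melt(id_vars="tree_id", var_name="cambial_age", value_name="value")
        long.insert(1, "trait", trait)
        records.append(long)

        tl = pd.DataFrame(betas, columns=latent_names)
        tl.insert(0, "tree_id", design["tree_id"].to_numpy())
        tl.insert(1, "trait", trait)
        truth_latents.append(tl)

    rings = pd.concat(records, ignore_index=True)
    rings["cambial_age"] = rings["cambial_age"].astype(int)
    rings = rings.sort_values(["trait", "tree_id", "cambial_age"]).reset_index(drop=True)
    truth = {
        "latent_traits": pd.concat(truth_latents, ignore_index=True),
        "qtl_effects": qtls,
        "knots": cfg.knots,
        "site_effects": site_eff.tolist(),
        "block_effects": block_eff.tolist(),
    }
    return rings, truth


def simulate_mfa_series(
    cfg: SimulationConfig, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tree microfibril-angle trajectories: exponential decay to a plateau.

    MFA(t) = plateau + (pith - plateau) * exp(-rate * (t - 1)) + noise,
    with per-tree pith, plateau and rate perturbations.  Emulates the typical
    conifer pattern of ~30 degrees at the pith stabilising at 10-12 degrees
    around cambial age 10.

    Returns (long ring table with trait 'MFA_Ring', truth table with each
    tree's decay parameters and analytic 20-degree crossing age; ``crossing_age``
    is NaN where the curve never crosses the threshold).
    """
    cfg.validate()
    if design is None:
        design = simulate_design(cfg)
    rng = np.random.default_rng(cfg._stage_seed(4))
    n = len(design)
    pith = rng.normal(cfg.mfa_pith, cfg.mfa_pith_sd, size=n)
    plateau = rng.normal(cfg.mfa_plateau, cfg.mfa_plateau_sd, size=n)
    rate = np.clip(rng.normal(cfg.mfa_decay_rate, cfg.mfa_rate_sd, size=n), 1e-3, None)
    pith = np.maximum(pith, plateau + 1.0)  # keep curves decaying

    ages = np.arange(1, cfg.n_rings + 1)
    curves = plateau[:, None] + (pith - plateau)[:, None] * np.exp(
        -rate[:, None] * (ages[None, :] - 1.0)
    )
    if cfg.mfa_noise_sd > 0:
        curves = curves + rng.normal(0.0, cfg.mfa_noise_sd, size=curves.shape)

    threshold = 20.0
    with np.errstate(divide="ignore", invalid="ignore"):
        crossing = 1.0 + np.log((pith - plateau) / (threshold - plateau)) / rate
    crossing = np.where((plateau < threshold) & (pith > threshold), crossing, np.nan)

    df = pd.DataFrame(curves, columns=ages)
    df.insert(0, "tree_id", design["tree_id"].to_numpy())
    long = df.melt(id_vars="tree_id", var_name="cambial_age", value_name="value")
    long.insert(1, "trait", "MFA_Ring")
    long["cambial_age"] = long["cambial_age"].astype(int)
    long = long.sort_values(["tree_id", "cambial_age"]).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "tree_id": design["tree_id"].to_numpy(),
            "pith": pith,
            "plateau": plateau,
            "rate": rate,
            "crossing_age": crossing,
        }
    )
    return long, truth


def write_truth(truth: dict, path) -> None:
    """Serialise the simulation truth (QTLs, latent traits) as JSON."""
    payload = {
        "knots": list(truth["knots"]),
        "site_effects": truth["site_effects"],
        "block_effects": truth["block_effects"],
        "qtl_effects": [dataclasses.asdict(q) for q in truth["qtl_effects"]],
        "latent_traits": truth["latent_traits"].to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
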