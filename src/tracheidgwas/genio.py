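"""Genotype/phenotype I/O and marker cleaning.

Genotypes live in a `GenotypeMatrix`: trees x markers integer codes (0 = AA,
1 = AB, 2 = BB, -1 = missing) with per-marker metadata.  VCF is the on-disk
interchange format (read via cyvcf2, written as plain v4.2 text); design and
ring tables are CSV.  Marker cleaning follows the usual exome-capture recipe:
drop markers with folded MAF below 0.05 or missingness above 20%, with equality
retained on both boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "ImputedGenotypes",
    "read_vcf",
    "write_vcf",
    "filter_markers",
    "impute_missing",
    "read_design",
    "read_rings",
]


@dataclass
class GenotypeMatrix:
    """Trees x markers genotype codes plus marker metadata.

    ``meta`` has columns contig, pos, ref, alt (maf / missingness are computed
    and appended on construction).  Marker ids are ``"{contig}_{pos}"``.
    """

    codes: np.ndarray  # (n_trees, n_markers) int8, MISSING for no-calls
    tree_ids: list[str]
    meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (trees x markers)")
        if self.codes.shape[0] != len(self.tree_ids):
            raise ValueError("codes rows must match tree_ids")
        if self.codes.shape[1] != len(self.meta):
            raise ValueError("codes columns must match meta rows")
        if len(set(self.tree_ids)) != len(self.tree_ids):
            raise ValueError("tree_ids must be unique")
        self.meta = self.meta.reset_index(drop=True).copy()
        maf, miss = self._marker_stats(self.codes)
        self.meta["maf"] = maf
        self.meta["missingness"] = miss

    @staticmethod
    def _marker_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        obs = codes != MISSING
        n_obs = obs.sum(axis=0)
        alt_count = np.where(obs, codes, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_obs > 0, alt_count / (2.0 * n_obs), np.nan)
        maf = np.minimum(p, 1.0 - p)  # folded
        miss = 1.0 - n_obs / codes.shape[0]
        return maf, miss

    @property
    def n_trees(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(
            self.meta["contig"].astype(str) + "_" + self.meta["pos"].astype(str),
            name="marker",
        )

    def take_markers(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            tree_ids=list(self.tree_ids),
            meta=self.meta.iloc[idx].drop(columns=["maf", "missingness"]),
            attrs=dict(self.attrs),
        )


@dataclass
class ImputedGenotypes:
    """Mean-imputed genotype dosages (float) with the original missing mask."""

    values: np.ndarray  # (n_trees, n_markers) float64
    missing_mask: np.ndarray  # bool, True where a call was imputed
    tree_ids: list[str]
    meta: pd.DataFrame

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(
            self.meta["contig"].astype(str) + "_" + self.meta["pos"].astype(str),
            name="marker",
        )


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Only bi-allelic SNP records are kept (others are skipped and counted in
    ``attrs['n_excluded_non_biallelic']``).  GT is mapped 0/0 -> 0, 0/1 -> 1,
    1/1 -> 2, missing -> -1; MAF and missingness are computed per marker over
    the observed calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    rows, meta_rows = [], []
    n_excluded = 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_excluded += 1
            continue
        rows.append(remap[var.gt_types])
        meta_rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_excluded:
        logger.info("read_vcf: skipped %d non-bi-allelic/non-SNP records", n_excluded)
    codes = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    meta = pd.DataFrame(meta_rows, columns=["contig", "pos", "ref", "alt"])
    geno = GenotypeMatrix(codes=codes, tree_ids=samples, meta=meta)
    geno.attrs["n_excluded_non_biallelic"] = n_excluded
    return geno


_GT = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    meta = geno.meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(meta["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.tree_ids)
            + "\n"
        )
        order = np.lexsort((meta["pos"].to_numpy(), meta["contig"].to_numpy()))
        for j in order:
            row = meta.iloc[j]
            gts = "\t".join(_GT[int(c)] for c in geno.codes[:, j])
            fh.write(
                f"{row.contig}\t{int(row.pos)}\t{row.contig}_{int(row.pos)}\t"
                f"{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def filter_markers(
    geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.20
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Marker cleaning: keep MAF >= maf_min and missingness <= miss_max.

    Equality is retained on both boundaries (the removal rules are strict
    "MAF < 0.05" and "missingness > 20%").  Returns the filtered matrix and a
    per-marker report (marker, maf, missingness, kept).
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise ValueError("miss_max must be in [0, 1]")
    maf = geno.meta["maf"].to_numpy()
    miss = geno.meta["missingness"].to_numpy()
    kept = (maf >= maf_min) & (miss <= miss_max) & ~np.isnan(maf)
    report = pd.DataFrame(
        {
            "marker": geno.marker_ids,
            "maf": maf,
            "missingness": miss,
            "kept": kept,
        }
    )
    if not kept.any():
        warnings.warn("filter_markers: no markers pass the filters", stacklevel=2)
    return geno.take_markers(np.flatnonzero(kept)), report


def impute_missing(geno: GenotypeMatrix) -> ImputedGenotypes:
    """Replace missing codes by the marker's mean genotype (a real value)."""
    mask = geno.codes == MISSING
    if (mask.all(axis=0)).any():
        bad = geno.marker_ids[mask.all(axis=0)]
        raise ValueError(f"markers with all calls missing cannot be imputed: {list(bad[:5])}")
    values = geno.codes.astype(np.float64)
    values[mask] = np.nan
    col_means = np.nanmean(values, axis=0)
    values = np.where(mask, col_means[None, :], values)
    return ImputedGenotypes(
        values=values,
        missing_mask=mask,
        tree_ids=list(geno.tree_ids),
        meta=geno.meta.copy(),
    )


def read_design(path) -> pd.DataFrame:
    """Design CSV (tree_id, site, block, family) with nesting validation."""
    df = pd.read_csv(path, dtype=str)
    required = {"tree_id", "site", "block", "family"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    sites_per_block = df.groupby("block")["site"].nunique()
    if (sites_per_block > 1).any():
        bad = sites_per_block[sites_per_block > 1].index.tolist()
        raise ValueError(f"block labels appear in more than one site: {bad}")
    return df


def read_rings(path) -> pd.DataFrame:
    """Ring phenotype CSV (tree_id, trait, cambial_age, value)."""
    df = pd.read_csv(path)
    required = {"tree_id", "trait", "cambial_age", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"ring table must have columns {sorted(required)}")
    df["cambial_age"] = df["cambial_age"].astype(int)
    return df
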