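"""Per-SNP pleiotropy quantified as phenome-wide association counts.

A variant's pleiotropy is measured PheWAS-style: the number of phenotypes it
associates with at a fixed p-value cutoff (strictly p < 5e-4 by default)
across a variant-by-phenotype p-value matrix. The genome-wide background
(mean/median associations per SNP, optionally restricted to common variants
by a minor-allele-frequency floor) is compared against sets of established
susceptibility loci for individual diseases, each summarized by the mean and
standard error of its member SNPs' counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PValueMatrix",
    "LocusSet",
    "DiseaseLocusStats",
    "BackgroundSummary",
    "PleiotropySummary",
    "EmptyStratumError",
    "count_associations",
    "background_summary",
    "locus_set_summary",
    "enrichment_flag",
    "pleiotropy_summary",
    "read_pvalue_matrix_long",
    "read_locus_sets",
]


class EmptyStratumError(ValueError):
    """A MAF stratum contains no SNPs."""


@dataclass(frozen=True)
class PValueMatrix:
    """SNP x phenotype association p-values with per-SNP minor-allele frequency.

    Missing entries are NaN and never count as associations.
    """

    snp_ids: tuple[str, ...]
    phen_ids: tuple[str, ...]
    p: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        maf = np.asarray(self.maf, dtype=float)
        if p.shape != (len(self.snp_ids), len(self.phen_ids)):
            raise ValueError(
                f"p matrix shape {p.shape} inconsistent with {len(self.snp_ids)} SNPs x "
                f"{len(self.phen_ids)} phenotypes"
            )
        if maf.shape != (len(self.snp_ids),):
            raise ValueError("maf must have one entry per SNP")
        finite = p[np.isfinite(p)]
        if finite.size and (finite.min() <= 0.0 or finite.max() > 1.0):
            raise ValueError("p-values must lie in (0, 1] (or NaN for missing)")
        if maf.size and (maf.min() <= 0.0 or maf.max() > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "maf", maf)


@dataclass(frozen=True)
class LocusSet:
    """Reported susceptibility-locus lead SNPs for one disease."""

    disease: str
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValueError(f"locus set for {self.disease!r} is empty")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"locus set for {self.disease!r} has duplicate SNP ids")


@dataclass(frozen=True)
class DiseaseLocusStats:
    disease: str
    mean: float
    se: float  # NaN when fewer than 2 resolvable SNPs
    n_snps: int


@dataclass(frozen=True)
class BackgroundSummary:
    mean: float
    median: float
    n_snps: int
    maf_min: float | None = None


@dataclass(frozen=True)
class PleiotropySummary:
    per_snp_counts: Mapping[str, int]
    genome: BackgroundSummary
    stratum: BackgroundSummary | None
    per_disease: tuple[DiseaseLocusStats, ...]
    threshold: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "genome_mean": self.genome.mean,
            "genome_median": self.genome.median,
            "stratum_mean": self.stratum.mean if self.stratum else None,
            "stratum_median": self.stratum.median if self.stratum else None,
            "stratum_maf_min": self.stratum.maf_min if self.stratum else None,
            "per_disease": [
                {"disease": d.disease, "mean": d.mean, "se": d.se, "n_snps": d.n_snps}
                for d in self.per_disease
            ],
            "enriched": enrichment_flag(self),
        }


def count_associations(m: PValueMatrix, threshold: float = 5e-4) -> pd.Series:
    """Number of phenotypes with p strictly below ``threshold``, per SNP.

    Missing (NaN) entries never count.
    """
    with np.errstate(invalid="ignore"):
        counts = (m.p < threshold).sum(axis=1)
    return pd.Series(counts.astype(int), index=list(m.snp_ids), name="n_associations")


def background_summary(
    counts: pd.Series, maf: Sequence[float] | None = None, maf_min: float | None = None
) -> BackgroundSummary:
    """Mean and median association count, optionally within a MAF > maf_min stratum."""
    values = counts.to_numpy(dtype=float)
    if maf_min is not None:
        if maf is None:
            raise ValueError("maf values are required for a MAF stratum")
        maf = np.asarray(maf, dtype=float)
        if maf.shape != values.shape:
            raise ValueError("counts and maf are not aligned")
        keep = maf > maf_min
        if not keep.any():
            raise EmptyStratumError(f"no SNPs with maf > {maf_min}")
        values = values[keep]
    return BackgroundSummary(
        mean=float(values.mean()),
        median=float(np.median(values)),
        n_snps=int(values.size),
        maf_min=maf_min,
    )


def locus_set_summary(
    counts: pd.Series, sets: Sequence[LocusSet], missing: str = "skip"
) -> list[DiseaseLocusStats]:
    """Per-disease mean and standard error of member-SNP association counts.

    SE is the sample standard deviation over the set divided by sqrt(set
    size); with fewer than two resolvable SNPs it is reported as NaN. SNPs
    absent from ``counts`` are skipped and logged (``missing="skip"``) or
    raise (``missing="raise"``).
    """
    out = []
    for s in sets:
        present = [i for i in s.snp_ids if i in counts.index]
        absent = set(s.snp_ids) - set(present)
        if absent:
            if missing == "raise":
                raise KeyError(f"locus set {s.disease!r}: SNPs not in counts: {sorted(absent)}")
            logger.warning("locus set %s: skipping %d unknown SNPs", s.disease, len(absent))
        vals = counts.loc[present].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"locus set {s.disease!r} has no resolvable SNPs")
        if vals.size < 2:
            logger.warning("locus set %s: SE undefined with a single SNP", s.disease)
            se = math.nan
        else:
            se = float(vals.std(ddof=1) / math.sqrt(vals.size))
        out.append(DiseaseLocusStats(disease=s.disease, mean=float(vals.mean()), se=se, n_snps=vals.size))
    return out


def enrichment_flag(summary: PleiotropySummary) -> dict[str, bool]:
    """Per-disease flag: locus-set mean strictly above the genome-wide mean."""
    return {d.disease: d.mean > summary.genome.mean for d in summary.per_disease}


def pleiotropy_summary(
    m: PValueMatrix,
    sets: Sequence[LocusSet] = (),
    threshold: float = 5e-4,
    maf_min: float | None = 0.3,
) -> PleiotropySummary:
    """Full pleiotropy report: per-SNP counts, background, and locus-set stats."""
    counts = count_associations(m, threshold=threshold)
    genome = background_summary(counts)
    stratum = background_summary(counts, maf=m.maf, maf_min=maf_min) if maf_min is not None else None
    per_disease = tuple(locus_set_summary(counts, sets)) if sets else ()
    return PleiotropySummary(
        per_snp_counts=dict(counts),
        genome=genome,
        stratum=stratum,
        per_disease=per_disease,
        threshold=threshold,
    )


def read_pvalue_matrix_long(path: str | Path, maf_path: str | Path | None = None) -> PValueMatrix:
    """Read a long-format TSV (snp, phenotype, p) plus a per-SNP MAF TSV (snp, maf).

    Pairs absent from the long table become missing entries. When no MAF
    table is given, all MAFs default to 0.5 (no stratification possible
    below that).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "phenotype": str})
    for col in ("snp", "phenotype", "p"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    wide = df.pivot_table(index="snp", columns="phenotype", values="p", aggfunc="first")
    if maf_path is not None:
        maf_df = pd.read_csv(maf_path, sep="\t", dtype={"snp": str}).set_index("snp")
        maf = maf_df["maf"].reindex(wide.index).to_numpy(dtype=float)
        if np.isnan(maf).any():
            raise ValueError("MAF table missing entries for some SNPs in the p-value table")
    else:
        maf = np.full(wide.index.size, 0.5)
    return PValueMatrix(
        snp_ids=tuple(wide.index),
        phen_ids=tuple(wide.columns),
        p=wide.to_numpy(dtype=float),
        maf=maf,
    )


def read_locus_sets(path: str | Path) -> list[LocusSet]:
    """Read locus sets from a TSV with columns (disease, snp)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("disease", "snp"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    return [
        LocusSet(disease=str(d), snp_ids=tuple(g["snp"]))
        for d, g in df.groupby("disease", sort=False)
    ]
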