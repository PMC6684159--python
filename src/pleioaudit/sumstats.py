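"""Read, write, orient and curate GWAS summary statistics for binary traits.

The on-disk format is tab-separated text with a header row, in the style of
the public UK Biobank per-phenotype association releases: one row per variant
with the effect allele, its frequency, the sample size, the observed-scale
(linear-model) effect and standard error, and the association p-value.
Column names are configurable through a :class:`Dialect`, so the same reader
ingests both the public release layout and this package's canonical layout.

Variant identifiers follow the ``chrom:pos_ref_alt`` convention (1-based
GRCh37 positions), e.g. ``3:46414943_TACAGTCAGTATCAATTCTGGAAGAATTTCCAG_T``
for the CCR5 32-bp deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "AssocStat",
    "PhenotypeMeta",
    "Dialect",
    "NEALE_DIALECT",
    "CANONICAL_DIALECT",
    "SumstatsFormatError",
    "AlleleMismatchError",
    "MissingMetadataError",
    "read_sumstats",
    "write_sumstats",
    "read_phenotype_manifest",
    "write_phenotype_manifest",
    "orient_to_target_allele",
    "filter_curated",
]


class SumstatsFormatError(ValueError):
    """A summary-statistics file violates its declared dialect."""


class AlleleMismatchError(ValueError):
    """A requested target allele matches neither allele of the variant."""


class MissingMetadataError(KeyError):
    """An association references a phenotype absent from the manifest."""


@dataclass(frozen=True)
class VariantKey:
    """A biallelic variant identified as ``chrom:pos_ref_alt`` (GRCh37, 1-based).

    ``info_score`` carries imputation quality when known; it does not take
    part in equality so that oriented copies of a record compare by locus.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    info_score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}_{self.ref}_{self.alt}"

    @classmethod
    def parse(cls, variant_id: str, info_score: float | None = None) -> "VariantKey":
        try:
            locus, ref, alt = variant_id.split("_")
            chrom, pos = locus.split(":")
            return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt, info_score=info_score)
        except (ValueError, AttributeError) as exc:
            raise SumstatsFormatError(
                f"cannot parse variant id {variant_id!r}; expected 'chrom:pos_ref_alt'"
            ) from exc

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.ref, self.alt))


@dataclass(frozen=True)
class AssocStat:
    """One variant-phenotype association on the observed (0/1 linear) scale."""

    variant: VariantKey
    phenotype_id: str
    effect_allele: str
    eaf: float
    n: int
    beta_obs: float
    se_obs: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must be in (0, 1), got {self.eaf}")
        if self.se_obs <= 0.0:
            raise ValueError(f"se_obs must be positive, got {self.se_obs}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.effect_allele not in self.variant.alleles:
            raise AlleleMismatchError(
                f"effect allele {self.effect_allele!r} is neither allele of {self.variant.id}"
            )


@dataclass(frozen=True)
class PhenotypeMeta:
    """Case/control counts for one binary phenotype; prevalence is derived."""

    phenotype_id: str
    name: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("case/control counts must be non-negative")
        if self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one sample")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def prevalence(self) -> float:
        """Marginal case fraction K in the analyzed cohort."""
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a summary-statistics layout.

    ``phenotype`` may be ``None`` for per-phenotype files that carry no
    phenotype column; the caller then supplies ``phenotype_id`` at read time.
    """

    variant: str = "variant"
    effect_allele: str = "effect_allele"
    eaf: str = "eaf"
    n: str = "n"
    beta: str = "beta"
    se: str = "se"
    p: str = "pval"
    phenotype: str | None = "phenotype"
    info_score: str | None = None


#: Layout of the public UK Biobank per-phenotype release files. The allele
#: column names the effect allele and the frequency column refers to it, so
#: effect-allele frequency is obtained directly at ingest.
NEALE_DIALECT = Dialect(
    variant="variant",
    effect_allele="minor_allele",
    eaf="minor_AF",
    n="n_complete_samples",
    beta="beta",
    se="se",
    p="pval",
    phenotype=None,
)

#: Layout written by :func:`write_sumstats`.
CANONICAL_DIALECT = Dialect()

DIALECTS: Mapping[str, Dialect] = {"neale": NEALE_DIALECT, "canonical": CANONICAL_DIALECT}


def read_sumstats(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    phenotype_id: str | None = None,
) -> list[AssocStat]:
    """Read a tab-separated summary-statistics file into :class:`AssocStat` records.

    Rows with missing beta, SE or p-value are skipped and the skip count is
    logged; rows with a frequency outside (0, 1) are collected and reported
    together in a single :class:`SumstatsFormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={dialect.variant: str}, float_precision="round_trip")
    required = [dialect.variant, dialect.effect_allele, dialect.eaf, dialect.n, dialect.beta, dialect.se, dialect.p]
    for col in required:
        if col not in df.columns:
            raise SumstatsFormatError(f"missing mandated column {col!r} in {path}")
    has_phen_col = dialect.phenotype is not None and dialect.phenotype in df.columns
    if not has_phen_col and phenotype_id is None:
        raise SumstatsFormatError(
            f"file {path} has no phenotype column and no phenotype_id was supplied"
        )

    records: list[AssocStat] = []
    n_skipped = 0
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        beta, se, p = row[dialect.beta], row[dialect.se], row[dialect.p]
        if any(pd.isna(v) for v in (beta, se, p, row[dialect.eaf])):
            n_skipped += 1
            continue
        eaf = float(row[dialect.eaf])
        if not 0.0 < eaf < 1.0:
            bad_rows.append(f"row {idx}: frequency {eaf!r} outside (0, 1)")
            continue
        info = float(row[dialect.info_score]) if dialect.info_score else None
        try:
            records.append(
                AssocStat(
                    variant=VariantKey.parse(str(row[dialect.variant]), info_score=info),
                    phenotype_id=str(row[dialect.phenotype]) if has_phen_col else phenotype_id,  # type: ignore[arg-type]
                    effect_allele=str(row[dialect.effect_allele]),
                    eaf=eaf,
                    n=int(row[dialect.n]),
                    beta_obs=float(beta),
                    se_obs=float(se),
                    p=float(p),
                )
            )
        except ValueError as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if n_skipped:
        logger.info("read_sumstats(%s): skipped %d rows with missing beta/se/p", path, n_skipped)
    if bad_rows:
        raise SumstatsFormatError(f"{len(bad_rows)} invalid rows in {path}: " + "; ".join(bad_rows))
    return records


def write_sumstats(assocs: Iterable[AssocStat], path: str | Path) -> None:
    """Write associations as canonical tab-separated text (see :data:`CANONICAL_DIALECT`)."""
    d = CANONICAL_DIALECT
    rows = [
        {
            d.variant: a.variant.id,
            d.phenotype: a.phenotype_id,
            d.effect_allele: a.effect_allele,
            d.eaf: a.eaf,
            d.n: a.n,
            d.beta: a.beta_obs,
            d.se: a.se_obs,
            d.p: a.p,
        }
        for a in assocs
    ]
    # shortest round-trip formatting keeps floats exact through read/write
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


def read_phenotype_manifest(path: str | Path) -> list[PhenotypeMeta]:
    """Read a phenotype manifest TSV (phenotype_id, name, n_cases, n_controls)."""
    df = pd.read_csv(path, sep="\t", dtype={"phenotype_id": str})
    for col in ("phenotype_id", "name", "n_cases", "n_controls"):
        if col not in df.columns:
            raise SumstatsFormatError(f"missing mandated column {col!r} in {path}")
    return [
        PhenotypeMeta(
            phenotype_id=str(r.phenotype_id),
            name=str(r.name_),
            n_cases=int(r.n_cases),
            n_controls=int(r.n_controls),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_phenotype_manifest(metas: Iterable[PhenotypeMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"phenotype_id": m.phenotype_id, "name": m.name, "n_cases": m.n_cases, "n_controls": m.n_controls}
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def orient_to_target_allele(a: AssocStat, target: str) -> AssocStat:
    """Re-sign an association so its effect refers to ``target``.

    Flipping the reported allele negates the observed-scale effect and
    complements the frequency; SE, p and n are unchanged. Applying the
    operation twice returns the original record.
    """
    if target not in a.variant.alleles:
        raise AlleleMismatchError(
            f"target allele {target!r} matches neither allele of {a.variant.id}"
        )
    if target == a.effect_allele:
        return a
    return replace(a, effect_allele=target, beta_obs=-a.beta_obs, eaf=1.0 - a.eaf)


def filter_curated(
    assocs: Sequence[AssocStat],
    metas: Sequence[PhenotypeMeta],
    min_cases: int = 1000,
) -> list[AssocStat]:
    """Keep associations whose phenotype has at least ``min_cases`` cases.

    Mirrors the curation rule used for biobank disease panels (phenotypes
    with at least 1000 cases by default). Order is preserved.
    """
    by_id = {m.phenotype_id: m for m in metas}
    out = []
    for a in assocs:
        meta = by_id.get(a.phenotype_id)
        if meta is None:
            raise MissingMetadataError(f"no phenotype metadata for {a.phenotype_id!r}")
        if meta.n_cases >= min_cases:
            out.append(a)
    return out
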