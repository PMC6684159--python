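"""Synthetic data with the statistical structure the audit assumes.

The generators emulate, at the summary-statistic level, the inputs of a
phenome-wide audit of a single candidate variant:

* a panel of binary disease phenotypes GWASed by linear regression of the
  0/1 outcome on allele dosage in one large cohort, where each phenotype's
  observed-scale SE follows from its prevalence and the dosage variance
  ``2 f (1 - f)``, and true standardized effects are drawn from the
  symmetric three-component Z-score mixture;
* sparse variant-by-phenotype p-value matrices with a controllable per-entry
  association rate (and optionally enriched locus sets) for the pleiotropy
  counter;
* genotype-count contingency tables under Hardy-Weinberg controls and a
  per-allele odds-ratio tilt in cases.

Defaults mirror the study conditions of the CCR5-deletion audit: 131
phenotypes, 361,194 individuals, a 9.2% target-allele frequency, and mixture
(pi_minus, pi_zero, pi_plus, mu_z) = (0, 0.769, 0.231, 1.003). All draws are
bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .contingency import GenotypeCountTable
from .mixture import MixtureParams, sample_mixture
from .pleiotropy import LocusSet, PValueMatrix
from .sumstats import AssocStat, PhenotypeMeta, VariantKey

__all__ = [
    "DEFAULT_MIXTURE",
    "DEFAULT_VARIANT",
    "PanelSpec",
    "gen_phenotype_panel",
    "gen_pvalue_matrix",
    "gen_genotype_table",
]

#: Mixture of true standardized effects used by default panels.
DEFAULT_MIXTURE = MixtureParams(pi_minus=0.0, pi_zero=0.769, pi_plus=0.231, mu_z=1.003)

#: The audited variant: the CCR5 32-bp deletion as imputed in UK Biobank
#: (GRCh37 coordinates; the deletion is the short allele).
DEFAULT_VARIANT = VariantKey(
    chrom="3",
    pos=46414943,
    ref="TACAGTCAGTATCAATTCTGGAAGAATTTCCAG",
    alt="T",
    info_score=0.838,
)


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for a synthetic phenotype panel.

    ``prevalence_range`` spans curated biobank diseases from the
    1000-case floor (about 0.3% of the cohort) up to common conditions.
    """

    n_phenotypes: int = 131
    prevalence_range: tuple[float, float] = (0.003, 0.2)
    eaf: float = 0.092
    n_samples: int = 361194
    mixture: MixtureParams = DEFAULT_MIXTURE
    seed: int | None = 0

    def __post_init__(self) -> None:
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"prevalence_range must lie within (0, 1), got {self.prevalence_range}")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_phenotypes < 1:
            raise ValueError("n_phenotypes must be >= 1")


def gen_phenotype_panel(
    spec: PanelSpec = PanelSpec(),
) -> tuple[list[AssocStat], list[PhenotypeMeta], dict]:
    """Simulate one variant's summary statistics across a disease panel.

    For each phenotype: prevalence K is uniform over the configured range; the
    observed-scale SE implied by the linear-dosage design is
    ``sqrt(K (1 - K) / (n * 2 f (1 - f)))``; the true standardized effect Z
    is drawn from the mixture and the observed beta set to ``Z * se`` (the
    sampling noise of the GWAS estimate is embodied in Z's unit component
    variance); the p-value is the two-sided normal tail of Z.

    Returns associations (oriented to the target allele), phenotype
    metadata, and a ground-truth record with the drawn components and Z
    scores for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.prevalence_range
    prevalence = rng.uniform(lo, hi, spec.n_phenotypes)
    comp = rng.choice(3, size=spec.n_phenotypes, p=spec.mixture.weights)
    means = np.array([-spec.mixture.mu_z, 0.0, spec.mixture.mu_z])
    z = rng.normal(loc=means[comp], scale=1.0)

    f = spec.eaf
    se = np.sqrt(prevalence * (1.0 - prevalence) / (spec.n_samples * 2.0 * f * (1.0 - f)))
    beta = z * se
    pvals = np.clip(2.0 * norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)

    assocs: list[AssocStat] = []
    metas: list[PhenotypeMeta] = []
    for i in range(spec.n_phenotypes):
        pid = f"D{i + 1:03d}"
        n_cases = max(1, int(round(prevalence[i] * spec.n_samples)))
        metas.append(
            PhenotypeMeta(
                phenotype_id=pid,
                name=f"synthetic disease {i + 1}",
                n_cases=n_cases,
                n_controls=spec.n_samples - n_cases,
            )
        )
        assocs.append(
            AssocStat(
                variant=DEFAULT_VARIANT,
                phenotype_id=pid,
                effect_allele=DEFAULT_VARIANT.alt,
                eaf=f,
                n=spec.n_samples,
                beta_obs=float(beta[i]),
                se_obs=float(se[i]),
                p=float(pvals[i]),
            )
        )
    truth = {
        "mixture": spec.mixture.as_dict(),
        "seed": spec.seed,
        "component": (comp - 1).tolist(),  # -1 protective, 0 null, +1 harmful
        "z": z.tolist(),
        "prevalence": prevalence.tolist(),
    }
    return assocs, metas, truth


def gen_pvalue_matrix(
    n_snps: int,
    n_phen: int,
    base_rate: float,
    enriched_sets: Mapping[str, tuple[int, float]] | None = None,
    seed: int | None = 0,
    threshold: float = 5e-4,
) -> tuple[PValueMatrix, list[LocusSet]]:
    """Simulate a sparse SNP x phenotype p-value matrix.

    Each entry is an association with its row's rate (p uniform below
    ``threshold``) and null otherwise (p uniform on (threshold, 1]).
    ``enriched_sets`` maps a disease name to ``(set_size, rate)``; each set
    claims distinct SNPs whose rows use the elevated rate. MAFs are uniform
    on (0.01, 0.5).
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError(f"base_rate must be in [0, 1], got {base_rate}")
    rng = np.random.default_rng(seed)
    snp_ids = tuple(f"rs{i + 1}" for i in range(n_snps))
    phen_ids = tuple(f"P{j + 1:03d}" for j in range(n_phen))

    rates = np.full(n_snps, base_rate)
    sets: list[LocusSet] = []
    cursor = 0
    for disease, (size, rate) in (enriched_sets or {}).items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {disease!r} must be in [0, 1], got {rate}")
        if cursor + size > n_snps:
            raise ValueError("enriched sets request more SNPs than the matrix has")
        idx = slice(cursor, cursor + size)
        rates[idx] = rate
        sets.append(LocusSet(disease=disease, snp_ids=snp_ids[idx]))
        cursor += size

    hit = rng.random((n_snps, n_phen)) < rates[:, None]
    p = np.where(
        hit,
        rng.uniform(np.nextafter(0.0, 1.0), threshold, (n_snps, n_phen)),
        rng.uniform(threshold, 1.0, (n_snps, n_phen)),
    )
    maf = rng.uniform(0.01, 0.5, n_snps)
    return PValueMatrix(snp_ids=snp_ids, phen_ids=phen_ids, p=p, maf=maf), sets


def gen_genotype_table(
    or_true: float,
    eaf: float,
    n_cases: int,
    n_controls: int,
    seed: int | None = 0,
) -> GenotypeCountTable:
    """Simulate a case/control genotype table with a per-allele odds-ratio tilt.

    Controls follow Hardy-Weinberg proportions at the variant-allele
    frequency; case genotype probabilities are the control proportions
    tilted by ``or_true ** dose`` and renormalized (the standard logistic
    allele-dose model for a rare disease). Counts are multinomial draws.
    """
    if or_true <= 0.0:
        raise ValueError(f"or_true must be positive, got {or_true}")
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    rng = np.random.default_rng(seed)
    f = eaf
    hwe = np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])
    tilt = hwe * np.power(or_true, [0.0, 1.0, 2.0])
    case_probs = tilt / tilt.sum()
    cases = rng.multinomial(n_cases, case_probs)
    controls = rng.multinomial(n_controls, hwe)
    return GenotypeCountTable(cases=tuple(int(c) for c in cases), controls=tuple(int(c) for c in controls))
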