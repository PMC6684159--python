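"""Observed-scale to odds-ratio conversion for binary-trait GWAS effects.

A linear regression of a 0/1 disease indicator on allele dosage yields an
"observed-scale" effect ``beta_obs`` whose size depends on disease prevalence,
which makes effects incomparable across diseases. For a variant explaining a
small fraction of phenotypic variance, ``beta_obs`` together with the cohort
prevalence K and the effect-allele frequency f is sufficient to recover the
allelic odds ratio: under Hardy-Weinberg genotype frequencies and the linear
risk model ``P(case | dose g) = mu + beta_obs * g`` with marginal prevalence
K (so ``mu = K - 2 f beta_obs``), the expected allele-by-status 2x2 table has
per-allele case probabilities

    p1 = K + beta_obs * (1 - f)   (effect allele)
    p0 = K - beta_obs * f         (other allele)

and the log odds ratio is the cross-product ratio
``log[p1 (1 - p0)] - log[p0 (1 - p1)]``.

The delta-method standard error propagates ``se_obs`` through the analytic
derivative of that expression; at ``beta_obs = 0`` the derivative is
``1 / (K (1 - K))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .sumstats import AssocStat, PhenotypeMeta

logger = logging.getLogger(__name__)

__all__ = [
    "TransformedEffect",
    "ScaleDomainError",
    "obs_beta_to_logor",
    "se_logor_delta",
    "z_score",
    "batch_transform",
    "effects_frame",
    "write_effects",
]


class ScaleDomainError(ValueError):
    """The implied per-allele case probabilities leave (0, 1)."""


@dataclass(frozen=True)
class TransformedEffect:
    """One association expressed on the log-odds-ratio scale."""

    phenotype_id: str
    logor: float
    or_: float
    se_logor: float
    z: float
    p: float

    @property
    def harmful(self) -> bool:
        """True when the target allele raises risk (logor > 0)."""
        return self.logor > 0.0


def _allele_case_probs(beta_obs: float, eaf: float, prevalence: float) -> tuple[float, float]:
    if not 0.0 < prevalence < 1.0:
        raise ScaleDomainError(f"prevalence must be in (0, 1), got {prevalence}")
    if not 0.0 < eaf < 1.0:
        raise ScaleDomainError(f"eaf must be in (0, 1), got {eaf}")
    p1 = prevalence + beta_obs * (1.0 - eaf)
    p0 = prevalence - beta_obs * eaf
    if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
        raise ScaleDomainError(
            "effect too large for given prevalence/frequency: "
            f"beta_obs={beta_obs}, eaf={eaf}, K={prevalence} gives p1={p1}, p0={p0}"
        )
    return p1, p0


def obs_beta_to_logor(beta_obs: float, eaf: float, prevalence: float) -> float:
    """Convert an observed-scale effect to a per-allele log odds ratio.

    Parameters
    ----------
    beta_obs
        Linear-model effect of one effect-allele copy on the 0/1 outcome.
    eaf
        Effect-allele frequency, in (0, 1).
    prevalence
        Marginal case fraction K of the cohort, in (0, 1).
    """
    p1, p0 = _allele_case_probs(beta_obs, eaf, prevalence)
    if beta_obs == 0.0:
        return 0.0
    return math.log(p1) + math.log1p(-p0) - math.log(p0) - math.log1p(-p1)


def se_logor_delta(beta_obs: float, se_obs: float, eaf: float, prevalence: float) -> float:
    """Delta-method SE of the log odds ratio.

    Uses d(logOR)/d(beta_obs) = (1-f)/(p1(1-p1)) + f/(p0(1-p0)), which
    reduces to 1/(K(1-K)) at beta_obs = 0.
    """
    if se_obs <= 0.0:
        raise ScaleDomainError(f"se_obs must be positive, got {se_obs}")
    p1, p0 = _allele_case_probs(beta_obs, eaf, prevalence)
    deriv = (1.0 - eaf) / (p1 * (1.0 - p1)) + eaf / (p0 * (1.0 - p0))
    return se_obs * abs(deriv)


def z_score(beta_obs: float, se_obs: float) -> float:
    """Standardized effect beta_obs / se_obs; N(0,1) under the null."""
    if se_obs <= 0.0:
        raise ScaleDomainError(f"se_obs must be positive, got {se_obs}")
    return beta_obs / se_obs


def batch_transform(
    assocs: Sequence[AssocStat],
    metas: Sequence[PhenotypeMeta],
    errors: Literal["raise", "collect"] = "raise",
) -> list[TransformedEffect]:
    """Transform a panel of oriented associations to the odds-ratio scale.

    Z scores are computed on the observed scale (the GWAS beta/SE) and source
    p-values are carried through unchanged. With ``errors="collect"``,
    per-record domain failures are logged and the record dropped; with
    ``"raise"`` the first failure aborts with the phenotype id attached.
    """
    by_id = {m.phenotype_id: m for m in metas}
    out: list[TransformedEffect] = []
    for a in assocs:
        meta = by_id.get(a.phenotype_id)
        if meta is None:
            raise KeyError(f"no phenotype metadata for {a.phenotype_id!r}")
        try:
            logor = obs_beta_to_logor(a.beta_obs, a.eaf, meta.prevalence)
            se = se_logor_delta(a.beta_obs, a.se_obs, a.eaf, meta.prevalence)
        except ScaleDomainError as exc:
            if errors == "raise":
                raise ScaleDomainError(f"phenotype {a.phenotype_id!r}: {exc}") from exc
            logger.warning("dropping phenotype %s: %s", a.phenotype_id, exc)
            continue
        out.append(
            TransformedEffect(
                phenotype_id=a.phenotype_id,
                logor=logor,
                or_=math.exp(logor),
                se_logor=se,
                z=z_score(a.beta_obs, a.se_obs),
                p=a.p,
            )
        )
    return out


def effects_frame(
    effects: Iterable[TransformedEffect],
    assocs: Sequence[AssocStat] | None = None,
    metas: Sequence[PhenotypeMeta] | None = None,
) -> pd.DataFrame:
    """Tabulate transformed effects, optionally joined with source stats and metadata."""
    df = pd.DataFrame(
        [
            {
                "phenotype_id": e.phenotype_id,
                "logor": e.logor,
                "or": e.or_,
                "se_logor": e.se_logor,
                "z": e.z,
                "p": e.p,
                "harmful": e.harmful,
            }
            for e in effects
        ]
    )
    if assocs is not None:
        src = pd.DataFrame(
            [{"phenotype_id": a.phenotype_id, "beta_obs": a.beta_obs, "se_obs": a.se_obs} for a in assocs]
        )
        df = src.merge(df, on="phenotype_id", how="right")
    if metas is not None:
        meta = pd.DataFrame(
            [
                {
                    "phenotype_id": m.phenotype_id,
                    "name": m.name,
                    "n_cases": m.n_cases,
                    "prevalence": m.prevalence,
                }
                for m in metas
            ]
        )
        df = meta.merge(df, on="phenotype_id", how="right")
    return df


def write_effects(
    path: str | Path,
    effects: Iterable[TransformedEffect],
    assocs: Sequence[AssocStat] | None = None,
    metas: Sequence[PhenotypeMeta] | None = None,
) -> None:
    effects_frame(effects, assocs, metas).to_csv(path, sep="\t", index=False)
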