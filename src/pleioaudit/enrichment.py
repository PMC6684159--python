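"""Direction counts, signed-rank enrichment, FDR labeling and QQ coordinates.

Operates on a panel of per-disease log odds ratios for a single variant:
counts how many diseases the target allele harms versus protects, tests the
symmetry of the signed effects around zero (Wilcoxon signed-rank, normal
approximation with continuity correction), labels diseases at a chosen
Benjamini-Hochberg false-discovery rate, and emits quantile-quantile plot
coordinates for the association p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .scale import TransformedEffect

__all__ = [
    "DirectionCounts",
    "EnrichmentReport",
    "direction_counts",
    "signed_rank_test",
    "bh_fdr",
    "qq_coordinates",
    "enrichment_report",
]


class DirectionCounts(NamedTuple):
    n_harmful: int
    n_protective: int
    n_zero: int


def _as_logor_array(effects) -> np.ndarray:
    if len(effects) and isinstance(effects[0], TransformedEffect):
        return np.array([e.logor for e in effects], dtype=float)
    return np.asarray(effects, dtype=float)


def direction_counts(effects: Sequence[TransformedEffect] | Sequence[float]) -> DirectionCounts:
    """Count risk-raising (logOR > 0), protective (< 0) and exactly-zero effects.

    Counts are by sign alone, regardless of statistical significance.
    """
    v = _as_logor_array(effects)
    if v.size == 0:
        raise ValueError("need at least one effect")
    return DirectionCounts(int((v > 0).sum()), int((v < 0).sum()), int((v == 0).sum()))


def signed_rank_test(values: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value against symmetry about zero.

    Normal approximation with continuity correction (+/- 0.5) and
    average-rank tie handling; exact zeros are dropped beforehand, per the
    standard (zeros-dropped) variant of the test.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    if v.size == 0:
        raise ValueError("signed-rank test undefined: all values are zero")
    res = wilcoxon(v, zero_method="wilcox", correction=True, alternative="two-sided", method="approx")
    return float(res.pvalue)


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone-adjusted q-values and reject flags.

    Rejects all hypotheses up to the largest rank i with p_(i) <= q * i / m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p <= 0.0) | np.any(p > 1.0) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvalues, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvalues, reject


def qq_coordinates(pvals: Sequence[float]) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a QQ plot, aligned by rank.

    The expected quantile for the i-th smallest of m p-values is
    -log10((i - 0.5) / m). Rows are ordered by ascending expected value.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    i = np.arange(1, m + 1)
    expected = -np.log10((i - 0.5) / m)  # decreasing in i
    observed = -np.log10(np.sort(p))  # rank 1 = smallest p = largest -log10
    return np.column_stack([expected[::-1], observed[::-1]])


@dataclass(frozen=True)
class EnrichmentReport:
    """Panel-level summary of effect directions and significance."""

    n_harmful: int
    n_protective: int
    n_zero: int
    wilcoxon_p: float
    fdr_q: float
    fdr_hits: tuple[str, ...]
    qvalues: Mapping[str, float]

    def as_dict(self) -> dict:
        return {
            "n_harmful": self.n_harmful,
            "n_protective": self.n_protective,
            "n_zero": self.n_zero,
            "wilcoxon_p": self.wilcoxon_p,
            "fdr_q": self.fdr_q,
            "fdr_hits": list(self.fdr_hits),
            "qvalues": dict(self.qvalues),
        }


def enrichment_report(
    effects: Sequence[TransformedEffect],
    q: float = 0.05,
    extra_pvals: Mapping[str, float] | None = None,
) -> EnrichmentReport:
    """Build the full enrichment summary for a panel of transformed effects.

    ``extra_pvals`` admits externally-derived associations (e.g. a disease
    studied outside the biobank) into the FDR computation without affecting
    the direction counts or the signed-rank test.
    """
    counts = direction_counts(effects)
    wp = signed_rank_test([e.logor for e in effects])
    ids = [e.phenotype_id for e in effects]
    pv = [e.p for e in effects]
    if extra_pvals:
        ids += list(extra_pvals.keys())
        pv += list(extra_pvals.values())
    qvalues, reject = bh_fdr(pv, q=q)
    hits = tuple(i for i, r in zip(ids, reject) if r)
    return EnrichmentReport(
        n_harmful=counts.n_harmful,
        n_protective=counts.n_protective,
        n_zero=counts.n_zero,
        wilcoxon_p=wp,
        fdr_q=q,
        fdr_hits=hits,
        qvalues=dict(zip(ids, qvalues.tolist())),
    )
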