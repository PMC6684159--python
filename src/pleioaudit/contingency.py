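"""Allele-dose logistic regression on genotype-count contingency tables.

For a case/control study summarized as counts over the three genotype
classes (wildtype homozygote, heterozygote, variant homozygote), the
per-allele odds ratio is estimated by maximum-likelihood logistic regression
of case status on allele dose g in {0, 1, 2} using the grouped counts. This
is the standard re-analysis route for published tables such as the 1996
case/control study in which the CCR5 32-bp deletion was first reported:
there, with zero deletion-homozygote cases, the genotypic model separates
but the additive dose model remains estimable.

The grouped fit goes through statsmodels' binomial GLM; a Jeffreys-prior
penalized (Firth) fit is available as an option for separated tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "GenotypeCountTable",
    "OrResult",
    "SeparationError",
    "allelic_logistic_or",
    "allele_2x2_from_genotypes",
    "odds_ratio_2x2",
]

_DOSES = np.array([0.0, 1.0, 2.0])


class SeparationError(RuntimeError):
    """The dose-response likelihood is maximized at infinite slope."""


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control counts by genotype class (wildtype hom, het, variant hom)."""

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]

    def __post_init__(self) -> None:
        counts = (*self.cases, *self.controls)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")
        if sum(self.cases) < 1 or sum(self.controls) < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    @classmethod
    def from_json(cls, path: str | Path) -> "GenotypeCountTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(cases=tuple(d["cases"]), controls=tuple(d["controls"]))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"cases": list(self.cases), "controls": list(self.controls)}, fh, indent=1)


@dataclass(frozen=True)
class OrResult:
    """Per-allele odds ratio with log-scale SE, Wald p and normal 95% CI."""

    or_: float
    logor: float
    se_logor: float
    p: float
    ci_low: float
    ci_high: float
    method: str

    def as_dict(self) -> dict:
        return {
            "or": self.or_,
            "logor": self.logor,
            "se_logor": self.se_logor,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
        }


def _firth_fit(y: np.ndarray, n: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Jeffreys-penalized logistic fit on grouped binomial data (Firth, 1993).

    Newton iterations on the penalized score U*(b) = X'(y - n*pi + h*(0.5 - pi))
    where h are leverages of sqrt(W) X (X'WX)^-1 X' sqrt(W), W = n pi (1-pi).
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = n * pi * (1.0 - pi)
        XtWX = X.T @ (w[:, None] * X)
        XtWX_inv = np.linalg.inv(XtWX)
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * w
        score = X.T @ (y - n * pi + h * (0.5 - pi))
        step = XtWX_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = n * pi * (1.0 - pi)
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    return beta, np.sqrt(np.diag(cov))


def allelic_logistic_or(table: GenotypeCountTable, firth: bool = False) -> OrResult:
    """Per-allele (additive dose) odds ratio from a 2x3 genotype table.

    Fits case status on variant-allele dose by grouped maximum-likelihood
    logistic regression; empty genotype classes are simply absent rows and
    the fit proceeds on the remaining classes. Complete separation along the
    dose gradient raises :class:`SeparationError` (use ``firth=True`` for a
    finite penalized estimate).
    """
    cases = np.asarray(table.cases, dtype=float)
    controls = np.asarray(table.controls, dtype=float)
    total = cases + controls
    keep = total > 0
    if keep.sum() < 2 or np.ptp(_DOSES[keep]) == 0:
        raise ValueError("allele-dose design has no variance: need counts in >= 2 genotype classes")
    y, n, dose = cases[keep], total[keep], _DOSES[keep]
    X = np.column_stack([np.ones_like(dose), dose])
    if firth:
        beta, bse = _firth_fit(y, n, X)
        slope, se = float(beta[1]), float(bse[1])
        method = "firth"
    else:
        with warnings.catch_warnings():
            # separation is detected and surfaced below, not via warnings
            warnings.simplefilter("ignore")
            res = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        method = "ml"
        if abs(slope) > 15.0 or not math.isfinite(se) or se > 50.0:
            raise SeparationError(
                "complete separation along allele dose: "
                f"slope={slope:.3g}, se={se:.3g}; cases={table.cases}, controls={table.controls}"
            )
    p = float(2.0 * norm.sf(abs(slope) / se)) if slope != 0.0 else 1.0
    half = 1.959963984540054 * se
    return OrResult(
        or_=math.exp(slope),
        logor=slope,
        se_logor=se,
        p=p,
        ci_low=math.exp(slope - half),
        ci_high=math.exp(slope + half),
        method=method,
    )


def allele_2x2_from_genotypes(table: GenotypeCountTable) -> np.ndarray:
    """Collapse genotype counts to a case/control x (variant, other) allele table.

    Each variant homozygote contributes two variant alleles, each
    heterozygote one of each; total alleles = 2 x total individuals.
    """
    out = np.empty((2, 2), dtype=int)
    for i, row in enumerate((table.cases, table.controls)):
        wt, het, hom = row
        out[i, 0] = 2 * hom + het
        out[i, 1] = 2 * wt + het
    return out


def odds_ratio_2x2(counts: np.ndarray) -> float:
    """Cross-product odds ratio of a 2x2 table [[a, b], [c, d]] -> (a d)/(b c)."""
    a, b = float(counts[0, 0]), float(counts[0, 1])
    c, d = float(counts[1, 0]), float(counts[1, 1])
    if min(a, b, c, d) == 0.0:
        raise ZeroDivisionError("2x2 odds ratio undefined with an empty cell")
    return (a * d) / (b * c)
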