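"""Configuration-driven orchestration of the full pleiotropy audit.

One call runs ingest -> allele orientation -> curation filter -> scale
transformation -> mixture fit with bootstrap -> enrichment summary, and
writes a plain-text report bundle (TSV/JSON only, no timestamps inside the
analytical payloads) that is byte-identical across reruns with the same
configuration and seed. Every output carries the seed and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrichment_report, qq_coordinates
from .mixture import SymmetricZMixture, bootstrap_inference, expected_affected, fit_mixture
from .scale import batch_transform, write_effects
from .sumstats import (
    DIALECTS,
    filter_curated,
    orient_to_target_allele,
    read_phenotype_manifest,
    read_sumstats,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_audit"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and tuning knobs of one audit run."""

    sumstats: str
    manifest: str
    out_dir: str
    target_allele: str
    dialect: str = "canonical"
    min_cases: int = 1000
    fdr_q: float = 0.05
    n_restarts: int = 20
    n_boot: int = 1000
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if self.min_cases < 0:
            raise ValueError("min_cases must be non-negative")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; choose from {sorted(DIALECTS)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"pleioaudit_version": __version__, "seed": config.seed, "config_hash": config.config_hash()}


def run_audit(config: RunConfig) -> dict:
    """Run the audit end to end and write the report bundle.

    Outputs under ``config.out_dir``: ``effects.tsv`` (per-disease odds
    ratios), ``mixture.json`` (mixture fit with bootstrap inference),
    ``posteriors.tsv`` (per-phenotype soft component assignments),
    ``enrichment.json`` (direction counts, signed-rank p, FDR hits),
    ``qq.tsv`` (QQ-plot coordinates) and ``config.json``. Returns the
    summary as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    assocs = read_sumstats(config.sumstats, dialect=DIALECTS[config.dialect])
    logger.info("audit: read %d associations", len(assocs))
    assocs = [orient_to_target_allele(a, config.target_allele) for a in assocs]
    metas = read_phenotype_manifest(config.manifest)
    assocs = filter_curated(assocs, metas, min_cases=config.min_cases)
    logger.info("audit: %d associations after curation (min_cases=%d)", len(assocs), config.min_cases)

    effects = batch_transform(assocs, metas)
    write_effects(out / "effects.tsv", effects, assocs=assocs, metas=metas)

    z = [e.z for e in effects]
    fit = fit_mixture(z, n_restarts=config.n_restarts, seed=config.seed, tol=config.tol)
    fit = bootstrap_inference(z, fit, n_boot=config.n_boot, seed=config.seed)
    expected, rounded = expected_affected(fit.params, len(effects))

    est = SymmetricZMixture(n_restarts=config.n_restarts, random_state=config.seed, tol=config.tol).fit(z)
    post = est.predict_proba(z)
    pd.DataFrame(
        {
            "phenotype_id": [e.phenotype_id for e in effects],
            "z": z,
            "p_protective": post[:, 0],
            "p_null": post[:, 1],
            "p_harmful": post[:, 2],
        }
    ).to_csv(out / "posteriors.tsv", sep="\t", index=False)

    mixture_payload = {
        **_provenance(config),
        **fit.as_dict(),
        "expected_affected": expected,
        "expected_affected_rounded": rounded,
    }
    (out / "mixture.json").write_text(json.dumps(mixture_payload, indent=1, sort_keys=True))

    report = enrichment_report(effects, q=config.fdr_q)
    enrichment_payload = {**_provenance(config), **report.as_dict()}
    (out / "enrichment.json").write_text(json.dumps(enrichment_payload, indent=1, sort_keys=True))

    qq = qq_coordinates([e.p for e in effects])
    pd.DataFrame(qq, columns=["expected_neglog10p", "observed_neglog10p"]).to_csv(
        out / "qq.tsv", sep="\t", index=False
    )
    (out / "config.json").write_text(
        json.dumps({**dataclasses.asdict(config), **_provenance(config)}, indent=1, sort_keys=True)
    )
    return {"mixture": mixture_payload, "enrichment": enrichment_payload, "n_phenotypes": len(effects)}
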