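"""End-to-end orchestration: expression -> modules -> interesting genes.

The pipeline mirrors the workflow the package automates: preprocess the
expression matrix, compute the similarity matrix, extract modules by
threshold decrement, pool border genes, rank them by differential
expression, map identifiers, build the semantic matrix, apply the beta
filter, and enrich each module against the ontology.  It is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .enrichment import enrich_all_modules
from .extract import THDConfig, ThresholdDecrementExtractor, modules_to_frame
from .interesting import BorderGenePrioritizer
from .io import ExpressionMatrix, preprocess
from .ontology import AnnotationIndex


@dataclass
class PipelineResult:
    preprocess_report: object
    extractor: ThresholdDecrementExtractor
    prioritizer: BorderGenePrioritizer | None
    enrichment: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(expression: ExpressionMatrix,
                 annotations: AnnotationIndex | None = None,
                 mapping: pd.DataFrame | None = None,
                 config: THDConfig | None = None,
                 k: int = 2000,
                 measure: str = "abspearson",
                 combine: str = "bma",
                 de_stat: str = "variance",
                 rule: str = "any",
                 with_enrichment: bool = True,
                 seed: int = 0) -> PipelineResult:
    """Run every stage; stages needing annotations are skipped without them."""
    cfg = config or THDConfig()
    clean, report = preprocess(expression)
    extractor = ThresholdDecrementExtractor(
        delta_start=cfg.delta_start, delta_end=cfg.delta_end, alpha=cfg.alpha,
        rho=cfg.rho, measure=measure, degree_scope=cfg.degree_scope)
    extractor.fit(clean.data)

    prioritizer = None
    enrichment = None
    if annotations is not None:
        border = sorted(extractor.border_pool_)
        if len(border) >= 2 and clean.sample_class is not None:
            prioritizer = BorderGenePrioritizer(
                k=k, de_stat=de_stat, combine=combine, rule=rule)
            prioritizer.fit(border, clean, annotations, mapping=mapping,
                            provenance=extractor.border_provenance_)
        if with_enrichment:
            enrichment = enrich_all_modules(extractor.modules_, annotations)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": asdict(cfg),
        "k": k,
        "measure": measure,
        "combine": combine,
        "de_stat": de_stat,
        "rule": rule,
        "counts": {
            "genes_in": expression.shape[0],
            "genes_removed": report.total_removed,
            "genes_clustered": clean.shape[0],
            "modules": len(extractor.modules_),
            "unassigned": len(extractor.unassigned_),
            "border_pool": len(extractor.border_pool_),
            "interesting": (len(prioritizer.interesting_)
                            if prioritizer is not None else None),
        },
        "beta": prioritizer.beta_ if prioritizer is not None else None,
    }
    return PipelineResult(preprocess_report=report, extractor=extractor,
                          prioritizer=prioritizer, enrichment=enrichment,
                          manifest=manifest)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def modules_table(result: PipelineResult) -> pd.DataFrame:
    return modules_to_frame(result.extractor.modules_,
                            result.extractor.unassigned_)
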