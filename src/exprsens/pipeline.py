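"""End-to-end orchestration: filter -> floor/log -> collapse -> CV -> rank ->
SV -> tail classification -> enrichment.

`run_pipeline` is the in-memory engine; the CLI wraps it with file I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import classify_tails
from .datatypes import (
    EnrichmentResult,
    ExpressionDataset,
    GeneGroupCollection,
    ProbeMap,
    SensitivityTable,
    TailClassification,
)
from .enrich import hypergeom_enrich
from .preprocess import PreprocessConfig, collapse_probes, filter_datasets, floor_and_log
from .sensitivity import SensitivityConfig, build_sensitivity_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    table: SensitivityTable
    classification: TailClassification
    enrichment: list[EnrichmentResult] = field(default_factory=list)


def preprocess_collection(
    datasets: list[ExpressionDataset],
    probe_map: ProbeMap,
    config: PreprocessConfig | None = None,
) -> list[ExpressionDataset]:
    """Filter raw datasets, floor-and-log them, and collapse probes to genes."""
    config = config or PreprocessConfig()
    kept = filter_datasets(datasets, config)
    logger.info("retained %d of %d datasets", len(kept), len(datasets))
    return [
        collapse_probes(floor_and_log(ds, config), probe_map, config)
        for ds in kept
    ]


def run_pipeline(
    datasets: list[ExpressionDataset],
    probe_map: ProbeMap,
    groups: GeneGroupCollection | None = None,
    preprocess_config: PreprocessConfig | None = None,
    sensitivity_config: SensitivityConfig | None = None,
    cutoff_fraction: float = 0.05,
) -> PipelineResult:
    """Run the whole analysis on raw probe-level datasets.

    Returns the sensitivity table, the tail classification, and (when gene
    groups are supplied) the enrichment results.
    """
    gene_level = preprocess_collection(datasets, probe_map, preprocess_config)
    table = build_sensitivity_table(gene_level, sensitivity_config)
    classification = classify_tails(table, cutoff_fraction)
    logger.info(
        "classified %d genes: %d robust, %d sensitive",
        classification.universe_size,
        classification.n_robust,
        classification.n_sensitive,
    )
    enrichment: list[EnrichmentResult] = []
    if groups is not None:
        enrichment = hypergeom_enrich(classification, groups)
    return PipelineResult(table, classification, enrichment)
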