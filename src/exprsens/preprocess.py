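"""Preprocessing: dataset filtering, intensity flooring, log transform, and
collapse of multi-probe genes to gene-level expression.

The fixed stage order is filter -> floor/log -> collapse. Flooring clamps
raw intensities at ``floor_value`` (default 10) before taking logs, so the
minimum possible log2 value under defaults is log2(10) ~ 3.3219 and every
gene mean is strictly positive — which is what makes the downstream
coefficient of variation well defined. Collapse takes, for each gene and
each sample, the maximum over that gene's probes; since the log transform is
monotone, the per-sample maximum commutes with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, ProbeMap
from .errors import ConfigurationError, PipelineError, StateError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    min_samples:
        Datasets with fewer arrays are discarded (default 6; the sample SD
        needs at least 2).
    floor_value:
        Raw intensities below this are raised to it before the log (default 10).
    log_base:
        Base of the log transform (default 2).
    collapse_method:
        ``per_sample_max`` takes the max over a gene's probes independently in
        each sample (default); ``max_mean_probe`` keeps the whole row of the
        probe with the highest mean.
    """

    min_samples: int = 6
    floor_value: float = 10.0
    log_base: float = 2.0
    collapse_method: str = "per_sample_max"

    def validate(self) -> None:
        if self.min_samples < 2:
            raise ConfigurationError("min_samples must be >= 2 (SD needs 2 samples)")
        if self.floor_value <= 0:
            raise ConfigurationError("floor_value must be positive")
        if self.log_base <= 1:
            raise ConfigurationError("log_base must be > 1")
        if self.collapse_method not in ("per_sample_max", "max_mean_probe"):
            raise ConfigurationError(
                f"unknown collapse_method {self.collapse_method!r}"
            )


def filter_datasets(
    datasets: list[ExpressionDataset],
    config: PreprocessConfig | None = None,
) -> list[ExpressionDataset]:
    """Keep datasets with at least ``min_samples`` arrays; log each discard."""
    config = config or PreprocessConfig()
    config.validate()
    kept: list[ExpressionDataset] = []
    for ds in datasets:
        if ds.n_samples >= config.min_samples:
            kept.append(ds)
        else:
            logger.info(
                "discarding dataset %s: %d arrays < %d",
                ds.dataset_id, ds.n_samples, config.min_samples,
            )
    if not kept:
        raise PipelineError("no datasets survive the minimum-sample filter")
    return kept


def floor_and_log(
    dataset: ExpressionDataset,
    config: PreprocessConfig | None = None,
) -> ExpressionDataset:
    """Clamp raw values at the floor, then log-transform.

    Every value v becomes log_base(max(v, floor_value)). Raises
    :class:`StateError` if the dataset is already log-transformed.
    """
    config = config or PreprocessConfig()
    config.validate()
    if dataset.log_transformed:
        raise StateError(
            f"dataset {dataset.dataset_id!r} is already log-transformed"
        )
    clamped = np.maximum(dataset.values.to_numpy(), config.floor_value)
    logged = np.log(clamped) / math.log(config.log_base)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        values=pd.DataFrame(
            logged, index=dataset.values.index, columns=dataset.values.columns
        ),
        log_transformed=True,
    )


def collapse_probes(
    dataset: ExpressionDataset,
    probe_map: ProbeMap,
    config: PreprocessConfig | None = None,
) -> ExpressionDataset:
    """Reduce probe rows to one row per gene.

    Probes absent from the map are dropped (with a logged count). With the
    default ``per_sample_max`` method, each gene/sample cell is the maximum
    over that gene's probes in that sample; ``max_mean_probe`` instead keeps
    the full row of the probe with the highest mean (ties broken by probe
    ID). Gene rows are ordered lexicographically.
    """
    config = config or PreprocessConfig()
    config.validate()
    if not dataset.log_transformed:
        raise StateError(
            f"dataset {dataset.dataset_id!r}: collapse_probes expects "
            "log-transformed data (run floor_and_log first)"
        )
    mapped = [p for p in dataset.probe_ids if p in probe_map.entries]
    n_dropped = dataset.n_probes - len(mapped)
    if n_dropped:
        logger.info(
            "dataset %s: dropping %d unmapped probe(s)",
            dataset.dataset_id, n_dropped,
        )
    if not mapped:
        raise PipelineError(
            f"dataset {dataset.dataset_id!r}: no probe maps to any gene"
        )
    sub = dataset.values.loc[mapped]
    gene_of = pd.Series([probe_map.entries[p] for p in mapped], index=sub.index)
    if config.collapse_method == "per_sample_max":
        collapsed = sub.groupby(gene_of, sort=True).max()
    else:  # max_mean_probe
        means = sub.mean(axis=1)
        rows = {}
        for gene, probes in sorted(gene_of.groupby(gene_of).groups.items()):
            best = means.loc[list(probes)].sort_index().idxmax()
            rows[gene] = sub.loc[best]
        collapsed = pd.DataFrame(rows).T.sort_index()
        collapsed.columns = sub.columns
    collapsed.index.name = "gene"
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, values=collapsed, log_transformed=True
    )
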