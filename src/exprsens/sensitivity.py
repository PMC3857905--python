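"""Coefficient-of-variation profiling and rank-mean sensitive values.

For gene i in dataset j the coefficient of variation is

    CV_ij = SD(g_ij) / mean(g_ij)

with the sample (n-1) standard deviation, computed by default on the
floored, log2-transformed expression values. CVs are ranked ascending
within each dataset (rank 1 = most stable gene, ties averaged) and the
sensitive value of a gene is the mean of its ranks over the M datasets in
which it is measured:

    SV_i = ( sum_j rank(CV_ij) ) / M_i

A low SV marks a gene whose expression is consistently stable across
studies ("robust"); a high SV marks a readily perturbed ("sensitive")
gene. Ranking within datasets is what harmonizes studies of different
scale and noise level — no further batch correction is applied.

Genes measured in fewer than ``min_coverage_fraction * M`` datasets are
excluded from the SV ranking (on a single platform every gene is measured
everywhere, making M_i = M and the exclusion vacuous; it only matters when
datasets over different gene universes are mixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionDataset, SensitivityTable
from .errors import ConfigurationError, NumericError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class SensitivityConfig:
    """Parameters of the CV/SV computation.

    cv_scale:
        ``log`` (default) computes CV on the log-transformed values the
        preprocessing emits; ``raw`` back-transforms to the floored raw scale
        first (CV on a log scale is unconventional, so both are offered).
    min_coverage_fraction:
        A gene must be measured in at least this fraction of datasets to
        receive an SV (default 0.5).
    tie_method:
        Rank ties receive the average of the tied positions (the only
        supported method; it preserves the rank-sum invariant).
    """

    cv_scale: str = "log"
    min_coverage_fraction: float = 0.5
    tie_method: str = "average"

    def validate(self) -> None:
        if self.cv_scale not in ("log", "raw"):
            raise ConfigurationError(f"unknown cv_scale {self.cv_scale!r}")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ConfigurationError("min_coverage_fraction must be in (0, 1]")
        if self.tie_method != "average":
            raise ConfigurationError("tie_method must be 'average'")


def compute_cv(
    dataset: ExpressionDataset,
    config: SensitivityConfig | None = None,
) -> pd.Series:
    """Per-gene CV = sample SD / mean for one gene-level dataset.

    Raises :class:`NumericError` naming the first offending gene if any mean
    is non-positive (cannot happen after default preprocessing, where the
    floor guarantees values >= log2(10)).
    """
    config = config or SensitivityConfig()
    config.validate()
    if dataset.n_samples < 2:
        raise PipelineError(
            f"dataset {dataset.dataset_id!r}: CV needs at least 2 samples"
        )
    values = dataset.values
    if config.cv_scale == "raw" and dataset.log_transformed:
        values = np.exp2(values)
    means = values.mean(axis=1)
    if (means <= 0).any():
        gene = means.index[(means <= 0).to_numpy().argmax()]
        raise NumericError(
            f"dataset {dataset.dataset_id!r}: non-positive mean for gene "
            f"{gene!r}; CV is undefined"
        )
    sds = values.std(axis=1, ddof=1)
    return sds / means


def rank_within_dataset(
    cv_vector: pd.Series,
    config: SensitivityConfig | None = None,
) -> pd.Series:
    """Ascending ranks of a dataset's CVs (1 = smallest, ties averaged)."""
    config = config or SensitivityConfig()
    config.validate()
    if len(cv_vector) == 0:
        raise PipelineError("cannot rank an empty CV vector")
    return pd.Series(
        rankdata(cv_vector.to_numpy(), method="average"), index=cv_vector.index
    )


def compute_sv(
    cv: pd.DataFrame,
    cv_rank: pd.DataFrame,
    config: SensitivityConfig | None = None,
) -> SensitivityTable:
    """Aggregate a genes x datasets rank matrix into sensitive values.

    ``cv``/``cv_rank`` hold NaN where a gene is not measured in a dataset.
    SV is the row mean of ranks over measured datasets; genes under the
    coverage threshold are excluded. The SV series is sorted ascending with
    ties broken by gene symbol.
    """
    config = config or SensitivityConfig()
    config.validate()
    M = cv_rank.shape[1]
    if M == 0:
        raise PipelineError("no datasets: cannot compute sensitive values")
    coverage = cv_rank.notna().sum(axis=1)
    min_cov = config.min_coverage_fraction * M
    eligible = coverage >= min_cov
    excluded = sorted(coverage.index[~eligible])
    if excluded:
        logger.info(
            "excluding %d gene(s) measured in fewer than %.3g of %d datasets",
            len(excluded), min_cov, M,
        )
    sv = cv_rank.loc[eligible].mean(axis=1, skipna=True)
    order = sorted(sv.index, key=lambda g: (sv[g], g))
    return SensitivityTable(
        cv=cv, cv_rank=cv_rank, sv=sv.loc[order],
        coverage=coverage, excluded=excluded,
    )


def build_sensitivity_table(
    datasets: list[ExpressionDataset],
    config: SensitivityConfig | None = None,
) -> SensitivityTable:
    """CV -> within-dataset ranks -> SV for a list of gene-level datasets.

    Gene universes may differ between datasets; ranks are computed over each
    dataset's own measured genes and aggregated over the union.
    """
    config = config or SensitivityConfig()
    config.validate()
    if not datasets:
        raise PipelineError("no datasets: cannot compute sensitive values")
    cv_cols = {ds.dataset_id: compute_cv(ds, config) for ds in datasets}
    rank_cols = {
        ds_id: rank_within_dataset(cv, config) for ds_id, cv in cv_cols.items()
    }
    genes = sorted(set().union(*(c.index for c in cv_cols.values())))
    ds_ids = [ds.dataset_id for ds in datasets]
    cv = pd.DataFrame(cv_cols, index=genes, columns=ds_ids)
    cv_rank = pd.DataFrame(rank_cols, index=genes, columns=ds_ids)
    return compute_sv(cv, cv_rank, config)
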