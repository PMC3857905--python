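"""Core in-memory containers for the expression-sensitivity pipeline.

The central objects are :class:`ExpressionDataset` (one study's probes x
samples intensity matrix), :class:`SensitivityTable` (per-gene, per-dataset
coefficients of variation, their within-dataset ranks, and the rank-mean
"sensitive value" SV), :class:`TailClassification` (robust / sensitive /
neither label per gene) and :class:`EnrichmentResult` (one hypergeometric
test of one gene group against one tail).

Matrices are stored as pandas DataFrames so that probe/gene and sample
identifiers travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError


@dataclass
class ExpressionDataset:
    """One dataset's expression matrix (rows = probes or genes, cols = samples).

    Parameters
    ----------
    dataset_id:
        Identifier of the dataset (e.g. a GEO-style accession or a synthetic ID).
    values:
        DataFrame of intensities, indexed by probe/gene ID with sample IDs as
        columns. Raw intensities must be non-negative.
    log_transformed:
        False while values are on the raw intensity scale; True after the
        floor-and-log preprocessing step.
    """

    dataset_id: str
    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(
                f"dataset {self.dataset_id!r}: duplicate probe ID {dup!r}"
            )
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(
                f"dataset {self.dataset_id!r}: duplicate sample ID {dup!r}"
            )
        if not self.log_transformed:
            vals = self.values.to_numpy()
            if vals.size and np.nanmin(vals) < 0:
                r, c = np.unravel_index(np.nanargmin(vals), vals.shape)
                raise FormatError(
                    f"dataset {self.dataset_id!r}: negative raw intensity at "
                    f"probe {idx[r]!r}, sample {cols[c]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]


@dataclass
class ProbeMap:
    """Many-to-one mapping from probe ID to gene symbol."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.entries.items():
            if not gene:
                raise FormatError(f"probe {probe!r} maps to an empty gene symbol")

    def genes(self) -> set[str]:
        return set(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneGroupCollection:
    """Named gene sets (e.g. disease gene groups), GMT-backed."""

    groups: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise FormatError(f"gene group {name!r} is empty")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)


@dataclass
class SensitivityTable:
    """Per-gene CV, within-dataset CV ranks and sensitive values.

    For gene i and dataset j, ``cv.iloc[i, j]`` is SD/mean of the gene's
    (preprocessed) expression in that dataset and ``cv_rank.iloc[i, j]`` its
    ascending rank among all genes measured in dataset j (rank 1 = most
    stable, ties averaged). ``sv`` is the mean rank over the datasets in
    which the gene is measured; ``coverage`` counts those datasets. Genes
    measured in too few datasets carry no SV and are listed in ``excluded``.
    """

    cv: pd.DataFrame          # genes x datasets, NaN where not measured
    cv_rank: pd.DataFrame     # same shape/index as cv
    sv: pd.Series             # indexed by gene, sorted ascending (ties: gene symbol)
    coverage: pd.Series       # indexed like cv.index
    excluded: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.cv.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.cv.columns)

    @property
    def n_datasets(self) -> int:
        return self.cv.shape[1]


@dataclass
class TailClassification:
    """Robust / sensitive / neither label per gene at a given cutoff fraction."""

    cutoff_fraction: float
    labels: dict[str, str]          # gene -> {"robust", "sensitive", "neither"}
    n_robust: int
    n_sensitive: int
    universe_size: int

    @property
    def robust_genes(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "robust"}

    @property
    def sensitive_genes(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "sensitive"}

    def tail(self, name: str) -> set[str]:
        if name == "robust":
            return self.robust_genes
        if name == "sensitive":
            return self.sensitive_genes
        raise ValueError(f"unknown tail {name!r}")


@dataclass
class EnrichmentResult:
    """One hypergeometric over-representation test of a group against a tail.

    ``p_value`` is the upper-tail probability P(X >= k) with
    X ~ Hypergeometric(N, K, n): k = overlap of group and tail, K = tail
    size, n = group size within the universe, N = universe size.
    """

    group: str
    tail: str                 # "robust" or "sensitive"
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class GeneProfileSummary:
    """Case/control expression summary for a single gene in one dataset."""

    gene: str
    group_means: dict[str, float]   # condition -> mean log2 expression
    mean_difference: float          # log2 units, first condition minus second
    t_statistic: float              # Welch two-sample t
    p_value: float                  # two-sided
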