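import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exprsens import (
    ExpressionDataset,
    SensitivityTable,
    SimulationConfig,
    simulate_collection,
    simulate_groups,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A desk-sized collection: 300 genes, 5 datasets, 8-12 samples."""
    return SimulationConfig(
        n_genes=300,
        n_datasets=5,
        samples_per_dataset=(8, 12),
        probes_per_gene=(1, 3),
        n_groups=8,
        n_enriched_groups=4,
        group_size=(15, 20),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_collection(tiny_config):
    return simulate_collection(tiny_config)


@pytest.fixture(scope="session")
def tiny_groups(tiny_config, tiny_collection):
    _, _, truth = tiny_collection
    return simulate_groups(sorted(truth.gene_labels), truth, tiny_config)


def make_dataset(values, dataset_id="DS1", probes=None, samples=None,
                 log_transformed=False) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    probes = probes or [f"p{i + 1}" for i in range(n_p)]
    samples = samples or [f"s{j + 1}" for j in range(n_s)]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=probes, columns=samples),
        log_transformed=log_transformed,
    )


def make_sv_table(sv: dict[str, float]) -> SensitivityTable:
    """A SensitivityTable carrying only an SV series (one pseudo-dataset)."""
    genes = sorted(sv, key=lambda g: (sv[g], g))
    series = pd.Series([sv[g] for g in genes], index=genes, dtype=float)
    frame = series.to_frame("D1")
    return SensitivityTable(
        cv=frame, cv_rank=frame, sv=series,
        coverage=pd.Series(1, index=series.index),
    )
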