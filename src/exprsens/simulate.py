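"""Synthetic expression collections with planted variability ground truth.

Generates a collection of expression datasets over a shared gene universe in
which a chosen fraction of genes is planted as "sensitive" (log-scale SD
inflated by ``sensitive_cv_multiplier``) or "robust" (SD shrunk by
``robust_cv_multiplier``), together with disease-style gene groups that are
preferentially drawn from one planted tail. The downstream pipeline can then
be scored against known truth without any external downloads.

Generative model
----------------
Per gene g: a log2 mean mu_g ~ Normal(baseline_mean_log2, 1.5), clipped at
4.5 so ordinary genes stay above the raw intensity floor; a base log2 SD
s_g = 0.25 * exp(Normal(0, 0.2)) (lognormal, median 0.25); a multiplier
m_g in {sensitive_cv_multiplier, robust_cv_multiplier, 1} by planted label.
A small fraction of background genes is given a low mean (~Normal(3.2, 0.4)
log2) so some raw values fall below the floor of 10 and the flooring rule is
exercised. Per dataset j, each sample value is Normal(mu_g + b_j, s_g * m_g)
on the log2 scale, with a dataset-level baseline shift b_j ~ Normal(0, 0.3);
raw intensities are 2**x. Extra probes for multi-probe genes are attenuated,
noisy replicates of the gene signal, so max-collapse has a defined correct
answer (the primary probe).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
substreams (one for gene-level parameters, one per dataset, one for group
construction), so outputs are bit-identical across runs for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneGroupCollection, ProbeMap
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

# Fixed model constants (not study conditions, hence not config fields).
_MEAN_SD_LOG2 = 1.5          # spread of per-gene log2 means
_MEAN_FLOOR_LOG2 = 4.5       # ordinary genes stay above the raw floor
_BASE_SD_MEDIAN = 0.25       # median per-gene log2 SD
_BASE_SD_SIGMA = 0.2         # lognormal sigma of per-gene SD
_LOW_MEAN_LOG2 = 3.2         # low-expression genes straddle the raw floor of 10
_LOW_MEAN_SD = 0.4
_DATASET_SHIFT_SD = 0.3      # per-dataset baseline shift
_EXTRA_PROBE_ATTENUATION = 1.0   # log2 drop of secondary probes
_EXTRA_PROBE_NOISE_SD = 0.1

# Stream tags so simulate_groups is reproducible independently of
# simulate_collection while both derive from the one config seed.
_GENE_STREAM = 0
_GROUP_STREAM = 1
_DATASET_STREAM = 2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic collection.

    Defaults mirror the regime the recovery analyses run under: 2000 genes,
    20 datasets of 20 samples, 5% planted sensitive and 5% planted robust
    genes with CV multipliers 4 and 0.25, 1-3 probes per gene, and 20
    disease-style groups of 30 genes of which 5 are tail-enriched with
    bias 0.9.
    """

    n_genes: int = 2000
    n_datasets: int = 20
    samples_per_dataset: tuple[int, int] = (20, 20)   # inclusive range
    frac_planted_sensitive: float = 0.05
    frac_planted_robust: float = 0.05
    frac_low_expression: float = 0.02
    baseline_mean_log2: float = 8.0
    sensitive_cv_multiplier: float = 4.0
    robust_cv_multiplier: float = 0.25
    probes_per_gene: tuple[int, int] = (1, 3)         # inclusive range
    n_groups: int = 20
    n_enriched_groups: int = 5
    group_size: tuple[int, int] = (30, 30)            # inclusive range
    group_tail_bias: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")
        for name in ("samples_per_dataset", "probes_per_gene", "group_size"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or < 1")
        for name in ("frac_planted_sensitive", "frac_planted_robust",
                     "frac_low_expression", "group_tail_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_planted_sensitive + self.frac_planted_robust > 1.0:
            raise ConfigurationError(
                "frac_planted_sensitive + frac_planted_robust exceeds 1"
            )
        if self.baseline_mean_log2 <= 0:
            raise ConfigurationError("baseline_mean_log2 must be positive")
        if self.sensitive_cv_multiplier <= 1:
            raise ConfigurationError("sensitive_cv_multiplier must be > 1")
        if not 0 < self.robust_cv_multiplier < 1:
            raise ConfigurationError("robust_cv_multiplier must be in (0, 1)")
        if self.n_groups < 0 or self.n_enriched_groups < 0:
            raise ConfigurationError("group counts must be >= 0")
        if self.n_enriched_groups > self.n_groups:
            raise ConfigurationError("n_enriched_groups exceeds n_groups")
        if self.group_size[1] > self.n_genes:
            raise ConfigurationError(
                f"group_size up to {self.group_size[1]} exceeds universe of "
                f"{self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Planted labels: per gene and per group."""

    gene_labels: dict[str, str]    # gene -> planted_sensitive | planted_robust | background
    group_labels: dict[str, str] = field(default_factory=dict)
    # group -> tail_enriched_sensitive | tail_enriched_robust | null

    def genes_with_label(self, label: str) -> set[str]:
        return {g for g, l in self.gene_labels.items() if l == label}

    @property
    def planted_sensitive(self) -> set[str]:
        return self.genes_with_label("planted_sensitive")

    @property
    def planted_robust(self) -> set[str]:
        return self.genes_with_label("planted_robust")


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], ProbeMap, GroundTruth]:
    """Generate ``config.n_datasets`` raw-scale datasets over one gene universe.

    Returns the datasets (probe-level, raw intensities), the probe-to-gene
    map, and the planted ground truth. Deterministic for a fixed seed.
    """
    config.validate()
    genes = _gene_names(config.n_genes)
    gene_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _GENE_STREAM])
    )

    n = config.n_genes
    n_sens = int(round(config.frac_planted_sensitive * n))
    n_rob = int(round(config.frac_planted_robust * n))
    perm = gene_rng.permutation(n)
    labels = np.full(n, "background", dtype=object)
    labels[perm[:n_sens]] = "planted_sensitive"
    labels[perm[n_sens:n_sens + n_rob]] = "planted_robust"

    mu = np.clip(
        gene_rng.normal(config.baseline_mean_log2, _MEAN_SD_LOG2, n),
        _MEAN_FLOOR_LOG2, None,
    )
    # Low-expression genes are drawn from the background so planted
    # multipliers act on genes the floor never censors.
    background_idx = perm[n_sens + n_rob:]
    n_low = min(int(round(config.frac_low_expression * n)), background_idx.size)
    low_idx = gene_rng.choice(background_idx, n_low, replace=False) if n_low else []
    mu[low_idx] = gene_rng.normal(_LOW_MEAN_LOG2, _LOW_MEAN_SD, n_low)

    base_sd = _BASE_SD_MEDIAN * np.exp(gene_rng.normal(0.0, _BASE_SD_SIGMA, n))
    mult = np.where(
        labels == "planted_sensitive", config.sensitive_cv_multiplier,
        np.where(labels == "planted_robust", config.robust_cv_multiplier, 1.0),
    )
    sd = base_sd * mult

    p_lo, p_hi = config.probes_per_gene
    probes_per_gene = gene_rng.integers(p_lo, p_hi + 1, n)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    probe_rank: list[int] = []   # 0 = primary probe
    entries: dict[str, str] = {}
    for i, g in enumerate(genes):
        for k in range(probes_per_gene[i]):
            pid = f"{g}_p{k + 1}"
            probe_ids.append(pid)
            probe_gene_idx.append(i)
            probe_rank.append(k)
            entries[pid] = g
    probe_gene_idx_arr = np.asarray(probe_gene_idx)
    probe_rank_arr = np.asarray(probe_rank)

    lo, hi = config.samples_per_dataset
    id_width = max(3, len(str(config.n_datasets)))
    datasets: list[ExpressionDataset] = []
    for j in range(config.n_datasets):
        ds_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _DATASET_STREAM, j])
        )
        n_samples = int(ds_rng.integers(lo, hi + 1))
        shift = ds_rng.normal(0.0, _DATASET_SHIFT_SD)
        gene_log2 = ds_rng.normal(
            (mu + shift)[:, None], sd[:, None], (n, n_samples)
        )
        probe_log2 = gene_log2[probe_gene_idx_arr]
        secondary = probe_rank_arr > 0
        if secondary.any():
            n_sec = int(secondary.sum())
            probe_log2[secondary] = (
                probe_log2[secondary]
                - _EXTRA_PROBE_ATTENUATION * probe_rank_arr[secondary, None]
                + ds_rng.normal(0.0, _EXTRA_PROBE_NOISE_SD, (n_sec, n_samples))
            )
        ds_id = f"SIM{j + 1:0{id_width}d}"
        values = pd.DataFrame(
            np.exp2(probe_log2),
            index=pd.Index(probe_ids, name="probe"),
            columns=[f"{ds_id}_s{s + 1}" for s in range(n_samples)],
        )
        datasets.append(ExpressionDataset(ds_id, values, log_transformed=False))
    logger.info(
        "simulated %d datasets over %d genes (%d probes): %d planted sensitive, "
        "%d planted robust, %d low-expression",
        config.n_datasets, n, len(probe_ids), n_sens, n_rob, n_low,
    )

    truth = GroundTruth(gene_labels=dict(zip(genes, labels)))
    return datasets, ProbeMap(entries), truth


def simulate_groups(
    genes: list[str], truth: GroundTruth, config: SimulationConfig
) -> GeneGroupCollection:
    """Build disease-style gene groups over ``genes`` with planted enrichment.

    The first ``n_enriched_groups`` groups alternate between the sensitive
    and robust planted tails; each draws, per member, from its tail with
    probability ``group_tail_bias`` and uniformly from background genes
    otherwise (no duplicates within a group). Remaining groups draw
    uniformly from the whole universe. Group labels are recorded in
    ``truth.group_labels``.
    """
    config.validate()
    if not genes:
        raise ConfigurationError("gene universe is empty")
    if config.group_size[1] > len(genes):
        raise ConfigurationError(
            f"group_size up to {config.group_size[1]} exceeds universe of "
            f"{len(genes)} genes"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _GROUP_STREAM])
    )
    genes_arr = np.asarray(sorted(genes), dtype=object)
    tails = {
        "tail_enriched_sensitive": np.asarray(
            sorted(truth.planted_sensitive & set(genes)), dtype=object
        ),
        "tail_enriched_robust": np.asarray(
            sorted(truth.planted_robust & set(genes)), dtype=object
        ),
    }
    background = np.asarray(
        sorted(truth.genes_with_label("background") & set(genes)), dtype=object
    )

    lo, hi = config.group_size
    width = max(2, len(str(config.n_groups)))
    groups: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for g in range(config.n_groups):
        name = f"group_{g + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if g < config.n_enriched_groups:
            label = ("tail_enriched_sensitive" if g % 2 == 0
                     else "tail_enriched_robust")
            tail_pool = tails[label]
            n_tail = min(int(rng.binomial(size, config.group_tail_bias)),
                         tail_pool.size)
            members = list(rng.choice(tail_pool, n_tail, replace=False))
            pool = background if background.size >= size - n_tail else genes_arr
            rest_pool = np.setdiff1d(pool, np.asarray(members, dtype=object))
            members += list(rng.choice(rest_pool, size - n_tail, replace=False))
        else:
            label = "null"
            members = list(rng.choice(genes_arr, size, replace=False))
        groups[name] = set(members)
        descriptions[name] = label
        truth.group_labels[name] = label
    return GeneGroupCollection(groups=groups, descriptions=descriptions)
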