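"""Robust / sensitive tail classification of the SV distribution.

Genes with the lowest sensitive values are "robust" (stably expressed
across perturbations) and those with the highest are "sensitive"; the
default cutoff takes 5% of the universe on each side. Tail size is
round-half-up of cutoff_fraction x universe — on the 31835-gene HGU133plus2
universe at 5% this gives 1592 genes per tail. Boundary ties in SV are
broken lexicographically by gene symbol so the tail size is exact and the
classification deterministic.
"""

from __future__ import annotations

import math

from .datatypes import SensitivityTable, TailClassification
from .errors import ConfigurationError, PipelineError


def tail_size(cutoff_fraction: float, universe_size: int) -> int:
    """round_half_up(cutoff_fraction * universe_size)."""
    return int(math.floor(cutoff_fraction * universe_size + 0.5))


def classify_tails(
    table: SensitivityTable, cutoff_fraction: float = 0.05
) -> TailClassification:
    """Label each gene with an SV as robust, sensitive, or neither.

    The universe is the set of genes carrying an SV (coverage-excluded genes
    are outside it). Raises :class:`ConfigurationError` for a cutoff outside
    (0, 0.5] and :class:`PipelineError` when the universe cannot hold two
    disjoint tails.
    """
    if not 0 < cutoff_fraction <= 0.5:
        raise ConfigurationError(
            f"cutoff_fraction {cutoff_fraction} outside (0, 0.5]"
        )
    sv = table.sv
    universe_size = len(sv)
    n_tail = tail_size(cutoff_fraction, universe_size)
    if n_tail < 1 or 2 * n_tail > universe_size:
        raise PipelineError(
            f"universe of {universe_size} genes cannot hold two disjoint "
            f"tails of {n_tail}"
        )
    # sv is already sorted by (value, gene symbol); that order is the tie rule.
    ordered = sorted(sv.index, key=lambda g: (sv[g], g))
    robust = ordered[:n_tail]
    sensitive = ordered[-n_tail:]
    labels = {g: "neither" for g in ordered}
    labels.update({g: "robust" for g in robust})
    labels.update({g: "sensitive" for g in sensitive})
    return TailClassification(
        cutoff_fraction=cutoff_fraction,
        labels=labels,
        n_robust=len(robust),
        n_sensitive=len(sensitive),
        universe_size=universe_size,
    )
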