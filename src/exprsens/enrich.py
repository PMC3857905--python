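"""Hypergeometric over-representation of gene groups in the SV tails.

For a group of n genes (within the N-gene classification universe) and a
tail of K genes containing k of the group's members, the enrichment p-value
is the upper tail P(X >= k) with X ~ Hypergeometric(N, K, n) — the chance
of drawing at least k group members when K genes are picked from the
universe at random. Every group is tested against both tails, and
Benjamini-Hochberg adjusted p-values are added across the full run; the raw
p-value stays the primary column.
"""

from __future__ import annotations

import logging

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import EnrichmentResult, GeneGroupCollection, TailClassification
from .errors import PipelineError

logger = logging.getLogger(__name__)

TAILS = ("robust", "sensitive")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    classification: TailClassification,
    groups: GeneGroupCollection,
) -> list[EnrichmentResult]:
    """Test every group against both SV tails.

    Groups are first intersected with the classification universe; groups
    with an empty intersection are skipped with a logged warning. Results
    are BH-adjusted jointly and returned sorted by (p_value, group, tail).
    """
    universe = set(classification.labels)
    N = len(universe)
    if N == 0:
        raise PipelineError("empty classification universe")
    tails = {t: classification.tail(t) for t in TAILS}
    results: list[EnrichmentResult] = []
    for name in sorted(groups.groups):
        members = groups.groups[name] & universe
        if not members:
            logger.warning(
                "group %r shares no genes with the universe; skipped", name
            )
            continue
        n = len(members)
        for tail_name in TAILS:
            tail_set = tails[tail_name]
            k = len(members & tail_set)
            K = len(tail_set)
            results.append(
                EnrichmentResult(
                    group=name, tail=tail_name, k=k, K=K, n=n, N=N,
                    p_value=hypergeom_pvalue(k, K, n, N),
                )
            )
    if results:
        _, adjusted, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
    results.sort(key=lambda r: (r.p_value, r.group, r.tail))
    return results
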