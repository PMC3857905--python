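"""Case/control expression profiling of a single gene.

Summarizes one gene's expression in one dataset split into two condition
groups (e.g. early-onset tumour vs normal mucosa): per-condition means,
their difference, and a Welch two-sample t-test. This is the style of check
used to ask whether a low-SV (robust) disease gene — e.g. HIF1A or MLH1 in
a colorectal-cancer cohort — shows any expression change in its own disease
condition; for robust genes it typically does not, which is exactly why
such genes are easily missed by differential-expression screens.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.stats import ttest_ind

from .datatypes import ExpressionDataset, GeneProfileSummary
from .errors import InputError


def profile_gene(
    dataset: ExpressionDataset,
    gene: str,
    condition_labels: dict[str, str],
) -> GeneProfileSummary:
    """Welch two-sample comparison of one gene between two conditions.

    ``condition_labels`` maps sample ID to condition name; exactly two
    conditions must appear, each covering at least two of the dataset's
    samples. The mean difference is first condition minus second, with
    conditions ordered by name.
    """
    if gene not in dataset.values.index:
        raise InputError(
            f"gene {gene!r} not present in dataset {dataset.dataset_id!r}"
        )
    labelled = [s for s in dataset.sample_ids if s in condition_labels]
    counts = Counter(condition_labels[s] for s in labelled)
    if len(counts) != 2:
        raise InputError(
            f"expected exactly 2 conditions, found {len(counts)}: "
            f"{sorted(counts)}"
        )
    cond_a, cond_b = sorted(counts)
    if min(counts.values()) < 2:
        small = min(counts, key=counts.get)
        raise InputError(
            f"condition {small!r} has {counts[small]} sample(s); need >= 2"
        )
    row = dataset.values.loc[gene]
    a = np.asarray([row[s] for s in labelled if condition_labels[s] == cond_a])
    b = np.asarray([row[s] for s in labelled if condition_labels[s] == cond_b])
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # Degenerate: both groups constant. No evidence of change when the
        # means agree; certain change when they differ.
        t = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t_res = ttest_ind(a, b, equal_var=False)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    return GeneProfileSummary(
        gene=gene,
        group_means={cond_a: float(a.mean()), cond_b: float(b.mean())},
        mean_difference=diff,
        t_statistic=t,
        p_value=p,
    )
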