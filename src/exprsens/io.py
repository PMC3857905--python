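"""Readers and writers for the pipeline's plain-text formats.

Formats: tab-separated expression matrices (first row sample IDs, first
column probe IDs), two-column probe->gene maps, GMT gene sets, TSV result
tables, and JSON ground truth for synthetic collections. Readers reject
malformed input rather than silently repairing it; the one documented
exception is GMT, where duplicate members within a line are deduplicated
with a logged warning.

All writers emit deterministic byte streams: fixed column order, stated row
sort keys, and shortest round-trip float formatting (so write -> read
reproduces values exactly).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    EnrichmentResult,
    ExpressionDataset,
    GeneGroupCollection,
    ProbeMap,
    SensitivityTable,
    TailClassification,
)
from .errors import FormatError
from .simulate import GroundTruth

logger = logging.getLogger(__name__)


def _fmt(v: float) -> str:
    return repr(float(v))


# ---------------------------------------------------------------- expression

def read_expression_tsv(path: str | Path, dataset_id: str | None = None
                        ) -> ExpressionDataset:
    """Parse a TSV expression matrix into a raw-scale :class:`ExpressionDataset`.

    Expects the first row to hold sample IDs (first cell is a corner label or
    empty), the first column probe IDs, and a fully numeric body with dot
    decimals. Raises :class:`FormatError` naming the offending row/column on
    ragged rows, non-numeric cells or duplicate IDs.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        if not sample_ids:
            raise FormatError(f"{path}: header row has no sample IDs")
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}: row {lineno} has {len(fields) - 1} values, "
                    f"expected {len(sample_ids)}"
                )
            probe_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError:
                for col, v in enumerate(fields[1:]):
                    try:
                        float(v)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {v!r} at row {lineno}, "
                            f"sample {sample_ids[col]!r}"
                        ) from None
    values = pd.DataFrame(
        np.asarray(rows, dtype=float) if rows else
        np.empty((0, len(sample_ids))),
        index=pd.Index(probe_ids, name="probe"),
        columns=sample_ids,
    )
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem, values=values, log_transformed=False
    )


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write an expression matrix as TSV (probes x samples)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("probe\t" + "\t".join(dataset.sample_ids) + "\n")
        for probe, row in zip(dataset.probe_ids, dataset.values.to_numpy()):
            fh.write(probe + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ----------------------------------------------------------------- probe map

def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a two-column TSV (probe, gene symbol)."""
    path = Path(path)
    entries: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected 2"
                )
            probe, gene = fields
            if probe in entries:
                raise FormatError(f"{path}: duplicate probe {probe!r} at line {lineno}")
            if not gene:
                raise FormatError(f"{path}: empty gene symbol at line {lineno}")
            entries[probe] = gene
    return ProbeMap(entries)


def write_probe_map(pmap: ProbeMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for probe in sorted(pmap.entries):
            fh.write(f"{probe}\t{pmap.entries[probe]}\n")


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> GeneGroupCollection:
    """Read gene sets in GMT format (name, description, members...).

    Duplicate members within a line are deduplicated with a logged warning;
    a line with fewer than three fields is a :class:`FormatError`.
    """
    path = Path(path)
    groups: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                    "name, description and at least one member"
                )
            name, desc, *members = fields
            if name in groups:
                raise FormatError(f"{path}: duplicate group name {name!r} at line {lineno}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s line %d: group %r has %d duplicate member(s), deduplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            groups[name] = unique
            descriptions[name] = desc
    return GeneGroupCollection(groups=groups, descriptions=descriptions)


def write_gmt(collection: GeneGroupCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sorted(collection.groups):
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.groups[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ------------------------------------------------------------- result tables

def write_sensitivity_table(table: SensitivityTable, path: str | Path) -> None:
    """Write the SV table as TSV: gene, sv, coverage, then per-dataset cv/rank.

    Rows are sorted by (sv ascending, gene symbol); coverage-excluded genes
    are omitted (they carry no SV) and reported in the run log instead.
    """
    path = Path(path)
    ds = table.dataset_ids
    cols = ["gene", "sv", "coverage"]
    cols += [f"cv_{d}" for d in ds] + [f"rank_{d}" for d in ds]
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for gene in table.sv.index:
            fields = [gene, _fmt(table.sv[gene]), str(int(table.coverage[gene]))]
            for d in ds:
                v = table.cv.at[gene, d]
                fields.append("" if pd.isna(v) else _fmt(v))
            for d in ds:
                v = table.cv_rank.at[gene, d]
                fields.append("" if pd.isna(v) else _fmt(v))
            fh.write("\t".join(fields) + "\n")


def read_sensitivity_table(path: str | Path) -> SensitivityTable:
    """Read back a table written by :func:`write_sensitivity_table`."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    ds = [c[len("cv_"):] for c in df.columns if c.startswith("cv_")]
    cv = df[[f"cv_{d}" for d in ds]].set_axis(ds, axis=1)
    rank = df[[f"rank_{d}" for d in ds]].set_axis(ds, axis=1)
    return SensitivityTable(
        cv=cv, cv_rank=rank, sv=df["sv"], coverage=df["coverage"], excluded=[]
    )


def write_classification(cls: TailClassification, path: str | Path) -> None:
    """Write per-gene tail labels as TSV sorted by (label, gene)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tlabel\n")
        for gene, label in sorted(cls.labels.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{gene}\t{label}\n")


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV sorted by (p_value, group, tail)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("group\ttail\tk\tK\tn\tN\tp_value\tp_adjusted\n")
        for r in sorted(results, key=lambda r: (r.p_value, r.group, r.tail)):
            fh.write(
                f"{r.group}\t{r.tail}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{_fmt(r.p_value)}\t{_fmt(r.p_adjusted)}\n"
            )


# -------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gene_labels": dict(sorted(truth.gene_labels.items())),
        "group_labels": dict(sorted(truth.group_labels.items())),
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        gene_labels=payload["gene_labels"],
        group_labels=payload.get("group_labels", {}),
    )


def read_condition_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, condition) for case/control profiling."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected 2"
                )
            sample, condition = fields
            if sample in labels:
                raise FormatError(f"{path}: duplicate sample {sample!r} at line {lineno}")
            labels[sample] = condition
    return labels
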