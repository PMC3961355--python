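"""Replicate averaging, gene collapsing and min–max normalization to [−1, 1].

These steps turn raw probe intensities into the "working database": one
normalized profile per record per condition.  Normalization is the affine
map onto [−1, 1],

    x'_j = 2 (x_j − x_min) / (x_max − x_min) − 1,

so the minimum of every non-constant record maps to −1 and the maximum to
+1.  A constant record (x_min = x_max) maps to all zeros — the midpoint of
the target interval — which keeps flat probes correlation-inert
downstream.  No background correction, quantile normalization or log
transform is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

from wcna.dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class NormalizedProfile:
    """One record's profile scaled to [−1, 1] for one condition.

    ``x_min``/``x_max`` are the pre-normalization extremes, retained so the
    applied map can be audited or inverted.
    """

    probe_id: str
    condition: str
    values: np.ndarray
    x_min: float
    x_max: float


class CollapseStats(NamedTuple):
    removed_unmapped: int
    merged_probes: int


def average_replicates(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse the replicate axis to its arithmetic mean (per cell)."""
    return ExpressionDataset(
        probe_ids=list(dataset.probe_ids),
        timepoints=dataset.timepoints.copy(),
        values={c: a.mean(axis=2, keepdims=True) for c, a in dataset.values.items()},
        gene_ids=dict(dataset.gene_ids),
    )


def collapse_to_genes(
    dataset: ExpressionDataset, gene_map: Mapping[str, str]
) -> tuple[ExpressionDataset, CollapseStats]:
    """Drop unmapped probes and average multiple probes of the same gene.

    Records in the result are keyed by gene symbol, in order of each
    gene's first appearance in the probe list.  Values of probes sharing a
    gene are replaced by their arithmetic mean, per condition and
    timepoint.  Replicates must already be averaged.

    Returns the collapsed dataset and counts of removed/merged probes.
    """
    members: dict[str, list[int]] = {}
    removed = 0
    for idx, probe in enumerate(dataset.probe_ids):
        gene = gene_map.get(probe)
        if not gene:
            removed += 1
            continue
        members.setdefault(gene, []).append(idx)
    if not members:
        raise ValueError("no probe maps to any gene; collapse would be empty")
    merged = sum(len(ix) for ix in members.values() if len(ix) > 1)
    genes = list(members)
    values = {
        cond: np.stack([arr[members[g]].mean(axis=0) for g in genes])
        for cond, arr in dataset.values.items()
    }
    log.info(
        "gene collapsing: %d probes -> %d gene records (%d unmapped removed, %d merged)",
        dataset.n_probes, len(genes), removed, merged,
    )
    return (
        ExpressionDataset(
            probe_ids=genes,
            timepoints=dataset.timepoints.copy(),
            values=values,
            gene_ids={g: g for g in genes},
        ),
        CollapseStats(removed_unmapped=removed, merged_probes=merged),
    )


def normalize_record(
    values: np.ndarray, probe_id: str = "", condition: str = ""
) -> NormalizedProfile:
    """Min–max normalize one profile to [−1, 1] (constant profiles → 0)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("profile must have at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite value in record {probe_id!r}")
    x_min, x_max = float(values.min()), float(values.max())
    if x_min == x_max:
        out = np.zeros_like(values)
    else:
        out = 2.0 * (values - x_min) / (x_max - x_min) - 1.0
    return NormalizedProfile(probe_id=probe_id, condition=condition,
                             values=out, x_min=x_min, x_max=x_max)


def normalize_dataset(dataset: ExpressionDataset) -> ExpressionDataset:
    """Normalize every record of every condition to [−1, 1].

    Replicates must already be averaged — normalization applies to each
    record of the working database, not to individual replicates.
    """
    values: dict[str, np.ndarray] = {}
    for cond in dataset.condition_labels:
        mat = dataset.matrix(cond)
        out = np.stack(
            [normalize_record(row, pid, cond).values
             for pid, row in zip(dataset.probe_ids, mat)]
        )
        values[cond] = out[:, :, None]
    return ExpressionDataset(
        probe_ids=list(dataset.probe_ids),
        timepoints=dataset.timepoints.copy(),
        values=values,
        gene_ids=dict(dataset.gene_ids),
    )
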