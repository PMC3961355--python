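"""In-memory container for two-condition time-course expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """Probes × timepoints × replicates expression values per condition.

    Parameters
    ----------
    probe_ids
        Ordered, unique record identifiers (probe or gene IDs; treated as
        opaque strings).
    timepoints
        Ordered sampling times in hours, shared by all conditions.
    values
        Mapping ``condition -> array`` of shape
        ``(n_probes, n_timepoints, n_replicates)``.  All conditions must
        hold the same probes in the same order and have identical
        timepoint and replicate counts.
    gene_ids
        Optional ``probe_id -> gene symbol`` mapping; probes may be absent
        (unannotated).
    """

    probe_ids: list[str]
    timepoints: np.ndarray
    values: dict[str, np.ndarray]
    gene_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            seen: set[str] = set()
            dup = next(p for p in self.probe_ids if p in seen or seen.add(p))
            raise ValueError(f"duplicate probe ID: {dup!r}")
        if not self.values:
            raise ValueError("dataset has no conditions")
        shapes = set()
        for cond, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:  # single replicate shorthand
                arr = arr[:, :, None]
            if arr.ndim != 3:
                raise ValueError(f"condition {cond!r}: expected 3-d array, got {arr.ndim}-d")
            if arr.shape[0] != len(self.probe_ids):
                raise ValueError(
                    f"condition {cond!r}: {arr.shape[0]} rows for {len(self.probe_ids)} probes"
                )
            if arr.shape[1] != len(self.timepoints):
                raise ValueError(
                    f"condition {cond!r}: {arr.shape[1]} columns for "
                    f"{len(self.timepoints)} timepoints"
                )
            if np.isnan(arr).any():
                raise ValueError(f"condition {cond!r} contains NaN values")
            self.values[cond] = arr
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise ValueError(f"conditions have differing shapes: {sorted(shapes)}")

    # -- structure ---------------------------------------------------------

    @property
    def condition_labels(self) -> list[str]:
        return list(self.values)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_replicates(self) -> int:
        return next(iter(self.values.values())).shape[2]

    def matrix(self, condition: str) -> np.ndarray:
        """Return the 2-d (probes × timepoints) matrix for *condition*.

        Requires the replicate axis to have been collapsed (see
        :func:`wcna.preprocess.average_replicates`).
        """
        arr = self.values[condition]
        if arr.shape[2] != 1:
            raise ValueError(
                "replicates not averaged; call preprocess.average_replicates first"
            )
        return arr[:, :, 0]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            probe_ids=list(self.probe_ids),
            timepoints=self.timepoints.copy(),
            values={c: a.copy() for c, a in self.values.items()},
            gene_ids=dict(self.gene_ids),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and np.allclose(self.timepoints, other.timepoints)
            and self.condition_labels == other.condition_labels
            and all(
                np.allclose(self.values[c], other.values[c], atol=1e-9)
                for c in self.values
            )
            and self.gene_ids == other.gene_ids
        )
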