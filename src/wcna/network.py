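"""Hard-threshold correlation networks and differential connectivity.

For each condition a Pearson correlation matrix R = (r_ij) is computed
over the probes' frequency vectors, and a binary adjacency L places an
edge wherever τ ≤ |r_ij| ≤ 1 (default τ = 0.7), ignoring self-correlation.
A probe's connectivity l_i is its degree.  The between-condition degree
difference m_i = l_i(A) − l_i(B) is summarized by the square ratio

    S_neg = Σ_{m_i<0} m_i² / Σ_i m_i²,    S_pos = Σ_{m_i>0} m_i² / Σ_i m_i²,

and the probes in the extreme tails of the sorted differences — beyond a
knee point or user thresholds — are flagged as key probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wcna.screening import InflectionConfig, find_inflection

log = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Correlation matrix and (optionally) thresholded adjacency for one condition."""

    condition: str
    probe_ids: list[str]
    R: np.ndarray
    tau: float | None = None
    L: np.ndarray | None = None
    degrees: np.ndarray | None = None


@dataclass
class ConnectivityDiffTable:
    """Per-probe degrees in two conditions and their differences.

    ``m = degrees_a − degrees_b``; negative m means the probe is more
    connected in condition b.  Selections hold probe IDs in the extreme
    negative/positive tails together with the thresholds that produced
    them.
    """

    probe_ids: list[str]
    condition_a: str
    condition_b: str
    degrees_a: np.ndarray
    degrees_b: np.ndarray
    m: np.ndarray
    gene_ids: dict[str, str] = field(default_factory=dict)
    selected_negative: list[str] | None = None
    selected_positive: list[str] | None = None
    negative_threshold: float | None = None
    positive_threshold: float | None = None

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.m < 0))

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.m > 0))

    @property
    def n_zero(self) -> int:
        return int(np.sum(self.m == 0))

    def to_frame(self) -> pd.DataFrame:
        flag = np.array([""] * len(self.probe_ids), dtype=object)
        for ids, label in ((self.selected_negative, "negative"),
                           (self.selected_positive, "positive")):
            if ids:
                sel = set(ids)
                flag[[i for i, p in enumerate(self.probe_ids) if p in sel]] = label
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "gene_id": [self.gene_ids.get(p, "") for p in self.probe_ids],
                f"degree_{self.condition_a}": self.degrees_a.astype(int),
                f"degree_{self.condition_b}": self.degrees_b.astype(int),
                "difference": self.m.astype(int),
                "selected": flag,
            }
        )


def correlation_matrix(
    vectors: np.ndarray, probe_ids: list[str], condition: str = ""
) -> CorrelationNetwork:
    """Pearson correlation matrix over the rows of *vectors*.

    r_ij = cov(X_i, X_j) / (σ_i σ_j) with sample moments.  Rows of zero
    variance (degenerate vectors, e.g. constant profiles) get r = 0
    off-diagonal with a logged warning; the diagonal is 1 throughout.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need a 2-d array with at least 2 probe vectors")
    if vectors.shape[0] != len(probe_ids):
        raise ValueError("probe_ids length does not match vector count")
    sd = vectors.std(axis=1)
    # scale-relative zero test: constant vectors can leave sd ~ 1e-17 in float
    degenerate = sd <= 1e-12 * (1.0 + np.abs(vectors).max(axis=1))
    if degenerate.all():
        raise ValueError("all frequency vectors are degenerate (zero variance)")
    if degenerate.any():
        log.warning(
            "%d degenerate (zero-variance) vectors; their correlations set to 0: %s",
            int(degenerate.sum()),
            [probe_ids[i] for i in np.flatnonzero(degenerate)],
        )
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    safe_sd = np.where(degenerate, 1.0, sd)
    R = (centered @ centered.T) / len(vectors[0]) / np.outer(safe_sd, safe_sd)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    return CorrelationNetwork(condition=condition, probe_ids=list(probe_ids), R=R)


def threshold_adjacency(network: CorrelationNetwork, tau: float = 0.7) -> CorrelationNetwork:
    """Binary adjacency l_ij = 1 ⇔ τ ≤ |r_ij| ≤ 1 (i ≠ j) and degrees.

    The comparison at τ is inclusive; the diagonal is forced to 0.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    L = (np.abs(network.R) >= tau).astype(int)
    np.fill_diagonal(L, 0)
    return CorrelationNetwork(
        condition=network.condition,
        probe_ids=list(network.probe_ids),
        R=network.R,
        tau=tau,
        L=L,
        degrees=L.sum(axis=1),
    )


def connectivity_difference(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> ConnectivityDiffTable:
    """Degree differences m_i = l_i(a) − l_i(b) over a shared probe order."""
    if net_a.probe_ids != net_b.probe_ids:
        raise ValueError("probe order differs between the two networks")
    for net in (net_a, net_b):
        if net.degrees is None:
            raise ValueError(
                f"network {net.condition!r} has no degrees; call threshold_adjacency"
            )
    m = net_a.degrees - net_b.degrees
    table = ConnectivityDiffTable(
        probe_ids=list(net_a.probe_ids),
        condition_a=net_a.condition,
        condition_b=net_b.condition,
        degrees_a=net_a.degrees.copy(),
        degrees_b=net_b.degrees.copy(),
        m=m,
    )
    log.info(
        "connectivity difference: %d negative, %d positive, %d zero",
        table.n_negative, table.n_positive, table.n_zero,
    )
    return table


def square_ratio(table: ConnectivityDiffTable | np.ndarray) -> tuple[float, float]:
    """Fractions of Σm² contributed by negative and positive differences.

    Returns ``(S_neg, S_pos)``; they sum to 1 whenever any m_i ≠ 0.
    """
    m = table.m if isinstance(table, ConnectivityDiffTable) else np.asarray(table)
    total = float(np.sum(m.astype(float) ** 2))
    if total == 0.0:
        raise ValueError("all connectivity differences are zero; square ratio undefined")
    s_neg = float(np.sum(m[m < 0].astype(float) ** 2)) / total
    s_pos = float(np.sum(m[m > 0].astype(float) ** 2)) / total
    return s_neg, s_pos


def select_key_probes(
    table: ConnectivityDiffTable,
    negative_config: InflectionConfig | None = None,
    positive_config: InflectionConfig | None = None,
) -> ConnectivityDiffTable:
    """Flag probes in the extreme tails of the connectivity differences.

    Each sign branch is sorted ascending and cut at a knee or manual
    threshold.  A manual threshold applies inclusively to the values:
    m ≤ threshold for the negative branch, m ≥ threshold for the
    positive branch.  An automatic knee cuts by rank: the branch members
    on the extreme side of the knee point (most-negative head,
    respectively most-positive tail) are selected, so a value plateau at
    the knee is not dragged in wholesale.  An empty branch — or one too
    short for knee detection — yields an empty selection with a warning.
    """
    m = table.m
    ids = np.asarray(table.probe_ids, dtype=object)

    def branch(mask: np.ndarray, config, sign: str) -> tuple[list[str], float | None]:
        config = config or InflectionConfig()
        if not mask.any():
            log.warning("no %s differences; empty selection", sign)
            return [], None
        members = np.flatnonzero(mask)
        order = members[np.argsort(m[members], kind="stable")]
        values = m[order].astype(float)
        if config.method == "manual":
            if config.manual_threshold is None:
                raise ValueError("manual method requires manual_threshold")
            thr = float(config.manual_threshold)
            keep = mask & (m <= thr if sign == "negative" else m >= thr)
            return list(ids[keep]), thr
        if len(values) < 5:
            log.warning("%s branch of %d values too short for knee detection",
                        sign, len(values))
            return [], None
        index, value = find_inflection(values, config)
        chosen = order[:index] if sign == "negative" else order[index:]
        return list(ids[np.sort(chosen)]), float(value)

    neg_ids, neg_thr = branch(m < 0, negative_config, "negative")
    pos_ids, pos_thr = branch(m > 0, positive_config, "positive")
    log.info("key probes: %d negative (m <= %s), %d positive (m >= %s)",
             len(neg_ids), neg_thr, len(pos_ids), pos_thr)
    return ConnectivityDiffTable(
        probe_ids=list(table.probe_ids),
        condition_a=table.condition_a,
        condition_b=table.condition_b,
        degrees_a=table.degrees_a,
        degrees_b=table.degrees_b,
        m=table.m,
        gene_ids=dict(table.gene_ids),
        selected_negative=neg_ids,
        selected_positive=pos_ids,
        negative_threshold=neg_thr,
        positive_threshold=pos_thr,
    )
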