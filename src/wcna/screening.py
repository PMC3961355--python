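"""Distance-based screening of probes whose expression differs between conditions.

Each record's between-condition difference is summarized by the Euclidean
distance between its two normalized profiles.  Sorting these distances
ascending gives a curve whose high tail holds the records most affected
by the condition contrast; the tail is cut either at an automatically
detected knee (maximum discrete curvature of the smoothed curve) or at a
user-supplied distance threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from wcna.dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class InflectionConfig:
    """How to locate the knee of a sorted value curve.

    ``smoothing_window`` is the width of the centered moving average
    (odd; ``None`` chooses 101 for curves longer than 1000 points, else
    about 5 % of the length rounded up to odd).  ``method``:

    ``"chord"`` (default)
        The point of the smoothed curve farthest from the straight line
        joining its endpoints.  Scale-invariant, so it finds the global
        elbow even on short, plateau-heavy integer curves.
    ``"curvature-max"``
        Maximum discrete curvature |Δ²s| / (1 + (Δ¹s)²)^{3/2} of the
        smoothed curve.  Sensitive to axis units: best on long, dense
        curves whose slope is well below 1 per index step.
    ``"manual"``
        Apply ``manual_threshold`` directly to the raw sorted values.
    """

    smoothing_window: int | None = None
    method: str = "chord"
    manual_threshold: float | None = None

    def resolved_window(self, n: int) -> int:
        if self.smoothing_window is not None:
            w = int(self.smoothing_window)
        elif n > 1000:
            w = 101
        else:
            w = max(1, round(0.05 * n))
        if w % 2 == 0:
            w += 1
        if w < 1 or w > n:
            raise ValueError(f"smoothing window {w} invalid for length-{n} series")
        return w


@dataclass
class DistanceRanking:
    """Probes ordered by ascending between-condition distance.

    ``inflection`` is ``(index, value)`` where ``index`` is the 1-based
    rank of the last unselected probe, so
    ``len(selected_ids) + index == len(probe_ids)``.
    """

    probe_ids: list[str]
    distances: np.ndarray
    inflection: tuple[int, float]
    selected_ids: list[str]


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equal-length profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return values.copy()
    h = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    return (cum[hi] - cum[lo]) / (hi - lo)


def _curvature(s: np.ndarray) -> np.ndarray:
    """Discrete curvature |Δ²s| / (1 + (Δ¹s)²)^{3/2} at interior points."""
    d1 = (s[2:] - s[:-2]) / 2.0
    d2 = s[2:] - 2.0 * s[1:-1] + s[:-2]
    return np.abs(d2) / (1.0 + d1**2) ** 1.5


def find_inflection(
    sorted_values: Sequence[float], config: InflectionConfig | None = None
) -> tuple[int, float]:
    """Locate the knee of an ascending value curve.

    Returns ``(index, value)`` with ``index`` the 1-based rank of the
    knee point: ranks strictly greater than ``index`` form the selected
    tail.

    Automatic methods smooth with a centered moving average first and
    break ties at the earliest index; a warning is logged when the
    criterion is flat along the whole curve (e.g. a strictly linear
    sequence).  The chord method returns the point farthest from the
    line joining the smoothed curve's endpoints; the curvature method
    returns the interior point maximizing the discrete curvature
    |Δ²s| / (1 + (Δ¹s)²)^{3/2}.  The manual method takes the count of
    raw values ≤ the threshold, so the selected tail is exactly
    ``{v : v > threshold}``.
    """
    config = config or InflectionConfig()
    values = np.asarray(sorted_values, dtype=float)
    n = len(values)

    if config.method == "manual":
        if config.manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        t = float(config.manual_threshold)
        if not (values[0] <= t <= values[-1]):
            raise ValueError(
                f"manual_threshold {t} outside value range [{values[0]}, {values[-1]}]"
            )
        index = int(np.searchsorted(values, t, side="right"))
        return index, t

    if config.method not in ("chord", "curvature-max"):
        raise ValueError(f"unknown inflection method {config.method!r}")
    if n < 5:
        raise ValueError("knee detection needs at least 5 values")
    s = moving_average(values, config.resolved_window(n))

    if config.method == "chord":
        x = np.arange(n)
        # distance to the endpoint chord, up to a constant positive factor
        dist = np.abs((s[-1] - s[0]) * x - (n - 1) * (s - s[0]))
        if math.isclose(float(dist.max()), 0.0, abs_tol=1e-9 * (1 + abs(s[-1] - s[0]))):
            log.warning("curve is indistinguishable from its chord; returning earliest index")
        pos = int(np.argmax(dist))
        return pos + 1, float(s[pos])

    kappa = _curvature(s)
    if math.isclose(float(kappa.max()), float(kappa.min()), abs_tol=1e-12):
        log.warning("curvature is constant along the curve; returning earliest index")
    pos = int(np.argmax(kappa)) + 1  # interior offset, 0-based position in s
    return pos + 1, float(s[pos])


def rank_distances(
    dataset: ExpressionDataset, condition_a: str | None = None, condition_b: str | None = None
) -> tuple[list[str], np.ndarray]:
    """Per-probe between-condition distances, sorted ascending.

    The dataset must hold normalized, replicate-averaged profiles for
    exactly the two conditions being contrasted (or name them explicitly).
    """
    labels = dataset.condition_labels
    if condition_a is None or condition_b is None:
        if len(labels) != 2:
            raise ValueError("name the two conditions to contrast")
        condition_a, condition_b = labels
    a = dataset.matrix(condition_a)
    b = dataset.matrix(condition_b)
    d = np.sqrt(np.sum((a - b) ** 2, axis=1))
    order = np.argsort(d, kind="stable")
    return [dataset.probe_ids[i] for i in order], d[order]


def select_important(
    dataset: ExpressionDataset,
    config: InflectionConfig | None = None,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> DistanceRanking:
    """Rank all records by between-condition distance and select the tail.

    Records with rank strictly greater than the inflection index are
    flagged as selected; with a manual threshold t this is exactly
    ``{i : d_i > t}``.
    """
    ids, dists = rank_distances(dataset, condition_a, condition_b)
    if np.allclose(dists, dists[0]):
        log.warning("all distances equal; selecting no probes")
        return DistanceRanking(ids, dists, (len(ids), float(dists[-1])), [])
    index, value = find_inflection(dists, config)
    selected = ids[index:]
    log.info("screening: %d of %d records above inflection (%d, %.4g)",
             len(selected), len(ids), index, value)
    return DistanceRanking(ids, dists, (index, value), selected)
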