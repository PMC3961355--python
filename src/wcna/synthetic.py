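"""Synthetic two-condition time-course generator with planted co-expression modules.

The generator emulates the design of a two-day circadian microarray
experiment: 12 timepoints sampled every 4 h under two conditions (e.g. a
light/dark cycle vs constant darkness), 3 replicates per sample, and a
mix of rhythmic and arrhythmic probes.  Planted modules share a latent
signal — a sinusoid of configurable period and amplitude plus latent
noise — mixed into each member so that the expected within-module
correlation hits a per-condition target; making a module tight in one
condition and loose in the other plants a known differential-connectivity
signal for the downstream network stages to recover.

The module also hosts small, loop-based reference implementations of the
correlation → adjacency → degree → difference chain (:func:`oracle_chain`
and friends) used as independent cross-checks in the test suite, and a
deterministic 8-probe worked example with expectations precomputed by
those references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from wcna.dataset import ExpressionDataset


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``correlation`` and ``amplitude`` map condition label → target
    within-module Pearson correlation (in [0, 1]) and rhythm amplitude
    (expression units).  ``period_hours`` is the rhythm period.
    """

    size: int
    correlation: Mapping[str, float]
    amplitude: Mapping[str, float]
    period_hours: float = 24.0


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_dataset`.

    Defaults mirror the two-day circadian design: 12 timepoints at 4 h
    intervals, 3 replicates, conditions LD and DD.  ``background_sd`` is
    the per-timepoint noise of unplanted probes and of module latent
    noise; ``replicate_sd`` the additive noise of individual replicates;
    ``baseline`` a constant intensity offset (removed by normalization).
    """

    n_probes: int = 300
    n_timepoints: int = 12
    n_replicates: int = 3
    interval_hours: float = 4.0
    conditions: tuple[str, str] = ("LD", "DD")
    modules: list[ModuleSpec] = field(default_factory=list)
    background_sd: float = 1.0
    replicate_sd: float = 0.3
    baseline: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if sum(m.size for m in self.modules) > self.n_probes:
            raise ValueError("module sizes exceed n_probes")
        for mod in self.modules:
            for cond in self.conditions:
                rho = mod.correlation[cond]
                if not (0.0 <= rho <= 1.0):
                    raise ValueError(f"infeasible correlation target {rho}")


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a dataset plus a ground-truth table.

    Module member i in condition c is ``√ρ_c · z_c + √(1−ρ_c) · ε_i`` with
    z_c the standardized latent (amplitude-weighted sinusoid plus latent
    noise) and ε_i unit Gaussian noise, so the expected pairwise
    within-module correlation is ρ_c.  Background probes are pure noise.
    Replicates add independent Gaussian noise on top of the probe signal.

    The ground truth records each probe's module (−1 = background) and
    the expected sign of its connectivity difference m = degree(first
    condition) − degree(second condition): a module tighter in the second
    condition gives negative m.

    Fixed seed ⇒ bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_timepoints) * config.interval_hours
    cond_a, cond_b = config.conditions

    profiles = {c: np.empty((config.n_probes, config.n_timepoints)) for c in config.conditions}
    module_of = np.full(config.n_probes, -1, dtype=int)
    expected_sign = np.zeros(config.n_probes, dtype=int)

    row = 0
    for mi, mod in enumerate(config.modules):
        rhythm = np.sin(2.0 * np.pi * t / mod.period_hours)
        members = slice(row, row + mod.size)
        module_of[members] = mi
        rho_a, rho_b = mod.correlation[cond_a], mod.correlation[cond_b]
        expected_sign[members] = int(np.sign(rho_a - rho_b))
        for cond in config.conditions:
            latent = (
                mod.amplitude[cond] * rhythm
                + config.background_sd * rng.normal(size=config.n_timepoints)
            )
            sd = latent.std()
            z = (latent - latent.mean()) / sd if sd > 0 else np.zeros_like(latent)
            rho = mod.correlation[cond]
            eps = rng.normal(size=(mod.size, config.n_timepoints))
            profiles[cond][members] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        row += mod.size
    for cond in config.conditions:
        profiles[cond][row:] = config.background_sd * rng.normal(
            size=(config.n_probes - row, config.n_timepoints)
        )

    values = {}
    for cond in config.conditions:
        reps = profiles[cond][:, :, None] + config.replicate_sd * rng.normal(
            size=(config.n_probes, config.n_timepoints, config.n_replicates)
        )
        values[cond] = config.baseline + reps

    width = len(str(config.n_probes - 1))
    probe_ids = [f"P{idx:0{width}d}" for idx in range(config.n_probes)]
    truth = pd.DataFrame(
        {"probe_id": probe_ids, "module": module_of, "expected_m_sign": expected_sign}
    )
    dataset = ExpressionDataset(
        probe_ids=probe_ids, timepoints=t, values=values
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# independent loop-based references (test oracles)


def oracle_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Textbook Pearson correlation via explicit sums (no numpy.corrcoef)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    return sxy / (sxx * syy) ** 0.5


def oracle_dwt_haar(x: Sequence[float]) -> tuple[list[float], list[float]]:
    """Haar analysis filters written as the pairwise sum/difference formulas."""
    root2 = 2.0**0.5
    approx = [(x[2 * k] + x[2 * k + 1]) / root2 for k in range(len(x) // 2)]
    detail = [(x[2 * k] - x[2 * k + 1]) / root2 for k in range(len(x) // 2)]
    return approx, detail


def oracle_chain(
    vectors_a: np.ndarray, vectors_b: np.ndarray, tau: float = 0.7
) -> dict[str, np.ndarray]:
    """Correlation → adjacency → degree → difference, all with plain loops.

    Independent of :mod:`wcna.network`; used to cross-check it on small
    instances.
    """
    out: dict[str, np.ndarray] = {}
    for label, vecs in (("a", vectors_a), ("b", vectors_b)):
        n = len(vecs)
        R = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                R[i, j] = R[j, i] = oracle_pearson(list(vecs[i]), list(vecs[j]))
        L = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                if i != j and tau <= abs(R[i, j]) <= 1.0 + 1e-12:
                    L[i, j] = 1
        out[f"R_{label}"] = R
        out[f"L_{label}"] = L
        out[f"degrees_{label}"] = L.sum(axis=1)
    out["m"] = out["degrees_a"] - out["degrees_b"]
    return out


# ---------------------------------------------------------------------------
# worked example


@dataclass
class WorkedExample:
    """Deterministic 8-probe fixture with oracle-computed expectations.

    ``dataset`` holds normalized single-replicate profiles for conditions
    LD and DD.  The expectation fields (R, L, degrees per condition, and
    m) are produced by the loop-based references above applied to the
    Haar frequency vectors, independently of the pipeline modules.
    """

    dataset: ExpressionDataset
    frequency: dict[str, np.ndarray]
    R: dict[str, np.ndarray]
    L: dict[str, np.ndarray]
    degrees: dict[str, np.ndarray]
    m: np.ndarray
    tau: float = 0.7


def make_worked_example() -> WorkedExample:
    """An 8-probe, 12-timepoint fixture exercising the whole network chain.

    Probes 0–3 follow a 24 h rhythm tightly in LD and are decoupled in
    DD; probes 4–6 couple tightly in DD only; probe 7 is an arrhythmic
    loner.  All values come from fixed trigonometric expressions (no
    RNG), so the fixture is identical across runs and platforms.
    """
    t = np.arange(12) * 4.0
    base = np.sin(2 * np.pi * t / 24.0)
    drift = np.cos(2 * np.pi * t / 48.0)
    wiggle = np.sin(2 * np.pi * t / 16.0 + 0.7)

    ld = np.stack(
        [
            base,
            0.9 * base + 0.1 * drift,
            0.8 * base - 0.2 * wiggle,
            -base,  # anti-correlated: |r| still above threshold
            drift + 0.6 * wiggle,
            wiggle - 0.5 * drift,
            0.3 * drift - wiggle,
            np.sin(2 * np.pi * t / 12.0 + 1.3),
        ]
    )
    dd = np.stack(
        [
            base + 1.5 * wiggle,
            drift - 0.8 * wiggle,
            -0.7 * drift + 0.4 * base,
            wiggle + 0.3 * base,
            drift,
            0.95 * drift + 0.05 * base,
            -drift + 0.1 * wiggle,
            np.cos(2 * np.pi * t / 12.0 - 0.4),
        ]
    )

    def norm(rows: np.ndarray) -> np.ndarray:
        out = np.empty_like(rows)
        for i, r in enumerate(rows):
            lo, hi = r.min(), r.max()
            out[i] = 2 * (r - lo) / (hi - lo) - 1 if hi > lo else 0.0
        return out

    probe_ids = [f"W{i}" for i in range(8)]
    dataset = ExpressionDataset(
        probe_ids=probe_ids,
        timepoints=t,
        values={"LD": norm(ld)[:, :, None], "DD": norm(dd)[:, :, None]},
    )
    freq = {}
    for cond in ("LD", "DD"):
        rows = []
        for i in range(8):
            a, d = oracle_dwt_haar(list(dataset.values[cond][i, :, 0]))
            rows.append(a + d)
        freq[cond] = np.array(rows)
    chain = oracle_chain(freq["LD"], freq["DD"], tau=0.7)
    return WorkedExample(
        dataset=dataset,
        frequency=freq,
        R={"LD": chain["R_a"], "DD": chain["R_b"]},
        L={"LD": chain["L_a"], "DD": chain["L_b"]},
        degrees={"LD": chain["degrees_a"], "DD": chain["degrees_b"]},
        m=chain["m"],
    )
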