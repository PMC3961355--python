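"""Single-level dyadic discrete wavelet transform of expression profiles.

Each normalized profile of length 2n is decomposed once (Mallat filter
bank, dyadic dilation/translation, periodic boundary) into n
approximation coefficients C = (c_1..c_n) — the low-frequency trend —
and n detail coefficients D = (d_1..d_n) — the high-frequency
fluctuation.  For the default Haar basis,

    c_k = (x_{2k-1} + x_{2k}) / √2,    d_k = (x_{2k-1} - x_{2k}) / √2.

The probe's *frequency vector* is the concatenation [C, D], the same
length as the original profile; with an orthonormal basis the transform
conserves energy (‖x‖² = ‖C‖² + ‖D‖²) and is perfectly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from wcna.dataset import ExpressionDataset


@dataclass(frozen=True)
class WaveletSpec:
    """Basis and boundary handling for the level-1 dyadic decomposition.

    ``basis`` is any orthogonal PyWavelets name ("haar", "db2", ...).
    Decomposition depth is fixed at one level — profiles of length 2n
    yield n + n coefficients — and the boundary mode is periodization,
    which keeps the coefficient count at exactly half the signal length
    and preserves orthonormality.
    """

    basis: str = "haar"
    mode: str = "periodization"

    def wavelet(self) -> pywt.Wavelet:
        try:
            w = pywt.Wavelet(self.basis)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet basis {self.basis!r}") from exc
        if not w.orthogonal:
            raise ValueError(f"basis {self.basis!r} is not orthogonal")
        return w


@dataclass
class FrequencyVector:
    """Level-1 wavelet coefficients of one probe's profile in one condition."""

    probe_id: str
    condition: str
    approx: np.ndarray
    detail: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        """The [approximation, detail] concatenation fed to correlation."""
        return np.concatenate([self.approx, self.detail])


def _validate(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if len(values) % 2 != 0:
        raise ValueError(
            f"profile length {len(values)} is odd; pad explicitly before transforming"
        )
    if not np.isfinite(values).all():
        raise ValueError("profile contains non-finite values")
    return values


def dwt_level1(values: np.ndarray, spec: WaveletSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One level of discrete wavelet decomposition.

    Returns ``(approx, detail)``, each half the profile length.
    """
    spec = spec or WaveletSpec()
    values = _validate(values)
    approx, detail = pywt.dwt(values, spec.wavelet(), mode=spec.mode)
    return approx, detail


def idwt_level1(
    approx: np.ndarray, detail: np.ndarray, spec: WaveletSpec | None = None
) -> np.ndarray:
    """Invert :func:`dwt_level1`; reconstructs the profile exactly."""
    spec = spec or WaveletSpec()
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape:
        raise ValueError("approx and detail must have equal length")
    return pywt.idwt(approx, detail, spec.wavelet(), mode=spec.mode)


def build_frequency_vectors(
    dataset: ExpressionDataset, spec: WaveletSpec | None = None
) -> dict[str, np.ndarray]:
    """Transform every record of every condition.

    Returns ``condition -> (n_probes, n_timepoints)`` matrices whose rows
    are the combined [approx, detail] frequency vectors, probe order
    identical across conditions (the dataset container enforces a single
    shared probe list).
    """
    spec = spec or WaveletSpec()
    out: dict[str, np.ndarray] = {}
    for cond in dataset.condition_labels:
        mat = dataset.matrix(cond)
        _validate(mat[0])
        approx, detail = pywt.dwt(mat, spec.wavelet(), mode=spec.mode, axis=1)
        out[cond] = np.concatenate([approx, detail], axis=1)
    return out


def frequency_vector(
    dataset: ExpressionDataset, probe_id: str, condition: str, spec: WaveletSpec | None = None
) -> FrequencyVector:
    """The :class:`FrequencyVector` of a single probe in one condition."""
    idx = dataset.probe_ids.index(probe_id)
    approx, detail = dwt_level1(dataset.matrix(condition)[idx], spec)
    return FrequencyVector(probe_id=probe_id, condition=condition, approx=approx, detail=detail)
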