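"""Frequency-domain analysis of voxel time-courses.

Per-voxel one-sided power spectra (mean removed, no window, no detrending),
tumour-average spectra, cohort mean +/- s.d. and dominant-frequency
read-out.  Power is normalised as |DFT|^2 / n with interior bins doubled,
so the spectrum of a voxel sums to n times its (population) time-domain
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SpectrumResult",
    "average_spectrum",
    "dominant_frequency",
    "cohort_spectra",
    "hz_to_cycles_per_hour",
]


@dataclass
class SpectrumResult:
    """A one-sided power spectrum (zero-frequency bin excluded)."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids differ")
        if (self.power < -1e-30).any():
            raise ValueError("power must be non-negative")


def average_spectrum(
    field_matrix: np.ndarray,
    frame_interval: float,
    voxels: Optional[np.ndarray] = None,
    provenance: Optional[dict] = None,
) -> SpectrumResult:
    """Voxel-average power spectrum of a (time x voxels) field.

    Each voxel time-course is mean-removed and Fourier transformed; the
    per-voxel power spectra are then averaged arithmetically.  ``voxels``
    optionally restricts the average to a boolean voxel subset.
    """
    x = np.asarray(field_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (time, voxels) matrix")
    n = x.shape[0]
    if n < 8:
        raise ValueError("need at least 8 frames")
    if voxels is not None:
        x = x[:, np.asarray(voxels, dtype=bool)]
    if x.shape[1] == 0:
        raise ValueError("empty voxel set")
    xc = x - x.mean(axis=0)
    spec = np.abs(np.fft.rfft(xc, axis=0)) ** 2 / n
    scale = np.full(spec.shape[0], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = (spec * scale[:, None]).mean(axis=1)[1:]
    freqs = np.fft.rfftfreq(n, d=frame_interval)[1:]
    prov = dict(provenance or {})
    prov.setdefault("n_voxels", int(x.shape[1]))
    prov.setdefault("n_frames", int(n))
    return SpectrumResult(frequencies=freqs, power=power, provenance=prov)


def dominant_frequency(spectrum: SpectrumResult) -> float:
    """Frequency of the maximum-power bin (peak height).

    Ties are broken toward the lower frequency.  An all-zero spectrum has
    no dominant frequency and returns NaN with a warning.
    """
    if spectrum.power.size == 0:
        raise ValueError("empty spectrum")
    if spectrum.power.max() <= 0:
        warnings.warn("all-zero spectrum: dominant frequency undefined")
        return float("nan")
    return float(spectrum.frequencies[int(np.argmax(spectrum.power))])


def cohort_spectra(spectra: Sequence[SpectrumResult]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean and sample s.d. across a cohort of spectra.

    All spectra must share the same frequency grid.  Returns
    ``(frequencies, mean, sd)``; a single-spectrum cohort has zero s.d.
    """
    if len(spectra) == 0:
        raise ValueError("empty cohort")
    freqs = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != freqs.shape or not np.allclose(s.frequencies, freqs):
            raise ValueError("spectra are on different frequency grids")
    stack = np.stack([s.power for s in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
    return freqs, mean, sd


def hz_to_cycles_per_hour(frequency_hz: float) -> float:
    """Convert a frequency in Hz to cycles per hour (1e-3 Hz = 3.6 h^-1)."""
    return float(frequency_hz) * 3600.0
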