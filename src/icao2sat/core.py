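"""Core data containers and R2* estimation.

The BOLD effect makes the effective transverse relaxation rate R2* (= 1/T2*)
of gradient-echo MRI sensitive to the local concentration of paramagnetic
deoxyhaemoglobin: more deoxyhaemoglobin means faster signal decay and a
higher R2*.  A dynamic series of R2* maps over a tumour therefore tracks
fluctuations in blood oxygenation, voxel by voxel.

This module defines the two primary inputs of the analysis -- a masked 4D
R2* time-series and a concurrently recorded systemic arterial oxygen
saturation (O2sat) trace -- together with the log-linear multi-echo R2*
estimator and simple temporal summary maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "R2StarSeries",
    "O2SatTrace",
    "SummaryMap",
    "estimate_r2star",
    "temporal_sd_map",
]


@dataclass
class R2StarSeries:
    """A voxel-wise R2* time-series over a tumour.

    Parameters
    ----------
    values
        R2* in ms^-1 on a ``(time, z, y, x)`` grid.  Values outside the
        mask are ignored (and may be zero).
    frame_interval
        Seconds per dynamic frame (> 0).
    mask
        Boolean ``(z, y, x)`` grid marking tumour voxels.
    voxel_size
        Optional ``(z, y, x)`` voxel dimensions in mm (metadata only).
    """

    values: np.ndarray
    frame_interval: float
    mask: np.ndarray
    voxel_size: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError("values must be a 4D (time, z, y, x) array")
        if self.mask.ndim != 3 or self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask must be 3D and match the spatial grid")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.values.shape[0] < 2:
            raise ValueError("series must contain at least two frames")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if not np.isfinite(self.values[:, self.mask]).all():
            raise ValueError("non-finite R2* values inside the mask")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition mid-points of each frame, in seconds from start."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval

    def masked_matrix(self) -> np.ndarray:
        """Return the ``(time, n_voxels)`` matrix X of in-mask time-courses.

        Voxels are ordered by C-order scan of the mask; the same ordering
        is used by every downstream operation.
        """
        return self.values[:, self.mask]

    def scatter(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values (last axis = in-mask voxel) onto the grid."""
        flat = np.asarray(flat)
        out = np.full(flat.shape[:-1] + self.mask.shape, fill, dtype=float)
        out[..., self.mask] = flat
        return out


@dataclass
class O2SatTrace:
    """Systemic arterial oxyhaemoglobin saturation from pulse oximetry.

    ``times`` are seconds from the start of the MRI acquisition; ``values``
    are saturation percentages in [0, 100].
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1D arrays")
        if self.times.size < 2:
            raise ValueError("trace needs at least two samples")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("O2sat values must lie in [0, 100]")

    def resample(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolate the trace at the requested times.

        The trace must cover the requested window; extrapolation is refused
        because the oximeter and scanner run concurrently.
        """
        times = np.asarray(times, dtype=float)
        if times.min() < self.times[0] or times.max() > self.times[-1]:
            raise ValueError("O2sat trace does not cover the requested times")
        return np.interp(times, self.times, self.values)


@dataclass
class SummaryMap:
    """A per-voxel scalar summary (e.g. temporal s.d.) on the tumour grid.

    ``values`` is a 3D grid with NaN outside the mask.
    """

    values: np.ndarray
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def estimate_r2star(echo_times: Sequence[float], signals: np.ndarray) -> np.ndarray:
    """Estimate R2* (ms^-1) from multi-echo gradient-echo magnitudes.

    Assumes mono-exponential decay ``S(TE) = S0 * exp(-R2* * TE)`` and fits
    the decay rate by ordinary least squares of ``-ln S`` against the echo
    time.  ``signals`` may carry extra leading axes (e.g. a volume), with
    echoes on the last axis.

    Noisy data can produce a non-positive estimate; the value is returned
    as-is so the caller can flag it.
    """
    te = np.asarray(echo_times, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if te.ndim != 1 or te.size < 2:
        raise ValueError("need at least two echoes")
    if not (np.diff(te) > 0).all():
        raise ValueError("echo times must be strictly increasing")
    if sig.shape[-1] != te.size:
        raise ValueError("last axis of signals must match echo_times")
    if (sig <= 0).any():
        raise ValueError("signals must be positive (log-linear fit)")
    y = -np.log(sig)
    te_c = te - te.mean()
    slope = (y * te_c).sum(axis=-1) / (te_c**2).sum()
    return slope


def temporal_sd_map(series: R2StarSeries) -> SummaryMap:
    """Per-voxel sample standard deviation (ddof=1) of R2* over time.

    High values mark voxels with large oxygenation fluctuations; the map is
    the usual first look at a dynamic tumour acquisition.
    """
    x = series.masked_matrix()
    sd = x.std(axis=0, ddof=1)
    values = np.full(series.mask.shape, np.nan)
    values[series.mask] = sd
    return SummaryMap(values=values, mask=series.mask, label="temporal_sd")
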