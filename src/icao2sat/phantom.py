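"""Synthetic 4D R2* phantoms with ground-truth oscillation labels.

The generator emulates a dynamic gradient-echo tumour acquisition: a ~60
minute series at 3.8 s per frame (947 frames) over an ellipsoidal tumour
mask, together with a concurrently sampled systemic O2sat trace.  Three
signal classes are injected:

* a *systemic* fluctuation -- a slow oscillation shared with the O2sat
  trace.  The sign convention is negative: a rise in arterial saturation
  lowers deoxyhaemoglobin and hence lowers R2*;
* *tumour-specific* oscillators -- spatially clustered sinusoids below
  1e-3 Hz, with random phase, independent of the systemic trace;
* white Gaussian noise in every mask voxel.

Ground-truth voxel label maps for both classes are returned so that
recovery by the decomposition pipeline can be scored.  The two truth maps
may overlap: a voxel can carry both a systemic and a tumour-specific
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import O2SatTrace, R2StarSeries

__all__ = [
    "ClusterSpec",
    "PhantomConfig",
    "SyntheticDataset",
    "generate_o2sat_trace",
    "generate_phantom",
    "balanced_accuracy",
]


@dataclass(frozen=True)
class ClusterSpec:
    """An ellipsoidal tumour-specific oscillator: centre (z, y, x), radius
    (scalar or per-axis semiaxes, voxels), R2* amplitude in ms^-1 and optional frequency in Hz (defaults
    cycle through ``PhantomConfig.tumour_frequencies``)."""

    centre: Tuple[int, int, int]
    radius: object  # scalar (sphere) or (z, y, x) semiaxes
    amplitude: float
    frequency: Optional[float] = None

    @property
    def semiaxes(self) -> Tuple[float, float, float]:
        r = self.radius
        return tuple(r) if np.ndim(r) else (float(r),) * 3


def _default_clusters() -> Tuple[ClusterSpec, ...]:
    return (
        ClusterSpec(centre=(2, 12, 12), radius=(2.2, 4.0, 4.0), amplitude=0.012),
        ClusterSpec(centre=(2, 19, 19), radius=(2.2, 4.0, 4.0), amplitude=0.012),
    )


@dataclass
class PhantomConfig:
    """Parameters of the synthetic acquisition.

    Defaults emulate the study conditions: a 32 x 32 x 5 grid, 947 frames
    of 3.8 s (~60 min), oscillation frequencies at or below 1e-3 Hz, an
    O2sat baseline near 95% with a few-percent slow excursion, and noise
    giving the injected oscillations an amplitude SNR of about 3.

    The default frequencies are harmonics of the acquisition window
    (k / (n_frames * frame_interval), i.e. exact DFT bins ~5.6e-4 Hz and
    ~8.3e-4 Hz) so that the injected systemic and tumour-specific sources
    are orthogonal over the recorded window and the ground-truth class of
    every voxel is unambiguous.

    The default systemic region is a peripheral shell (all mask voxels
    beyond ``systemic_inner_radius`` in-plane voxels from the tumour axis),
    reflecting the tendency of systemically driven fluctuations to sit at
    the tumour rim where the feeding vasculature enters; the default
    tumour-specific clusters occupy the core, spatially disjoint from the
    shell.  Setting ``systemic_semiaxes`` instead switches to a central
    ellipsoidal systemic region (which may overlap clusters: spatial ICA
    separates overlapping sources less cleanly, exactly as with real
    tumours).
    """

    shape: Tuple[int, int, int] = (5, 32, 32)  # (z, y, x)
    frame_interval: float = 3.8
    n_frames: int = 947  # floor(3600 / 3.8)
    mask_semiaxes: Tuple[float, float, float] = (2.6, 12.5, 12.5)
    systemic_frequency: float = 2.0 / (947 * 3.8)  # ~5.56e-4 Hz
    tumour_frequencies: Tuple[float, ...] = (3.0 / (947 * 3.8),)  # ~8.34e-4 Hz
    systemic_inner_radius: Optional[float] = 9.0  # periphery shell (voxels)
    systemic_semiaxes: Optional[Tuple[float, float, float]] = None
    systemic_gain: float = 0.004  # ms^-1 per % O2sat deviation
    clusters: Tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    noise_sd: float = 0.004  # ms^-1
    baseline_r2star: float = 0.12  # ms^-1
    o2sat_baseline: float = 95.0  # %
    o2sat_excursion: float = 3.0  # % amplitude of the slow oscillation
    o2sat_noise_sd: float = 0.2  # % stationary s.d. of the AR(1) noise
    o2sat_ar: float = 0.8  # AR(1) coefficient at the oximeter rate
    o2sat_rate_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.frame_interval)
        freqs = (self.systemic_frequency, *self.tumour_frequencies)
        if any(f <= 0 or f >= nyquist for f in freqs):
            raise ValueError("frequencies must lie in (0, Nyquist)")
        if self.noise_sd < 0 or self.systemic_gain < 0:
            raise ValueError("amplitudes must be non-negative")
        if any(c.amplitude < 0 for c in self.clusters):
            raise ValueError("cluster amplitudes must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval


@dataclass
class SyntheticDataset:
    """A phantom acquisition with its ground truth."""

    series: R2StarSeries
    o2sat: O2SatTrace
    truth_systemic: np.ndarray
    truth_tumour_specific: np.ndarray
    params: dict


def _rngs(seed: int):
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _ellipsoid(shape, centre, semiaxes) -> np.ndarray:
    zz, yy, xx = np.indices(shape)
    d2 = (
        ((zz - centre[0]) / semiaxes[0]) ** 2
        + ((yy - centre[1]) / semiaxes[1]) ** 2
        + ((xx - centre[2]) / semiaxes[2]) ** 2
    )
    return d2 <= 1.0


def generate_o2sat_trace(config: PhantomConfig) -> O2SatTrace:
    """Synthetic pulse-oximetry trace covering the acquisition.

    Baseline plus a slow sinusoid at the systemic frequency plus AR(1)
    noise, sampled at ``o2sat_rate_hz`` and clipped to [0, 100].
    Deterministic for a fixed config seed.
    """
    rng, _ = _rngs(config.seed)
    n = int(np.ceil(config.duration * config.o2sat_rate_hz)) + 1
    times = np.arange(n) / config.o2sat_rate_hz
    values = config.o2sat_baseline + config.o2sat_excursion * np.sin(
        2 * np.pi * config.systemic_frequency * times
    )
    if config.o2sat_noise_sd > 0:
        phi = config.o2sat_ar
        innov = rng.normal(0.0, config.o2sat_noise_sd * np.sqrt(1 - phi**2), n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.o2sat_noise_sd)
        for t in range(1, n):
            noise[t] = phi * noise[t - 1] + innov[t]
        values = values + noise
    if values.max() > 105.0 or values.min() < -5.0:
        warnings.warn("O2sat excursion exceeds the physical range by > 5 points")
    return O2SatTrace(times=times, values=np.clip(values, 0.0, 100.0))


def generate_phantom(config: PhantomConfig) -> SyntheticDataset:
    """Generate a phantom acquisition with ground-truth label maps.

    The systemic contribution at each systemic voxel is
    ``-gain * (O2sat(t) - mean)`` with the trace interpolated to the frame
    mid-points, so with zero noise the in-mask systemic time-courses
    correlate perfectly (negatively) with the trace.  Cluster voxels
    additionally receive their sinusoid; Gaussian noise is added to every
    mask voxel.  Raises if a cluster is not contained in the tumour mask.
    """
    _, rng = _rngs(config.seed)
    shape = config.shape
    centre = tuple((s - 1) / 2.0 for s in shape)
    mask = _ellipsoid(shape, centre, config.mask_semiaxes)
    if not mask.any():
        raise ValueError("tumour mask is empty; enlarge mask_semiaxes")

    o2sat = generate_o2sat_trace(config)
    t_mid = config.frame_times
    o2_frames = o2sat.resample(t_mid)
    o2_dev = o2_frames - o2_frames.mean()

    if config.systemic_semiaxes is not None:
        truth_sys = _ellipsoid(shape, centre, config.systemic_semiaxes) & mask
    elif config.systemic_inner_radius is not None:
        # peripheral shell: systemic oscillations are typically carried by
        # the feeding vasculature at the tumour rim
        zz, yy, xx = np.indices(shape)
        rad2 = (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
        truth_sys = mask & (rad2 > config.systemic_inner_radius**2)
    else:
        truth_sys = mask.copy()
    if config.systemic_gain == 0:
        truth_sys = np.zeros(shape, dtype=bool)

    values = np.zeros((config.n_frames,) + shape)
    values[:, mask] = config.baseline_r2star
    if config.systemic_gain > 0:
        values[:, truth_sys] += (-config.systemic_gain * o2_dev)[:, None]

    truth_tsp = np.zeros(shape, dtype=bool)
    phases, freqs_used = [], []
    for i, spec in enumerate(config.clusters):
        freq = spec.frequency
        if freq is None:
            freq = config.tumour_frequencies[i % len(config.tumour_frequencies)]
        sphere = _ellipsoid(shape, spec.centre, spec.semiaxes)
        if (sphere & ~mask).any():
            raise ValueError(f"cluster {i} at {spec.centre} extends outside the mask")
        phase = rng.uniform(0.0, 2 * np.pi)
        phases.append(phase)
        freqs_used.append(freq)
        if spec.amplitude > 0:
            wave = spec.amplitude * np.sin(2 * np.pi * freq * t_mid + phase)
            values[:, sphere] += wave[:, None]
            truth_tsp |= sphere

    if config.noise_sd > 0:
        values[:, mask] += rng.normal(0.0, config.noise_sd, (config.n_frames, int(mask.sum())))

    series = R2StarSeries(
        values=values, frame_interval=config.frame_interval, mask=mask
    )
    params = {
        "seed": config.seed,
        "systemic_frequency_hz": config.systemic_frequency,
        "cluster_frequencies_hz": freqs_used,
        "cluster_phases_rad": phases,
        "cluster_amplitudes": [c.amplitude for c in config.clusters],
        "systemic_gain": config.systemic_gain,
        "noise_sd": config.noise_sd,
        "n_mask_voxels": int(mask.sum()),
        "n_systemic_voxels": int(truth_sys.sum()),
        "n_tumour_specific_voxels": int(truth_tsp.sum()),
    }
    return SyntheticDataset(
        series=series,
        o2sat=o2sat,
        truth_systemic=truth_sys,
        truth_tumour_specific=truth_tsp,
        params=params,
    )


def balanced_accuracy(predicted: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Mean of sensitivity and specificity of a voxel label map within the mask."""
    pred = np.asarray(predicted, dtype=bool)[mask]
    true = np.asarray(truth, dtype=bool)[mask]
    pos = true.sum()
    neg = (~true).sum()
    sens = (pred & true).sum() / pos if pos else 1.0
    spec = (~pred & ~true).sum() / neg if neg else 1.0
    return float((sens + spec) / 2.0)
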