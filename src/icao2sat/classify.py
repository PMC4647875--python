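"""Component classification and class-wise reconstruction.

Each independent component is assigned to one of three classes:

* **systemic** -- its time-course correlates significantly (two-sided
  p < 0.01) with the systemic O2sat trace;
* **tumour-specific** -- not systemic, but either its time-course has a
  dominant spectral peak (evidence of a cycling process), or its spatial
  map shows a coherent cluster (>= 5 face-connected voxels at |z| >= 2.2)
  together with a non-noise-like ("distinctive") time-course;
* **noise** -- everything else.

Class-wise R2* fields are then rebuilt by running the decomposition in
reverse (summing ``M_col @ S_row`` over the components of a class), and
individual voxels are thresholded against the O2sat trace: voxels of the
systemic field with p < 0.01 are systemically oscillating, voxels of the
tumour-specific field with p > 0.05 are tumour-specific.  A voxel only
enters a class map if the class field actually carries signal there (its
temporal s.d. must reach a configurable fraction of the residual noise
floor); the correlation coefficient is scale-free, so without this gate
arbitrarily small spill-over of a component into a voxel would be enough
to label it.

No multiple-testing correction is applied at either the component or the
voxel level: thresholds act on raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .core import O2SatTrace
from .decompose import DEFAULT_PEAK_RATIO, ICADecomposition, has_dominant_peak
from .stats import pearson_t_p

__all__ = [
    "SYSTEMIC",
    "TUMOUR_SPECIFIC",
    "NOISE",
    "Cluster",
    "ComponentLabel",
    "ReconstructedFields",
    "pearson_vs_o2sat",
    "zscore_threshold_map",
    "find_clusters",
    "distinctiveness",
    "classify_components",
    "reconstruct_class",
    "reconstruct_fields",
    "threshold_voxels",
    "pearson_map",
]

SYSTEMIC = "systemic"
TUMOUR_SPECIFIC = "tumour_specific"
NOISE = "noise"

DEFAULT_Z_THRESHOLD = 2.2
DEFAULT_MIN_CLUSTER = 5
DEFAULT_P_SYSTEMIC = 0.01
DEFAULT_P_TUMOUR = 0.05
DEFAULT_DISTINCTIVENESS = 0.3
DEFAULT_AMPLITUDE_GATE = 0.5


@dataclass
class Cluster:
    """A connected set of suprathreshold voxels in a component map."""

    indices: np.ndarray  # (n, 3) voxel coordinates (z, y, x)
    size: int
    sign: int  # +1 / -1 dominant excursion


@dataclass
class ComponentLabel:
    """Classification of one independent component with its evidence."""

    index: int
    label: str
    o2sat_r: float
    o2sat_p: float
    has_peak: bool
    peak_frequency_hz: float
    clusters: List[Cluster] = field(default_factory=list)
    distinctiveness: float = float("nan")

    @property
    def cluster_sizes(self) -> List[int]:
        return [c.size for c in self.clusters]


@dataclass
class ReconstructedFields:
    """Class-wise R2* fields and the voxel-level class maps."""

    systemic: np.ndarray  # (time, voxels)
    tumour_specific: np.ndarray
    noise: np.ndarray
    systemic_mask: Optional[np.ndarray] = None  # 3D bool
    tumour_specific_mask: Optional[np.ndarray] = None
    systemic_r: Optional[np.ndarray] = None
    systemic_p: Optional[np.ndarray] = None
    tumour_specific_r: Optional[np.ndarray] = None
    tumour_specific_p: Optional[np.ndarray] = None
    report: dict = field(default_factory=dict)


def _frame_midpoints(n: int, frame_interval: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * frame_interval


def pearson_vs_o2sat(timecourse, o2sat: O2SatTrace, frame_interval: float):
    """Correlate a time-course with the O2sat trace.

    The trace is linearly interpolated to the frame mid-points (no lag is
    modelled: murine circulation time is far below the frame interval).
    Returns ``(r, p)`` with a two-sided p from the t transform.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.size < 4:
        raise ValueError("need at least 4 frames")
    y = o2sat.resample(_frame_midpoints(tc.size, frame_interval))
    res = pearson_t_p(tc, y)
    return res.statistic, res.pvalue


def zscore_threshold_map(values, z_threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """Boolean map of voxels with |z| >= threshold after z-normalisation.

    The map is normalised to zero mean and unit variance over its voxels;
    a constant map yields an empty result (with a warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("map must have more than one voxel")
    sd = v.std()
    if sd == 0:
        warnings.warn("constant spatial map: empty threshold result")
        return np.zeros(v.shape, dtype=bool)
    z = (v - v.mean()) / sd
    return np.abs(z) >= z_threshold


def find_clusters(
    thresholded: np.ndarray, min_size: int = DEFAULT_MIN_CLUSTER, connectivity: int = 1
) -> List[Cluster]:
    """Connected components of a boolean 3D map, discarding small ones.

    Face (6-neighbour) connectivity by default, so clusters may span
    imaging slices; ``connectivity`` follows the scipy convention (1 =
    faces, 2 = +edges, 3 = +corners).
    """
    t = np.asarray(thresholded, dtype=bool)
    if t.ndim != 3:
        raise ValueError("expected a 3D boolean map")
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(t, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] >= min_size:
            clusters.append(Cluster(indices=idx, size=int(idx.shape[0]), sign=+1))
    return clusters


def distinctiveness(timecourse) -> float:
    """Lag-1 autocorrelation of a time-course.

    A slow oscillation sampled densely has lag-1 autocorrelation near
    cos(2*pi*f*dt) ~ 1, whereas white noise gives ~ 0; this is the
    "non-noise-like" score used to screen cluster-based evidence.
    Returns NaN for a constant time-course.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.size < 8:
        raise ValueError("time-course too short")
    a, b = x[:-1], x[1:]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def classify_components(
    ica: ICADecomposition,
    o2sat: O2SatTrace,
    frame_interval: float,
    mask: np.ndarray,
    p_systemic: float = DEFAULT_P_SYSTEMIC,
    peak_ratio: float = DEFAULT_PEAK_RATIO,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    distinctiveness_threshold: float = DEFAULT_DISTINCTIVENESS,
    connectivity: int = 1,
) -> List[ComponentLabel]:
    """Classify every independent component.

    Decision rule per component: systemic if the O2sat correlation has
    p < ``p_systemic``; otherwise tumour-specific if its time-course has a
    dominant spectral peak, or if its spatial map contains a cluster of at
    least ``min_cluster`` voxels at |z| >= ``z_threshold`` *and* the
    time-course is distinctive; otherwise noise.  All tests are two-sided /
    magnitude-based, so the ICA sign indeterminacy cannot change a label.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != ica.S.shape[1]:
        raise ValueError("mask voxel count does not match the spatial maps")
    labels: List[ComponentLabel] = []
    for i in range(ica.k):
        tc = ica.M[:, i]
        r, p = pearson_vs_o2sat(tc, o2sat, frame_interval)
        peak, freq = has_dominant_peak(tc, frame_interval, peak_ratio)
        map3d = np.zeros(mask.shape)
        map3d[mask] = ica.S[i]
        thr = zscore_threshold_map(ica.S[i], z_threshold)
        thr3d = np.zeros(mask.shape, dtype=bool)
        thr3d[mask] = thr
        clusters = find_clusters(thr3d, min_cluster, connectivity)
        for c in clusters:
            vals = map3d[tuple(c.indices.T)]
            c.sign = +1 if vals.mean() >= 0 else -1
        score = distinctiveness(tc)
        if p < p_systemic:
            label = SYSTEMIC
        elif peak or (clusters and np.isfinite(score) and score >= distinctiveness_threshold):
            label = TUMOUR_SPECIFIC
        else:
            label = NOISE
        labels.append(
            ComponentLabel(
                index=i,
                label=label,
                o2sat_r=float(r) if np.isfinite(r) else float("nan"),
                o2sat_p=float(p),
                has_peak=bool(peak),
                peak_frequency_hz=float(freq),
                clusters=clusters,
                distinctiveness=score,
            )
        )
    return labels


def reconstruct_class(
    ica: ICADecomposition, labels: List[ComponentLabel], which: str
) -> np.ndarray:
    """Class-wise R2* field: the reverse of the ICA decomposition.

    Sums the outer products of the mixing columns and spatial maps of the
    components carrying the requested label; an empty class yields a zero
    field.  The three class fields sum to ``M @ S`` exactly.
    """
    idx = [l.index for l in labels if l.label == which]
    if not idx:
        return np.zeros((ica.M.shape[0], ica.S.shape[1]))
    return ica.M[:, idx] @ ica.S[idx]


def reconstruct_fields(ica: ICADecomposition, labels: List[ComponentLabel]) -> ReconstructedFields:
    """Build the systemic, tumour-specific and noise fields."""
    return ReconstructedFields(
        systemic=reconstruct_class(ica, labels, SYSTEMIC),
        tumour_specific=reconstruct_class(ica, labels, TUMOUR_SPECIFIC),
        noise=reconstruct_class(ica, labels, NOISE),
    )


def pearson_map(field_matrix: np.ndarray, reference: np.ndarray):
    """Vectorised per-voxel Pearson r and two-sided p against a reference.

    Zero-variance voxel time-courses get r = NaN, p = 1 (nothing to
    correlate).
    """
    x = np.asarray(field_matrix, dtype=float)
    y = np.asarray(reference, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt((xc**2).sum(axis=0))
    yn = float(np.sqrt((yc**2).sum()))
    valid = (xn > 0) & (yn > 0)
    r = np.full(x.shape[1], np.nan)
    r[valid] = np.clip((xc[:, valid] * yc[:, None]).sum(axis=0) / (xn[valid] * yn), -1, 1)
    p = np.ones(x.shape[1])
    finite = valid & (np.abs(r) < 1)
    t = r[finite] * np.sqrt((n - 2) / (1.0 - r[finite] ** 2))
    p[finite] = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[valid & (np.abs(r) >= 1)] = 5e-324
    return r, p


def threshold_voxels(
    fields: ReconstructedFields,
    o2sat: O2SatTrace,
    frame_interval: float,
    mask: np.ndarray,
    residual: Optional[np.ndarray] = None,
    p_systemic: float = DEFAULT_P_SYSTEMIC,
    p_tumour: float = DEFAULT_P_TUMOUR,
    amplitude_gate: float = DEFAULT_AMPLITUDE_GATE,
    leak_floor: float = 0.01,
    noise_floor: Optional[float] = None,
) -> ReconstructedFields:
    """Threshold the class fields into voxel-level class maps.

    Systemic map: voxels whose systemic-field time-course correlates with
    the O2sat trace at two-sided p < ``p_systemic``.  Tumour-specific map:
    voxels whose tumour-specific-field time-course is *uncorrelated* with
    the trace (p > ``p_tumour``).  Voxels in the indeterminate band
    [p_systemic, p_tumour] of the tumour-specific field belong to neither
    map; their count is reported.

    Both maps additionally require the class field's temporal s.d. at the
    voxel to be at least ``amplitude_gate`` times the voxel's noise s.d.,
    taken as the larger of the per-voxel residual s.d. (pass ``residual =
    X_centred - M @ S`` from the pipeline) and the optional global
    ``noise_floor`` estimate.  The global floor matters when the
    eigenvector selection has swallowed most of the spectrum (as happens
    on signal-free data, where the knee of a pure noise eigenvalue curve
    sits deep in the bulk): the post-selection residual is then far
    smaller than the true noise, while the ICA maps overfit noise into a
    few spatially extreme voxels.  A relative floor of ``leak_floor``
    times the largest class
    s.d. is always applied as well: the ICA solver tolerance leaves every
    component a trace presence in every voxel, and correlation is blind to
    scale, so voxels carrying only that numerical leakage must not enter a
    class map even when the residual is (near) zero, as in noiseless
    reconstruction checks.

    Returns ``fields`` completed with masks, per-voxel r/p and a report of
    prevalence (% of mask voxels) and mean temporal s.d. per class.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if fields.systemic.shape[1] != n_vox:
        raise ValueError("field width does not match the mask voxel count")
    n_t = fields.systemic.shape[0]
    y = o2sat.resample(_frame_midpoints(n_t, frame_interval))

    sd_sys = fields.systemic.std(axis=0, ddof=1)
    sd_tsp = fields.tumour_specific.std(axis=0, ddof=1)
    floor_sys = leak_floor * sd_sys.max()
    floor_tsp = leak_floor * sd_tsp.max()
    ref = np.zeros(n_vox)
    if residual is not None:
        ref = np.asarray(residual, dtype=float).std(axis=0, ddof=1)
    if noise_floor is not None:
        ref = np.maximum(ref, noise_floor)
    if ref.max() > 0:
        gate_sys = sd_sys >= np.maximum(amplitude_gate * ref, floor_sys)
        gate_tsp = sd_tsp >= np.maximum(amplitude_gate * ref, floor_tsp)
    else:
        gate_sys = sd_sys > floor_sys
        gate_tsp = sd_tsp > floor_tsp

    r_sys, p_sys = pearson_map(fields.systemic, y)
    r_tsp, p_tsp = pearson_map(fields.tumour_specific, y)

    sys_flat = (p_sys < p_systemic) & gate_sys
    tsp_flat = (p_tsp > p_tumour) & gate_tsp
    midband = int(((p_tsp >= p_systemic) & (p_tsp <= p_tumour) & gate_tsp).sum())

    def to3d(flat, dtype=bool):
        out = np.zeros(mask.shape, dtype=dtype)
        out[mask] = flat
        return out

    fields.systemic_mask = to3d(sys_flat)
    fields.tumour_specific_mask = to3d(tsp_flat)
    fields.systemic_r, fields.systemic_p = r_sys, p_sys
    fields.tumour_specific_r, fields.tumour_specific_p = r_tsp, p_tsp
    fields.report = {
        "n_mask_voxels": n_vox,
        "systemic_prevalence_pct": 100.0 * sys_flat.sum() / n_vox,
        "tumour_specific_prevalence_pct": 100.0 * tsp_flat.sum() / n_vox,
        "systemic_mean_sd": float(sd_sys[sys_flat].mean()) if sys_flat.any() else 0.0,
        "tumour_specific_mean_sd": float(sd_tsp[tsp_flat].mean()) if tsp_flat.any() else 0.0,
        "indeterminate_tumour_specific_voxels": midband,
        "p_systemic": p_systemic,
        "p_tumour": p_tumour,
        "amplitude_gate": amplitude_gate,
    }
    return fields
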