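"""End-to-end analysis: PCA -> selection -> spatial ICA -> classification ->
class-wise reconstruction -> voxel thresholding -> spectra.

:func:`analyse` is the in-memory entry point; :func:`run_pipeline` wraps it
with file I/O, artefact writing and a JSON run report in which every
threshold and seed used appears verbatim.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import classify as cls
from . import decompose as dec
from . import io as iio
from .core import O2SatTrace, R2StarSeries, temporal_sd_map
from .spectra import average_spectrum, dominant_frequency

__all__ = ["AnalysisParams", "AnalysisResult", "RunConfig", "analyse", "run_pipeline"]

log = logging.getLogger("icao2sat")


@dataclass
class AnalysisParams:
    """Thresholds and solver settings of the decomposition pipeline."""

    z_threshold: float = cls.DEFAULT_Z_THRESHOLD
    min_cluster: int = cls.DEFAULT_MIN_CLUSTER
    p_systemic: float = cls.DEFAULT_P_SYSTEMIC
    p_tumour: float = cls.DEFAULT_P_TUMOUR
    peak_ratio: float = dec.DEFAULT_PEAK_RATIO
    distinctiveness: float = cls.DEFAULT_DISTINCTIVENESS
    amplitude_gate: float = cls.DEFAULT_AMPLITUDE_GATE
    connectivity: int = 1
    ica_seed: int = 0
    ica_tol: float = 1e-6
    ica_max_iter: int = 1000

    def validate(self) -> None:
        if min(self.z_threshold, self.p_systemic, self.p_tumour, self.peak_ratio) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")


@dataclass
class AnalysisResult:
    """Everything the decomposition produced, plus a summary report."""

    pca: dec.PCADecomposition
    selection: dec.EigenSelection
    ica: dec.ICADecomposition
    labels: List[cls.ComponentLabel]
    fields: cls.ReconstructedFields
    spectra: dict
    report: dict


def analyse(
    series: R2StarSeries, o2sat: O2SatTrace, params: Optional[AnalysisParams] = None
) -> AnalysisResult:
    """Run the full decomposition on an in-memory series and O2sat trace."""
    params = params or AnalysisParams()
    params.validate()
    pca = dec.pca_decompose(series)
    selection = dec.select_eigenvectors(pca, peak_ratio=params.peak_ratio)
    log.info(
        "selected %d of %d eigenvectors (shoulder at %d, %d by frequency peak)",
        len(selection),
        pca.eigenvalues.size,
        selection.shoulder_index,
        selection.peak_set.size,
    )
    x_reduced = dec.reduce(pca, selection)
    ica = dec.run_spatial_ica(
        x_reduced,
        k=len(selection),
        seed=params.ica_seed,
        tol=params.ica_tol,
        max_iter=params.ica_max_iter,
    )
    labels = cls.classify_components(
        ica,
        o2sat,
        series.frame_interval,
        series.mask,
        p_systemic=params.p_systemic,
        peak_ratio=params.peak_ratio,
        z_threshold=params.z_threshold,
        min_cluster=params.min_cluster,
        distinctiveness_threshold=params.distinctiveness,
        connectivity=params.connectivity,
    )
    fields = cls.reconstruct_fields(ica, labels)
    x = series.masked_matrix()
    residual = (x - x.mean(axis=0)) - ica.M @ ica.S
    fields = cls.threshold_voxels(
        fields,
        o2sat,
        series.frame_interval,
        series.mask,
        residual=residual,
        p_systemic=params.p_systemic,
        p_tumour=params.p_tumour,
        amplitude_gate=params.amplitude_gate,
        noise_floor=dec.estimate_noise_sd(pca),
    )
    spectra = {}
    for name, matrix, mask3d in (
        ("systemic", fields.systemic, fields.systemic_mask),
        ("tumour_specific", fields.tumour_specific, fields.tumour_specific_mask),
    ):
        flat = mask3d[series.mask]
        if flat.any():
            spec = average_spectrum(
                matrix,
                series.frame_interval,
                voxels=flat,
                provenance={"class": name},
            )
            spectra[name] = spec

    counts = {
        lab: sum(1 for l in labels if l.label == lab)
        for lab in (cls.SYSTEMIC, cls.TUMOUR_SPECIFIC, cls.NOISE)
    }
    report = {
        "n_frames": series.n_frames,
        "frame_interval_s": series.frame_interval,
        "n_mask_voxels": series.n_voxels,
        "n_eigenvectors": int(pca.eigenvalues.size),
        "n_selected_eigenvectors": len(selection),
        "shoulder_index": int(selection.shoulder_index),
        "component_counts": counts,
        "ica_iterations": ica.n_iter,
        "dominant_frequency_hz": {
            name: dominant_frequency(spec) for name, spec in spectra.items()
        },
        "thresholds": dataclasses.asdict(params),
        **fields.report,
    }
    return AnalysisResult(
        pca=pca,
        selection=selection,
        ica=ica,
        labels=labels,
        fields=fields,
        spectra=spectra,
        report=report,
    )


@dataclass
class RunConfig:
    """File-based pipeline configuration.

    Threshold defaults match the analysis defaults (|z| >= 2.2, clusters of
    >= 5 voxels, component/voxel p thresholds 0.01 and 0.05).
    """

    series_path: str
    mask_path: str
    o2sat_path: str
    output_dir: str
    frame_interval: Optional[float] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_json(cls_, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        params = AnalysisParams(**raw.pop("params", {}))
        return cls_(params=params, **raw)

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)


def _write_artifacts(result: AnalysisResult, series: R2StarSeries, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    iio.save_mask(result.fields.systemic_mask, outdir / "systemic_mask.nii.gz")
    iio.save_mask(
        result.fields.tumour_specific_mask, outdir / "tumour_specific_mask.nii.gz"
    )
    sd_all = temporal_sd_map(series)
    iio.save_map(np.nan_to_num(sd_all.values), outdir / "sd_map.nii.gz")
    for name, matrix in (
        ("systemic", result.fields.systemic),
        ("tumour_specific", result.fields.tumour_specific),
    ):
        sd = matrix.std(axis=0, ddof=1)
        iio.save_map(series.scatter(sd), outdir / f"sd_map_{name}.nii.gz")
    pd.DataFrame(
        {f"component_{l.index + 1}": result.ica.M[:, l.index] for l in result.labels}
    ).assign(frame=np.arange(series.n_frames)).to_csv(
        outdir / "component_timecourses.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "component": l.index,
                "label": l.label,
                "o2sat_r": l.o2sat_r,
                "o2sat_p": l.o2sat_p,
                "has_peak": l.has_peak,
                "peak_frequency_hz": l.peak_frequency_hz,
                "n_clusters": len(l.clusters),
                "cluster_sizes": ";".join(map(str, l.cluster_sizes)),
                "distinctiveness": l.distinctiveness,
            }
            for l in result.labels
        ]
    ).to_csv(outdir / "component_labels.csv", index=False)
    for name, spec in result.spectra.items():
        pd.DataFrame(
            {"frequency_hz": spec.frequencies, "power": spec.power}
        ).to_csv(outdir / f"spectrum_{name}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=float)


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run :func:`analyse` and write all artefacts.

    Returns the run report (also written as ``report.json``).  Stage
    failures propagate as exceptions tagged with the failing stage.
    """
    stage = "load"
    try:
        series = iio.load_series(
            config.series_path, config.mask_path, config.frame_interval
        )
        o2sat = iio.load_o2sat(config.o2sat_path)
        stage = "analyse"
        result = analyse(series, o2sat, config.params)
        stage = "write"
        _write_artifacts(result, series, Path(config.output_dir))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return result.report
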