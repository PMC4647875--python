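"""File I/O: NIfTI volumes, O2sat traces and tabular exports."""

from __future__ import annotations

import logging
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import O2SatTrace, R2StarSeries

__all__ = [
    "load_series",
    "save_series",
    "load_mask",
    "save_mask",
    "save_map",
    "load_o2sat",
    "save_o2sat",
]

log = logging.getLogger("icao2sat")

# NIfTI stores volumes (x, y, z[, t]); internally we use (t, z, y, x).


def _to_nifti_order(values: np.ndarray) -> np.ndarray:
    return np.transpose(values, (3, 2, 1, 0)) if values.ndim == 4 else values.T


def _from_nifti_order(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (3, 2, 1, 0)) if data.ndim == 4 else data.T


def save_series(series: R2StarSeries, path, mask_path=None) -> None:
    """Write a series as 4D NIfTI-1 (float32), frame interval in the header."""
    img = nib.Nifti1Image(
        _to_nifti_order(series.values).astype(np.float32), affine=np.eye(4)
    )
    zooms = list(img.header.get_zooms())
    zooms[3] = series.frame_interval
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    if mask_path is not None:
        save_mask(series.mask, mask_path)


def save_mask(mask: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask).T.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return _from_nifti_order(np.asarray(nib.load(str(path)).dataobj)) > 0


def save_map(values: np.ndarray, path) -> None:
    """Write a 3D scalar map as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32).T, affine=np.eye(4))
    nib.save(img, str(path))


def load_series(path, mask_path, frame_interval: Optional[float] = None) -> R2StarSeries:
    """Load a 4D R2* series and its tumour mask.

    The frame interval is taken from the NIfTI time-axis zoom unless a
    configured value is given, which wins (and is logged).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("series must be a 4D volume")
    values = _from_nifti_order(data)
    mask = load_mask(mask_path)
    if mask.shape != values.shape[1:]:
        raise ValueError("mask shape does not match the series grid")
    header_dt = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if frame_interval is not None:
        if header_dt and not np.isclose(header_dt, frame_interval):
            log.info(
                "frame interval override: header %.4g s, using configured %.4g s",
                header_dt,
                frame_interval,
            )
        dt = frame_interval
    elif header_dt > 0:
        dt = header_dt
    else:
        raise ValueError("no frame interval in header; pass frame_interval")
    return R2StarSeries(values=values, frame_interval=dt, mask=mask)


def save_o2sat(trace: O2SatTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "o2sat_pct": trace.values}).to_csv(
        path, index=False
    )


def load_o2sat(path) -> O2SatTrace:
    """Read a two-column delimited O2sat trace (time_s, o2sat_pct).

    A header row is optional; validation (monotone times, percent range) is
    delegated to :class:`O2SatTrace`.
    """
    df = pd.read_csv(path)
    if {"time_s", "o2sat_pct"}.issubset(df.columns):
        times, values = df["time_s"], df["o2sat_pct"]
    else:
        df = pd.read_csv(path, header=None)
        if df.shape[1] < 2:
            raise ValueError("expected two columns: time_s, o2sat_pct")
        times, values = df.iloc[:, 0], df.iloc[:, 1]
    return O2SatTrace(times=np.asarray(times, float), values=np.asarray(values, float))
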