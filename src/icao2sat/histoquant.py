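"""Quantification of fluorescence histology sections.

Pixel-wise coverage metrics on 2D sections: the fraction of an ROI above a
fluorescence threshold for each marker (CD31 endothelium, alpha-SMA
pericytes, Hoechst perfusion, pimonidazole hypoxia), and the percentage of
endothelial pixels colocalised with pericyte staining as a vessel-maturity
proxy.  Analysis is strictly pixel-based; no vessel segmentation is
attempted.

Background thresholds must be supplied explicitly; Otsu's method is
offered as a convenience default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np

__all__ = [
    "SectionImage",
    "coverage_fraction",
    "pericyte_vessel_coverage",
    "otsu_threshold",
    "read_image",
    "quantify_section",
]


@dataclass
class SectionImage:
    """A multi-channel 2D section with a tumour ROI."""

    channels: Dict[str, np.ndarray]
    roi: np.ndarray

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=bool)
        if not self.roi.any():
            raise ValueError("ROI is empty")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.roi.shape:
                raise ValueError(f"channel {name!r} shape differs from ROI")
            if (ch < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = ch


def coverage_fraction(channel: np.ndarray, roi: np.ndarray, threshold: float) -> float:
    """Fraction of ROI pixels whose intensity exceeds the threshold."""
    roi = np.asarray(roi, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    if channel.shape != roi.shape:
        raise ValueError("channel and ROI shapes differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return float((channel[roi] > threshold).mean())


def pericyte_vessel_coverage(cd31_mask, sma_mask, roi) -> float:
    """Percentage of CD31-positive pixels also positive for alpha-SMA.

    Mature vessels are wrapped by pericytes; a higher percentage means a
    more mature vascular bed.  NaN (with a warning) if the ROI contains no
    CD31-positive pixels.
    """
    roi = np.asarray(roi, dtype=bool)
    cd31 = np.asarray(cd31_mask, dtype=bool) & roi
    sma = np.asarray(sma_mask, dtype=bool) & roi
    n_cd31 = int(cd31.sum())
    if n_cd31 == 0:
        warnings.warn("no CD31-positive pixels in ROI: coverage undefined")
        return float("nan")
    return 100.0 * float((cd31 & sma).sum()) / n_cd31


def otsu_threshold(channel: np.ndarray, roi=None) -> float:
    """Otsu background threshold of a channel (optionally within the ROI)."""
    from skimage.filters import threshold_otsu

    channel = np.asarray(channel, dtype=float)
    values = channel[np.asarray(roi, dtype=bool)] if roi is not None else channel.ravel()
    return float(threshold_otsu(values))


def read_image(path) -> np.ndarray:
    """Read a 2D image (TIFF/PNG) as a float array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to intensity
        img = img[..., :3].mean(axis=-1)
    return img


def quantify_section(
    section: SectionImage, thresholds: Dict[str, float] | None = None
) -> Dict[str, float]:
    """Coverage fraction per channel (and pericyte coverage when CD31 and
    alpha-SMA channels are both present).

    Channels missing from ``thresholds`` fall back to Otsu within the ROI;
    every threshold used is reported alongside the metrics.
    """
    thresholds = dict(thresholds or {})
    out: Dict[str, float] = {}
    for name, ch in section.channels.items():
        thr = thresholds.get(name)
        if thr is None:
            thr = otsu_threshold(ch, section.roi)
            warnings.warn(f"channel {name!r}: falling back to Otsu threshold {thr:.4g}")
        thresholds[name] = thr
        out[f"{name}_coverage"] = coverage_fraction(ch, section.roi, thr)
        out[f"{name}_threshold"] = float(thr)
    if "CD31" in section.channels and "aSMA" in section.channels:
        cd31 = section.channels["CD31"] > thresholds["CD31"]
        sma = section.channels["aSMA"] > thresholds["aSMA"]
        out["pericyte_vessel_coverage_pct"] = pericyte_vessel_coverage(
            cd31, sma, section.roi
        )
    return out
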