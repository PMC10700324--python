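"""ROI time-series preparation: volume discard, ROI means, band-pass.

Takes already-preprocessed 4-D fMRI volumes (motion-corrected,
normalized, smoothed upstream — this module deliberately performs none
of those steps) or raw per-region series, and produces the analysis
matrix: the first volumes are discarded to let magnetization reach
equilibrium, each atlas region's mean intensity series is extracted,
and every series is band-pass filtered to the low-frequency BOLD band
(default 0.01–0.08 Hz).

The band-pass is a zero-phase forward–backward Butterworth (order 4,
effective order 8 after the double pass) with odd-reflection edge
padding — short series (~130 points) make transient suppression at the
edges matter. Atlas label integers are 1-based region indices matching
the region table; mismatched volume/label grids are an error, never
silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .regions import RegionTable

__all__ = [
    "BandpassSpec",
    "discard_initial_volumes",
    "extract_roi_means",
    "bandpass_filter",
    "prepare_series",
    "MissingRegionError",
]

DEFAULT_N_DISCARD = 10


class MissingRegionError(ValueError):
    """A region of the table has no voxels in the label volume."""


@dataclass(frozen=True)
class BandpassSpec:
    """Band-pass filter specification for ROI series."""

    low_hz: float = 0.01
    high_hz: float = 0.08
    tr_seconds: float = 3.0
    order: int = 4

    def __post_init__(self):
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:.4g} Hz at TR {self.tr_seconds} s)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def discard_initial_volumes(volumes: np.ndarray, n_discard: int = DEFAULT_N_DISCARD) -> np.ndarray:
    """Drop the first ``n_discard`` time points of a 4-D (x, y, z, t) series."""
    volumes = np.asarray(volumes)
    if volumes.ndim != 4:
        raise ValueError(f"expected a 4-D volume series, got ndim={volumes.ndim}")
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if volumes.shape[-1] <= n_discard:
        raise ValueError(
            f"series has {volumes.shape[-1]} volumes, cannot discard {n_discard}"
        )
    return volumes[..., n_discard:]


def extract_roi_means(volumes: np.ndarray, labels: np.ndarray, table: RegionTable) -> np.ndarray:
    """Mean intensity series per atlas region.

    Row ``r-1`` of the output is the arithmetic mean, at each time
    point, over all voxels labeled ``r``; label 0 (background) is
    ignored. Every region in ``table`` must be present in ``labels``.
    """
    volumes = np.asarray(volumes, dtype=float)
    labels = np.asarray(labels)
    if volumes.ndim != 4:
        raise ValueError("volumes must be 4-D (x, y, z, t)")
    if labels.shape != volumes.shape[:3]:
        raise ValueError(
            f"label grid {labels.shape} does not match volume grid {volumes.shape[:3]}"
        )
    n_t = volumes.shape[-1]
    out = np.empty((len(table), n_t), dtype=float)
    flat_vol = volumes.reshape(-1, n_t)
    flat_lab = labels.reshape(-1)
    for region in table:
        mask = flat_lab == region.index
        if not mask.any():
            raise MissingRegionError(
                f"region {region.index} ({region.abbreviation}) has no voxels in the label volume"
            )
        out[region.index - 1] = flat_vol[mask].mean(axis=0)
    return out


def bandpass_filter(series: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase Butterworth band-pass of each row of ``series``.

    Forward–backward second-order-section filtering (no temporal shift);
    odd-reflection edge padding. Output dims equal input dims.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_t = series.shape[-1]
    padlen = 3 * spec.order
    if n_t < 3 * spec.order:
        raise ValueError(
            f"series length {n_t} too short for order-{spec.order} filtering"
        )
    sos = sp_signal.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=1.0 / spec.tr_seconds,
        output="sos",
    )
    return sp_signal.sosfiltfilt(sos, series, axis=-1, padtype="odd",
                                 padlen=min(padlen * 2, n_t - 1))


def prepare_series(
    volumes: np.ndarray,
    labels: np.ndarray,
    table: RegionTable,
    spec: BandpassSpec | None = None,
    n_discard: int = DEFAULT_N_DISCARD,
) -> np.ndarray:
    """Full prep: discard initial volumes, ROI means, band-pass.

    A default 140-volume input yields a 116 × 130 matrix.
    """
    spec = spec or BandpassSpec()
    trimmed = discard_initial_volumes(volumes, n_discard)
    roi = extract_roi_means(trimmed, labels, table)
    return bandpass_filter(roi, spec)
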