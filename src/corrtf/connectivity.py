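"""Directed spectral-ratio connectivity (CorrTF) and the Pearson arm.

The correlation transfer function (CorrTF) treats a pair of ROI mean
time series as input and output of a linear system and summarizes the
magnitude of the empirical transfer function between them.  For series
``x`` (output role) and ``y`` (input role), the per-frequency feature is

    ratio(f) = |DFT(x)(f)| / |DFT(y)(f)|

evaluated on the one-sided discrete Fourier transform, and the scalar
connection value is the mean of these ratios over the analysis band
(default 0.01–0.08 Hz).  The feature is directed — swapping the two
series inverts every per-bin ratio — and the convention here is that
the *denominator* series is the input, so the matrix entry ``(i, j)``
holds the connection directed from region ``j`` to region ``i``.

Near-zero denominator bins are excluded from the band mean (rather than
clipped) using a relative threshold, to avoid inflating ratios where
the input series has essentially no power.

The comparison arm is conventional undirected functional connectivity:
Pearson correlation of region pairs, variance-stabilized with Fisher's
z-transform (inverse hyperbolic tangent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BAND",
    "DEFAULT_EPS_REL",
    "CorrTFSpectrum",
    "ConnectivityMatrix",
    "corrtf_spectrum",
    "corrtf_value",
    "corrtf_matrix",
    "pearson_matrix",
    "fisher_z",
    "DegenerateConnectionError",
    "DegenerateRegionError",
]

#: Analysis band (Hz) shared with the band-pass stage.
DEFAULT_BAND: tuple[float, float] = (0.01, 0.08)

#: Relative denominator threshold: in-band bins where |DFT(y)| falls below
#: eps_rel × max in-band |DFT(y)| are excluded from the band mean.
DEFAULT_EPS_REL: float = 1e-12

_AGGREGATIONS = ("mean", "median", "max")


class DegenerateConnectionError(ValueError):
    """All in-band bins of a connection's denominator are below threshold."""


class DegenerateRegionError(ValueError):
    """A region's series has zero variance (Pearson undefined)."""


@dataclass(frozen=True)
class CorrTFSpectrum:
    """Per-bin transfer-function magnitudes between two series.

    ``valid`` marks bins whose denominator magnitude exceeds the
    regularization floor; ratios at invalid bins are computed against
    the floor and should not enter band aggregates.
    """

    frequencies: np.ndarray
    ratios: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if not (len(self.frequencies) == len(self.ratios) == len(self.valid)):
            raise ValueError("frequencies, ratios and valid must align")


@dataclass
class ConnectivityMatrix:
    """R×R connection matrix; the diagonal is masked (NaN).

    ``kind`` is one of ``corrtf`` (directed, non-negative; entry (i, j)
    is the connection j → i), ``pearson`` (symmetric, in [−1, 1]) or
    ``fisher_z`` (symmetric, finite).
    """

    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if self.kind not in ("corrtf", "pearson", "fisher_z"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """All defined (off-diagonal) entries, row-major."""
        mask = ~np.eye(self.n_regions, dtype=bool)
        return self.values[mask]

    def to_tsv(self, path: str | Path, labels: list[str] | None = None) -> None:
        labels = labels or [f"R{i}" for i in range(1, self.n_regions + 1)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(
            path, sep="\t", float_format="%.10g")

    def to_edge_csv(self, path: str | Path, labels: list[str] | None = None) -> None:
        """Long-format edge list (source, target, value).

        For the directed ``corrtf`` kind the source is the denominator
        (input) region — the column index; for symmetric kinds each
        unordered pair appears once with source < target.
        """
        labels = labels or [f"R{i}" for i in range(1, self.n_regions + 1)]
        rows = []
        n = self.n_regions
        if self.kind == "corrtf":
            for i in range(n):
                for j in range(n):
                    if i != j:
                        rows.append((labels[j], labels[i], self.values[i, j]))
        else:
            for i in range(n):
                for j in range(i + 1, n):
                    rows.append((labels[i], labels[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["source", "target", "value"]).to_csv(
            path, index=False, float_format="%.10g")


def _onesided_magnitudes(x: np.ndarray) -> np.ndarray:
    return np.abs(np.fft.rfft(np.asarray(x, dtype=float)))


def corrtf_spectrum(x: np.ndarray, y: np.ndarray, tr_seconds: float = 3.0,
                    eps_rel: float = DEFAULT_EPS_REL) -> CorrTFSpectrum:
    """Per-bin magnitude ratio |DFT(x)| / |DFT(y)| on one-sided bins.

    ``x`` plays the output role and ``y`` the input (denominator) role.
    Bins where |DFT(y)| ≤ eps_rel × max |DFT(y)| are flagged invalid and
    their ratios computed against that floor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    ax = _onesided_magnitudes(x)
    ay = _onesided_magnitudes(y)
    floor = eps_rel * ay.max() if ay.max() > 0 else np.finfo(float).tiny
    valid = ay > floor
    ratios = ax / np.maximum(ay, floor)
    freqs = np.fft.rfftfreq(len(x), d=tr_seconds)
    return CorrTFSpectrum(frequencies=freqs, ratios=ratios, valid=valid)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    if not (0.0 < low < high):
        raise ValueError(f"band {band} must satisfy 0 < low < high")
    return (freqs >= low) & (freqs <= high) & (freqs > 0.0)


def corrtf_value(x: np.ndarray, y: np.ndarray, band: tuple[float, float] = DEFAULT_BAND,
                 tr_seconds: float = 3.0, eps_rel: float = DEFAULT_EPS_REL,
                 aggregation: str = "mean") -> float:
    """Scalar CorrTF of the connection directed from ``y`` to ``x``.

    Aggregates the per-bin ratios over bins with ``low ≤ f ≤ high``
    (DC always excluded), skipping bins whose denominator falls below
    the relative threshold.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < band[0] < band[1] < nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:.4g})")
    spec = corrtf_spectrum(x, y, tr_seconds=tr_seconds, eps_rel=eps_rel)
    in_band = _band_mask(spec.frequencies, band)
    if not in_band.any():
        raise DegenerateConnectionError(
            f"no DFT bins fall inside band {band} for series of length {len(x)}"
        )
    use = in_band & spec.valid
    if not use.any():
        raise DegenerateConnectionError(
            "all in-band denominator bins below regularization threshold"
        )
    vals = spec.ratios[use]
    if aggregation == "mean":
        return float(vals.mean())
    if aggregation == "median":
        return float(np.median(vals))
    return float(vals.max())


def corrtf_matrix(series: np.ndarray, band: tuple[float, float] = DEFAULT_BAND,
                  tr_seconds: float = 3.0, eps_rel: float = DEFAULT_EPS_REL,
                  aggregation: str = "mean") -> ConnectivityMatrix:
    """Directed CorrTF matrix of a regions × time matrix.

    Entry ``(i, j)``, i ≠ j, equals
    ``corrtf_value(series[i], series[j], ...)`` — the connection
    directed from region j (input) to region i (output).  The diagonal
    is NaN.  Vectorized over all pairs: one FFT per region, then band
    aggregation of the ratio tensor.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D regions × time matrix")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
    n_regions, n_t = series.shape
    mags = np.abs(np.fft.rfft(series, axis=1))  # (R, nbins)
    freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < band[0] < band[1] < nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:.4g})")
    in_band = _band_mask(freqs, band)
    if not in_band.any():
        raise DegenerateConnectionError(
            f"no DFT bins fall inside band {band} for series of length {n_t}"
        )
    bmags = mags[:, in_band]  # (R, B)
    maxes = bmags.max(axis=1)
    floors = np.where(maxes > 0, eps_rel * maxes, np.finfo(float).tiny)
    valid = bmags > floors[:, None]  # validity of region as denominator
    counts = valid.sum(axis=1)
    if (counts == 0).any():
        bad = int(np.flatnonzero(counts == 0)[0])
        raise DegenerateConnectionError(
            f"region {bad + 1} has no usable in-band bins as denominator "
            f"(all below threshold); connections (*, {bad + 1}) degenerate"
        )
    if aggregation == "mean":
        # values[i, j] = (1/|V_j|) Σ_{k∈V_j} bmags[i,k] / bmags[j,k]
        weights = np.where(valid, 1.0 / np.where(valid, bmags, 1.0), 0.0)  # (R, B)
        values = (bmags @ weights.T) / counts[None, :]
    else:
        values = np.empty((n_regions, n_regions), dtype=float)
        for j in range(n_regions):
            ratios = bmags[:, valid[j]] / bmags[j, valid[j]][None, :]
            values[:, j] = np.median(ratios, axis=1) if aggregation == "median" \
                else ratios.max(axis=1)
    np.fill_diagonal(values, np.nan)
    return ConnectivityMatrix(values=values, kind="corrtf")


def pearson_matrix(series: np.ndarray) -> ConnectivityMatrix:
    """Symmetric Pearson correlation matrix of region pairs (diagonal NaN)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D regions × time matrix")
    sd = series.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateRegionError(f"region {bad + 1} has zero variance")
    values = np.corrcoef(series)
    values = 0.5 * (values + values.T)  # exact symmetry (corrcoef is ulp-asymmetric)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, np.nan)
    return ConnectivityMatrix(values=values, kind="pearson")


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform (atanh) of a Pearson matrix, entrywise."""
    if matrix.kind != "pearson":
        raise ValueError("fisher_z expects a pearson-kind matrix")
    r = matrix.values
    off = ~np.eye(matrix.n_regions, dtype=bool)
    at_unit = off & (np.abs(r) >= 1.0)
    if at_unit.any():
        i, j = map(int, np.argwhere(at_unit)[0])
        raise ValueError(
            f"|r| = 1 for region pair ({i + 1}, {j + 1}); Fisher z undefined"
        )
    z = np.full_like(r, np.nan)
    z[off] = np.arctanh(r[off])
    return ConnectivityMatrix(values=z, kind="fisher_z")
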