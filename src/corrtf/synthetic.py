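"""Synthetic longitudinal rs-fMRI cohort generator.

Real multi-visit rs-fMRI cohorts of the kind this pipeline analyzes are
access-restricted, so this module generates ROI time-series cohorts with
the statistical structure the analysis assumes:

* band-limited signal content — each region's latent series is a sum of
  ``n_oscillators`` sinusoids with frequencies drawn uniformly inside the
  BOLD band (default 0.01–0.08 Hz), unit-normalized, so essentially all
  spectral power lies in-band;
* within-subject stability — a subject's latent oscillators (frequencies,
  phases) are drawn once and reused at every visit, while white
  measurement noise is redrawn per visit.  With no injected effects the
  visits are therefore exchangeable, which is the basis of the type-I
  error checks downstream;
* injectable directed longitudinal effects — an :class:`EffectSpec` adds
  the source region's *latent* (noise-free) signal into the target
  region with a per-visit gain, so the expected directed connectivity of
  that pair changes across visits in a controlled way.

The default cohort dimensions reproduce the study design this pipeline
targets: four groups (NC 29, EMCI 23, LMCI 24, AD 23 subjects), three
visits, 116 regions × 130 time points at TR = 3 s.

No hemodynamic response, head motion, or physiological noise is
simulated; the generator provides exactly the features the band-limited
spectral analysis consumes (see the methods note for what that implies
about real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "EffectSpec",
    "CohortConfig",
    "SubjectVisitSeries",
    "generate_cohort",
    "generate_labeled_volume_fixture",
    "write_cohort",
    "read_cohort",
    "CohortConfigError",
]

#: Study-group sample sizes of the targeted longitudinal design.
DEFAULT_GROUP_SIZES: dict[str, int] = {"NC": 29, "EMCI": 23, "LMCI": 24, "AD": 23}


class CohortConfigError(ValueError):
    """Raised for invalid cohort configurations or effect specs."""


@dataclass(frozen=True)
class EffectSpec:
    """A planted directed longitudinal connectivity effect.

    The target region receives the source region's latent signal scaled
    by ``visit_gains[v]`` at visit ``v``; a gain sequence that changes
    across visits plants a longitudinal effect on the directed
    connection source → target in that group.
    """

    group: str
    source_region: int  # 1-based region index
    target_region: int
    visit_gains: tuple[float, ...]

    def __post_init__(self):
        if self.source_region == self.target_region:
            raise CohortConfigError("effect source and target regions must differ")


@dataclass
class CohortConfig:
    """Full description of a synthetic longitudinal cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_visits: int = 3
    n_regions: int = 116
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    signal_band: tuple[float, float] = (0.01, 0.08)
    noise_sd: float = 1.0
    n_oscillators: int = 5
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.signal_band
        if not (self.n_visits > 0 and self.n_regions > 0 and self.n_timepoints > 0):
            raise CohortConfigError("counts must be positive")
        if any(n <= 0 for n in self.group_sizes.values()) or not self.group_sizes:
            raise CohortConfigError("group sizes must be positive")
        if not (0 < low < high < nyquist):
            raise CohortConfigError(
                f"signal band {self.signal_band} must satisfy 0 < low < high < "
                f"Nyquist ({nyquist:.4g} Hz at TR {self.tr_seconds} s)"
            )
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be non-negative")
        for eff in self.effects:
            if eff.group not in self.group_sizes:
                raise CohortConfigError(f"effect references unknown group {eff.group!r}")
            for r in (eff.source_region, eff.target_region):
                if not (1 <= r <= self.n_regions):
                    raise CohortConfigError(
                        f"effect region {r} out of range 1..{self.n_regions}"
                    )
            if len(eff.visit_gains) != self.n_visits:
                raise CohortConfigError(
                    f"effect visit_gains length {len(eff.visit_gains)} != "
                    f"n_visits {self.n_visits}"
                )


@dataclass
class SubjectVisitSeries:
    """One subject-visit ROI time-series matrix (regions × time)."""

    subject_id: str
    group: str
    visit: int  # 0 = baseline, 1 = visit1, 2 = visit2
    series: np.ndarray  # shape (n_regions, n_timepoints)
    tr_seconds: float

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D regions × time matrix")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")


def _latent_signals(rng: np.random.Generator, n_regions: int, n_timepoints: int,
                    tr: float, band: tuple[float, float], k: int) -> np.ndarray:
    """Unit-SD band-limited latent series, one row per region."""
    t = np.arange(n_timepoints) * tr
    # frequencies are drawn uniformly among the DFT-bin frequencies inside
    # the band: exact-bin sinusoids have no spectral leakage, so the latent
    # signal is band-limited by construction (all power strictly in-band)
    bin_freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    candidates = bin_freqs[(bin_freqs >= band[0]) & (bin_freqs <= band[1])]
    if len(candidates) == 0:
        raise ValueError(
            f"no DFT bins inside band {band} for {n_timepoints} points at TR {tr} s"
        )
    replace = len(candidates) < k
    freqs = np.stack([rng.choice(candidates, size=k, replace=replace)
                      for _ in range(n_regions)])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_regions, k))
    # (R, K, T) -> sum over K
    latent = np.sin(2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None])
    latent = latent.sum(axis=1)
    sd = latent.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # degenerate draw; keep series finite
    return latent / sd


def generate_cohort(config: CohortConfig) -> list[SubjectVisitSeries]:
    """Generate one :class:`SubjectVisitSeries` per subject per visit.

    The output order is deterministic (groups in ``group_sizes`` order,
    subjects then visits in index order) and bit-reproducible for a
    fixed ``config.seed``.
    """
    config.validate()
    n_subjects = sum(config.group_sizes.values())
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(n_subjects)

    # effects indexed by group for quick lookup
    effects_by_group: dict[str, list[EffectSpec]] = {}
    for eff in config.effects:
        effects_by_group.setdefault(eff.group, []).append(eff)

    out: list[SubjectVisitSeries] = []
    subj_counter = 0
    for group, size in config.group_sizes.items():
        group_effects = effects_by_group.get(group, [])
        for s in range(size):
            rng = np.random.default_rng(subject_seeds[subj_counter])
            subj_counter += 1
            latent = _latent_signals(
                rng, config.n_regions, config.n_timepoints,
                config.tr_seconds, config.signal_band, config.n_oscillators,
            )
            subject_id = f"{group}{s + 1:03d}"
            for visit in range(config.n_visits):
                signal = latent.copy()
                for eff in group_effects:
                    gain = eff.visit_gains[visit]
                    signal[eff.target_region - 1] += gain * latent[eff.source_region - 1]
                noise = rng.normal(0.0, config.noise_sd,
                                   size=(config.n_regions, config.n_timepoints))
                out.append(SubjectVisitSeries(
                    subject_id=subject_id, group=group, visit=visit,
                    series=signal + noise, tr_seconds=config.tr_seconds,
                ))
    return out


# ---------------------------------------------------------------------------
# labeled 4-D volume fixtures (for testing real-data ingestion)
# ---------------------------------------------------------------------------

def _block_grid(n_regions: int, shape: tuple[int, int, int]) -> list[tuple[slice, slice, slice]]:
    """Disjoint voxel cuboids, one per region, tiling part of ``shape``."""
    # choose per-axis division counts whose product covers n_regions
    divs = [1, 1, 1]
    while divs[0] * divs[1] * divs[2] < n_regions:
        # grow the axis with the most voxels per current division
        ratios = [shape[i] / divs[i] for i in range(3)]
        axis = int(np.argmax(ratios))
        if divs[axis] + 1 > shape[axis]:
            candidates = [i for i in range(3) if divs[i] < shape[i]]
            if not candidates:
                raise ValueError(
                    f"cannot host {n_regions} regions in shape {shape}"
                )
            axis = max(candidates, key=lambda i: shape[i] / divs[i])
        divs[axis] += 1

    def bounds(extent: int, n: int) -> list[tuple[int, int]]:
        edges = np.linspace(0, extent, n + 1).astype(int)
        return [(edges[i], edges[i + 1]) for i in range(n)]

    cells = []
    for x0, x1 in bounds(shape[0], divs[0]):
        for y0, y1 in bounds(shape[1], divs[1]):
            for z0, z1 in bounds(shape[2], divs[2]):
                if x1 > x0 and y1 > y0 and z1 > z0:
                    cells.append((slice(x0, x1), slice(y0, y1), slice(z0, z1)))
    if len(cells) < n_regions:
        raise ValueError(f"cannot host {n_regions} regions in shape {shape}")
    return cells[:n_regions]


def generate_labeled_volume_fixture(
    n_regions: int,
    shape: tuple[int, int, int],
    n_volumes: int,
    seed: int,
    voxel_noise_sd: float = 0.0,
    tr_seconds: float = 3.0,
    signal_band: tuple[float, float] = (0.01, 0.08),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a tiny labeled 4-D volume with known per-region mean series.

    Returns ``(volumes, labels, truth)`` where ``volumes`` has shape
    ``shape + (n_volumes,)``, ``labels`` is an integer volume with values
    ``1..n_regions`` on disjoint voxel blocks (0 = background), and
    ``truth`` is the ``n_regions × n_volumes`` ground-truth series each
    region's voxels carry (before optional voxel noise).
    """
    rng = np.random.default_rng(seed)
    truth = _latent_signals(rng, n_regions, n_volumes, tr_seconds, signal_band, 5)
    labels = np.zeros(shape, dtype=np.int16)
    volumes = np.zeros(shape + (n_volumes,), dtype=float)
    for r, cell in enumerate(_block_grid(n_regions, shape), start=1):
        labels[cell] = r
        volumes[cell] = truth[r - 1]
    if voxel_noise_sd > 0:
        volumes += rng.normal(0.0, voxel_noise_sd, size=volumes.shape)
        volumes[labels == 0] = 0.0
    return volumes, labels, truth


# ---------------------------------------------------------------------------
# cohort TSV round trip
# ---------------------------------------------------------------------------

def _series_columns(n_regions: int, abbreviations: Sequence[str] | None) -> list[str]:
    if abbreviations is not None:
        if len(abbreviations) != n_regions:
            raise ValueError("abbreviation count does not match region count")
        return list(abbreviations)
    return [f"R{i}" for i in range(1, n_regions + 1)]


def write_cohort(cohort: Sequence[SubjectVisitSeries], out_dir: str | Path,
                 abbreviations: Sequence[str] | None = None) -> Path:
    """Write one TSV per subject-visit (time rows × region columns) plus a
    manifest TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for sv in cohort:
        cols = _series_columns(sv.series.shape[0], abbreviations)
        fname = f"{sv.subject_id}_visit{sv.visit}.tsv"
        pd.DataFrame(sv.series.T, columns=cols).to_csv(
            out_dir / fname, sep="\t", index=False, float_format="%.10g")
        records.append({"subject": sv.subject_id, "group": sv.group,
                        "visit": sv.visit, "file": fname, "tr": sv.tr_seconds})
    manifest = out_dir / "cohort_manifest.tsv"
    pd.DataFrame.from_records(records).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectVisitSeries]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject", "group", "visit", "file", "tr"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"cohort manifest missing columns {sorted(missing)}")
    cohort = []
    for row in manifest.itertuples(index=False):
        series = pd.read_csv(base / row.file, sep="\t").to_numpy().T
        cohort.append(SubjectVisitSeries(
            subject_id=str(row.subject), group=str(row.group),
            visit=int(row.visit), series=series, tr_seconds=float(row.tr),
        ))
    return cohort
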