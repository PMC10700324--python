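"""Two-stage longitudinal significance screening of connections.

For each disease group and each connection, the connection value is
collected across subjects at each of the three visits.  A connection is
declared significant when all three of the following reject at level
``alpha`` (default 0.05, uncorrected — the screening is deliberately
per-connection):

1. paired t-test between baseline and visit 1,
2. paired t-test between visit 1 and visit 2,
3. one-way ANOVA over the three visits.

Before testing, connection values are normalized to unit sum of
squares.  Two axes are available and the choice matters:

* per subject (pipeline default) — each subject-visit's whole
  connection profile is scaled to unit Euclidean norm.  This removes
  global scale differences between subjects and visits while leaving
  each connection's cross-subject mean shift intact, so the t-tests
  keep their nominal calibration and their power against planted
  longitudinal effects (applied upstream, see
  :func:`normalize_subject_profiles`);
* per connection (``normalize=True`` here) — each visit's cross-subject
  vector is scaled to unit norm.  Because connectivity features are
  positive with mean well above their spread, this removes most of any
  across-the-board shift between visits and is therefore very
  conservative against exactly the effects the screening looks for; it
  is kept selectable as the literal reading of the procedure but is not
  the default.

The temporal profile of a significant connection is then
classified by the signs of the two t statistics (e.g. positive →
negative: an increase from baseline to visit 1 followed by a decrease).

Degenerate connections (zero-variance differences, zero within-group
variance) are reported as non-significant with an explicit flag rather
than dropped, so the result list always covers every tested connection.
Optional Benjamini–Hochberg correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionTable

__all__ = [
    "GroupConnectionSample",
    "LongitudinalTestResult",
    "normalize_sum_squares",
    "normalize_subject_profiles",
    "paired_ttest",
    "independent_ttest",
    "oneway_anova",
    "find_significant_connections",
    "classify_sign_pattern",
    "results_to_frame",
    "write_results_csv",
    "DegenerateTestError",
]

SIGN_PATTERNS = (
    "positive_to_negative",
    "negative_to_positive",
    "same_sign_positive",
    "same_sign_negative",
)


class DegenerateTestError(ValueError):
    """A test statistic is undefined (zero variance where variance is needed)."""


@dataclass
class GroupConnectionSample:
    """Connection values of one directed connection across a group.

    ``per_visit_values`` has one row per subject and one column per
    visit (baseline, visit 1, visit 2); rows are the same subjects in
    the same order at every visit (paired design).
    """

    group: str
    connection: tuple[int, int]  # (source region index, target region index)
    per_visit_values: np.ndarray  # (n_subjects, n_visits)

    def __post_init__(self):
        self.per_visit_values = np.asarray(self.per_visit_values, dtype=float)
        if self.per_visit_values.ndim != 2:
            raise ValueError("per_visit_values must be subjects × visits")
        if self.per_visit_values.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")


@dataclass
class LongitudinalTestResult:
    """All statistics for one connection in one group."""

    group: str
    connection: tuple[int, int]
    t_baseline_v1: float
    p_baseline_v1: float
    t_v1_v2: float
    p_v1_v2: float
    f_anova: float
    p_anova: float
    significant: bool
    sign_pattern: str | None
    degenerate: bool = False


def normalize_sum_squares(values: np.ndarray) -> np.ndarray:
    """Scale a vector so its sum of squares equals one."""
    values = np.asarray(values, dtype=float)
    norm = float(np.sqrt(np.sum(values**2)))
    if norm == 0.0:
        raise DegenerateTestError("cannot normalize an all-zero vector")
    return values / norm


def normalize_subject_profiles(stack: np.ndarray) -> np.ndarray:
    """Unit-sum-of-squares normalization of each subject-visit profile.

    ``stack`` holds connection values with the last axes indexing the
    connections of one subject-visit (e.g. ``(n_subj, n_visits, R, R)``
    matrices with NaN diagonal, or ``(n_subj, n_visits, C)`` vectors);
    each leading-index slice is scaled so its finite entries have unit
    sum of squares.
    """
    stack = np.asarray(stack, dtype=float)
    flat = stack.reshape(stack.shape[0], stack.shape[1], -1) if stack.ndim >= 3 \
        else stack[..., None]
    ss = np.nansum(flat**2, axis=-1)
    if (ss == 0.0).any():
        raise DegenerateTestError("a subject-visit profile is all zero; cannot normalize")
    norms = np.sqrt(ss).reshape(stack.shape[0], stack.shape[1],
                                *([1] * (stack.ndim - 2)))
    return stack / norms


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on the differences ``b − a`` (two-sided).

    ``t = mean(d) / (sd(d)/√n)`` on n−1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    d = b - a
    if np.ptp(d) == 0.0:
        raise DegenerateTestError("paired differences are constant; t undefined")
    res = sp_stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


def independent_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample (unpaired, equal-variance) t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise DegenerateTestError("both samples constant; t undefined")
    res = sp_stats.ttest_ind(b, a)
    return float(res.statistic), float(res.pvalue)


def oneway_anova(v0: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA over three samples (visits as groups)."""
    groups = [np.asarray(v, dtype=float) for v in (v0, v1, v2)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each visit sample needs at least 2 values")
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    if ss_within == 0.0:
        raise DegenerateTestError("zero within-group variance; F undefined")
    res = sp_stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def classify_sign_pattern(t1: float, t2: float) -> str:
    """Temporal pattern from the two transition t statistics.

    Exact zeros take the nonzero partner's sign; the double-zero case is
    ``same_sign_positive`` by convention.
    """
    if not (np.isfinite(t1) and np.isfinite(t2)):
        raise ValueError("sign pattern requires finite t statistics")
    if t1 > 0 > t2:
        return "positive_to_negative"
    if t1 < 0 < t2:
        return "negative_to_positive"
    if t1 == 0.0 and t2 == 0.0:
        return "same_sign_positive"
    ref = t1 if t1 != 0.0 else t2
    return "same_sign_positive" if ref > 0 else "same_sign_negative"


def _vectorized_tests(values: np.ndarray, paired: bool) -> tuple[np.ndarray, ...]:
    """t and ANOVA statistics for a (C, n, 3) stack of connections.

    Returns (t1, p1, t2, p2, f, pf, degenerate) arrays of length C.
    NaNs mark degenerate connections.
    """
    v0, v1, v2 = values[:, :, 0], values[:, :, 1], values[:, :, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        if paired:
            deg_t1 = np.ptp(v1 - v0, axis=1) == 0.0
            deg_t2 = np.ptp(v2 - v1, axis=1) == 0.0
            r1 = sp_stats.ttest_rel(v1, v0, axis=1)
            r2 = sp_stats.ttest_rel(v2, v1, axis=1)
        else:
            deg_t1 = (np.ptp(v0, axis=1) == 0.0) & (np.ptp(v1, axis=1) == 0.0)
            deg_t2 = (np.ptp(v1, axis=1) == 0.0) & (np.ptp(v2, axis=1) == 0.0)
            r1 = sp_stats.ttest_ind(v1, v0, axis=1)
            r2 = sp_stats.ttest_ind(v2, v1, axis=1)
        ssw = sum(np.sum((v - v.mean(axis=1, keepdims=True)) ** 2, axis=1)
                  for v in (v0, v1, v2))
        deg_f = ssw == 0.0
        rf = sp_stats.f_oneway(v0, v1, v2, axis=1)
    t1 = np.where(deg_t1, np.nan, r1.statistic)
    p1 = np.where(deg_t1, np.nan, r1.pvalue)
    t2 = np.where(deg_t2, np.nan, r2.statistic)
    p2 = np.where(deg_t2, np.nan, r2.pvalue)
    f = np.where(deg_f, np.nan, rf.statistic)
    pf = np.where(deg_f, np.nan, rf.pvalue)
    degenerate = deg_t1 | deg_t2 | deg_f | ~np.isfinite(p1) | ~np.isfinite(p2) | ~np.isfinite(pf)
    return t1, p1, t2, p2, f, pf, degenerate


def find_significant_connections(
    samples: Sequence[GroupConnectionSample],
    alpha: float = 0.05,
    normalize: bool = False,
    paired: bool = True,
    correction: str | None = None,
) -> list[LongitudinalTestResult]:
    """Run the two-stage screening on every connection sample.

    Per connection: optional unit-sum-of-squares normalization of each
    visit's cross-subject vector (``normalize=True``; see the module
    docstring for why the pipeline normalizes per subject upstream
    instead), the two transition t-tests, the three-visit one-way
    ANOVA; significant iff all three p-values fall below ``alpha``.
    Degenerate connections are reported with ``degenerate=True`` and
    ``significant=False``, never dropped.

    ``correction='bh'`` applies Benjamini–Hochberg across connections to
    each of the three p-value families before thresholding (off by
    default, matching the uncorrected screening procedure).
    """
    if not samples:
        raise ValueError("empty sample list")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if correction not in (None, "none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    for s in samples:
        if s.per_visit_values.shape[1] != 3:
            raise ValueError("the screening procedure expects exactly 3 visits")

    # vectorize per block of identical subject counts
    t1 = np.empty(len(samples)); p1 = np.empty(len(samples))
    t2 = np.empty(len(samples)); p2 = np.empty(len(samples))
    f = np.empty(len(samples)); pf = np.empty(len(samples))
    degenerate = np.zeros(len(samples), dtype=bool)
    by_n: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        by_n.setdefault(s.per_visit_values.shape[0], []).append(i)
    for n, idxs in by_n.items():
        stack = np.stack([samples[i].per_visit_values for i in idxs])  # (C, n, 3)
        if normalize:
            norms = np.sqrt(np.sum(stack**2, axis=1, keepdims=True))
            zero = norms == 0.0
            stack = np.where(zero, np.nan, stack / np.where(zero, 1.0, norms))
        res = _vectorized_tests(stack, paired)
        for arr, out in zip(res[:6], (t1, p1, t2, p2, f, pf)):
            out[idxs] = arr
        degenerate[idxs] = res[6]

    if correction == "bh":
        for p in (p1, p2, pf):
            ok = np.isfinite(p)
            if ok.any():
                p[ok] = multipletests(p[ok], method="fdr_bh")[1]

    with np.errstate(invalid="ignore"):
        significant = (p1 < alpha) & (p2 < alpha) & (pf < alpha) & ~degenerate

    results = []
    for i, s in enumerate(samples):
        pattern = None
        if np.isfinite(t1[i]) and np.isfinite(t2[i]):
            pattern = classify_sign_pattern(float(t1[i]), float(t2[i]))
        results.append(LongitudinalTestResult(
            group=s.group, connection=s.connection,
            t_baseline_v1=float(t1[i]), p_baseline_v1=float(p1[i]),
            t_v1_v2=float(t2[i]), p_v1_v2=float(p2[i]),
            f_anova=float(f[i]), p_anova=float(pf[i]),
            significant=bool(significant[i]), sign_pattern=pattern,
            degenerate=bool(degenerate[i]),
        ))
    return results


def results_to_frame(results: Sequence[LongitudinalTestResult],
                     table: RegionTable | None = None) -> pd.DataFrame:
    """Tabulate results; abbreviations resolved when a table is given."""
    def abbr(idx: int) -> str:
        return table.abbreviation_of(idx) if table is not None else f"R{idx}"

    rows = [{
        "group": r.group,
        "source": r.connection[0],
        "target": r.connection[1],
        "source_abbr": abbr(r.connection[0]),
        "target_abbr": abbr(r.connection[1]),
        "t1": r.t_baseline_v1, "p1": r.p_baseline_v1,
        "t2": r.t_v1_v2, "p2": r.p_v1_v2,
        "F": r.f_anova, "pF": r.p_anova,
        "significant": r.significant,
        "sign_pattern": r.sign_pattern or "",
        "degenerate": r.degenerate,
    } for r in results]
    return pd.DataFrame(rows)


def write_results_csv(results: Sequence[LongitudinalTestResult], path: str | Path,
                      table: RegionTable | None = None) -> None:
    results_to_frame(results, table).to_csv(path, index=False, float_format="%.10g")
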