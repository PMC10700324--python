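"""Region- and network-level summaries of significant connections.

Three views of a group's significant-connection set:

* per-source counts — how many significant directed connections
  originate at each region (the directed "hub" view);
* network-pair counts — each connection increments the unordered pair
  of its endpoints' functional networks (directionality ignored), a
  6 × 6 upper-triangle-plus-diagonal table;
* percentage contribution — per network, the share of distinct regions
  touched by any significant connection (denominator configurable:
  distinct regions, or connection endpoints counted with multiplicity).

An empty significant set yields zero counts and zero percentages by
convention — a group with no longitudinal change is a data outcome, not
an error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .longitudinal_stats import LongitudinalTestResult
from .regions import NETWORKS, RegionTable

__all__ = [
    "NetworkPairCounts",
    "ContributionTable",
    "count_by_source_region",
    "count_network_pairs",
    "percent_contribution",
    "compare_methods",
    "write_circos_table",
]


def _significant(results: Sequence[LongitudinalTestResult]) -> list[LongitudinalTestResult]:
    return [r for r in results if r.significant]


@dataclass
class NetworkPairCounts:
    """Counts of significant connections per unordered network pair.

    ``counts`` has all 21 keys (15 off-diagonal pairs + 6 diagonal),
    each a tuple sorted in canonical network order.
    """

    counts: dict[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def matrix(self) -> pd.DataFrame:
        """Symmetric 6×6 count table (off-diagonal cells mirrored)."""
        frame = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS))
        for (a, b), c in self.counts.items():
            frame.loc[a, b] += c
            if a != b:
                frame.loc[b, a] += c
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.matrix().to_csv(path)


@dataclass
class ContributionTable:
    """Per-network contributing-region counts and percentages."""

    region_counts: dict[str, int]
    percentages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "network": list(NETWORKS),
            "regions": [self.region_counts[n] for n in NETWORKS],
            "percent": [self.percentages[n] for n in NETWORKS],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _pair_key(net_a: str, net_b: str) -> tuple[str, str]:
    order = {n: i for i, n in enumerate(NETWORKS)}
    return (net_a, net_b) if order[net_a] <= order[net_b] else (net_b, net_a)


def count_by_source_region(results: Sequence[LongitudinalTestResult]) -> dict[int, int]:
    """Significant directed connections per source region.

    The values sum to the number of significant connections (the
    sum-of-parts identity used to cross-check figure-level totals).
    """
    counts: dict[int, int] = {}
    for r in _significant(results):
        src = r.connection[0]
        counts[src] = counts.get(src, 0) + 1
    return counts


def count_network_pairs(results: Sequence[LongitudinalTestResult],
                        table: RegionTable) -> NetworkPairCounts:
    """Significant connections per unordered functional-network pair."""
    counts = {
        _pair_key(a, b): 0
        for a, b in itertools.combinations_with_replacement(NETWORKS, 2)
    }
    for r in _significant(results):
        src, tgt = r.connection
        key = _pair_key(table.network_of(src), table.network_of(tgt))
        counts[key] += 1
    return NetworkPairCounts(counts=counts)


def percent_contribution(results: Sequence[LongitudinalTestResult],
                         table: RegionTable,
                         denominator: str = "distinct_regions") -> ContributionTable:
    """Per-network share of regions involved in significant connections.

    ``denominator='distinct_regions'`` (default): contributing regions
    of a network are the distinct regions of that network appearing as
    source or target of any significant connection, and percentages are
    taken over the total distinct regions across all networks.
    ``denominator='endpoints'`` counts connection endpoints with
    multiplicity instead.
    """
    if denominator not in ("distinct_regions", "endpoints"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    sig = _significant(results)
    region_counts = {n: 0 for n in NETWORKS}
    if denominator == "distinct_regions":
        regions = {idx for r in sig for idx in r.connection}
        for idx in regions:
            region_counts[table.network_of(idx)] += 1
    else:
        for r in sig:
            for idx in r.connection:
                region_counts[table.network_of(idx)] += 1
    total = sum(region_counts.values())
    if total == 0:
        percentages = {n: 0.0 for n in NETWORKS}  # empty-set convention
    else:
        percentages = {n: 100.0 * c / total for n, c in region_counts.items()}
    return ContributionTable(region_counts=region_counts, percentages=percentages)


def compare_methods(corrtf_table: ContributionTable,
                    pearson_table: ContributionTable) -> pd.DataFrame:
    """Side-by-side per-network contribution of the two connectivity arms.

    No statistical test is attached — the comparison is descriptive.
    """
    if set(corrtf_table.percentages) != set(pearson_table.percentages):
        raise ValueError("contribution tables cover different network sets")
    return pd.DataFrame({
        "network": list(NETWORKS),
        "corrtf_percent": [corrtf_table.percentages[n] for n in NETWORKS],
        "pearson_percent": [pearson_table.percentages[n] for n in NETWORKS],
        "difference": [corrtf_table.percentages[n] - pearson_table.percentages[n]
                       for n in NETWORKS],
    })


def write_circos_table(results: Sequence[LongitudinalTestResult],
                       table: RegionTable, path: str | Path) -> None:
    """Write a CIRCOS-tableviewer-compatible region count matrix.

    Rows are source regions, columns target regions (labels =
    abbreviations), cells the number of significant connections; only
    regions participating in at least one significant connection are
    included, keeping the table compact for the online tableviewer.
    """
    sig = _significant(results)
    involved = sorted({idx for r in sig for idx in r.connection})
    labels = [table.abbreviation_of(i) for i in involved]
    pos = {idx: k for k, idx in enumerate(involved)}
    frame = pd.DataFrame(0, index=labels, columns=labels)
    for r in sig:
        src, tgt = r.connection
        frame.iloc[pos[src], pos[tgt]] += 1
    with open(path, "w") as fh:
        fh.write("labels\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, frame.itertuples(index=False)):
            fh.write(lab + "\t" + "\t".join(str(v) for v in row) + "\n")
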