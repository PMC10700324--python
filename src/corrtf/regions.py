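"""AAL-116 region table and the region → functional-network mapping.

The package ships a complete table of the 116 Automated Anatomical
Labeling (AAL) regions — 90 cerebral regions in the standard paired
ordering (odd index = left, even = right), 18 cerebellar hemisphere
regions, and 8 midline vermis regions — each assigned to one of six
functional networks:

``SMC``  sensorimotor cortex, ``EAN`` executive attention network,
``VC``   visual cortex,       ``Cereb`` cerebellum,
``DMN``  default-mode network, ``SN``  subcortical nuclei.

The network assignment is a documented reconstruction from conventional
AAL groupings (no authoritative per-region table exists for this exact
six-network scheme) and can be overridden region-by-region with a YAML
or TSV file, so analyses never depend on a hard-coded mapping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "NETWORKS",
    "HEMISPHERES",
    "Region",
    "RegionTable",
    "load_region_table",
    "network_of",
    "RegionConfigError",
]

#: The six functional networks used for network-level summaries.
NETWORKS: tuple[str, ...] = ("SMC", "EAN", "VC", "Cereb", "DMN", "SN")

HEMISPHERES: tuple[str, ...] = ("left", "right", "midline")

_RESOURCE = "aal116_regions.tsv"
_COLUMNS = ["index", "name", "abbreviation", "hemisphere", "network"]


class RegionConfigError(ValueError):
    """Raised for invalid region tables or network-mapping overrides."""


@dataclass(frozen=True)
class Region:
    """One atlas region: 1-based atlas label plus naming and grouping."""

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    network: str


class RegionTable:
    """Ordered table of the 116 AAL regions.

    Wraps a :class:`pandas.DataFrame` with columns
    ``index, name, abbreviation, hemisphere, network`` and validates the
    structural invariants on construction: exactly contiguous 1..N
    indices, unique names/abbreviations, and networks drawn from the
    closed six-label vocabulary.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, _COLUMNS].copy()
        frame["index"] = frame["index"].astype(int)
        frame = frame.sort_values("index").reset_index(drop=True)
        n = len(frame)
        if list(frame["index"]) != list(range(1, n + 1)):
            raise RegionConfigError(
                "region indices must be unique and contiguous starting at 1"
            )
        if frame["abbreviation"].duplicated().any():
            dup = frame.loc[frame["abbreviation"].duplicated(), "abbreviation"]
            raise RegionConfigError(f"duplicate abbreviations: {sorted(set(dup))}")
        bad_net = set(frame["network"]) - set(NETWORKS)
        if bad_net:
            raise RegionConfigError(
                f"unknown network labels {sorted(bad_net)}; expected one of {NETWORKS}"
            )
        bad_hemi = set(frame["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise RegionConfigError(f"unknown hemisphere labels {sorted(bad_hemi)}")
        self._frame = frame
        self._by_index = {r.index: r for r in self}
        self._by_abbr = {r.abbreviation: r for r in self}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[Region]:
        for row in self._frame.itertuples(index=False):
            yield Region(row.index, row.name, row.abbreviation, row.hemisphere, row.network)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    # -- lookups -------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table as a DataFrame (copy)."""
        return self._frame.copy()

    def region(self, index: int) -> Region:
        try:
            return self._by_index[int(index)]
        except KeyError:
            raise IndexError(f"region index {index} out of range 1..{len(self)}") from None

    def by_abbreviation(self, abbr: str) -> Region:
        try:
            return self._by_abbr[abbr]
        except KeyError:
            raise KeyError(f"unknown region abbreviation {abbr!r}") from None

    def network_of(self, index: int) -> str:
        """Functional-network label of region ``index`` (1-based)."""
        return self.region(index).network

    def abbreviation_of(self, index: int) -> str:
        return self.region(index).abbreviation

    @property
    def abbreviations(self) -> list[str]:
        return list(self._frame["abbreviation"])

    def indices_of_network(self, network: str) -> list[int]:
        if network not in NETWORKS:
            raise RegionConfigError(f"unknown network {network!r}")
        sel = self._frame["network"] == network
        return [int(i) for i in self._frame.loc[sel, "index"]]

    # -- serialization -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def with_overrides(self, mapping: Mapping[object, str]) -> "RegionTable":
        """Return a new table with network reassignments applied.

        Keys may be integer region indices or abbreviation strings;
        values must be one of the six network labels.
        """
        frame = self._frame.copy()
        for key, network in mapping.items():
            if network not in NETWORKS:
                raise RegionConfigError(
                    f"override for {key!r} assigns unknown network {network!r}"
                )
            if isinstance(key, int) or (isinstance(key, str) and key.isdigit()):
                idx = int(key)
                if idx not in self._by_index:
                    raise RegionConfigError(f"override names unknown region index {idx}")
                frame.loc[frame["index"] == idx, "network"] = network
            elif isinstance(key, str):
                if key not in self._by_abbr:
                    raise RegionConfigError(f"override names unknown abbreviation {key!r}")
                frame.loc[frame["abbreviation"] == key, "network"] = network
            else:
                raise RegionConfigError(f"override key {key!r} is neither index nor abbreviation")
        return RegionTable(frame)


def _read_override(path: str | Path) -> dict[object, str]:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise RegionConfigError(f"override file {path} must be a mapping")
        return dict(data)
    # TSV with two columns: region key (index or abbreviation), network
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise RegionConfigError(f"override TSV {path} needs two columns (region, network)")
    key_col, net_col = frame.columns[0], frame.columns[1]
    return {k: v for k, v in zip(frame[key_col], frame[net_col])}


def load_region_table(mapping_override: str | Path | None = None) -> RegionTable:
    """Load the packaged AAL-116 table, optionally overriding network labels.

    Parameters
    ----------
    mapping_override:
        Optional YAML (``{region: network}`` mapping) or two-column TSV
        reassigning the functional network of specific regions, keyed by
        1-based index or abbreviation.
    """
    resource = importlib.resources.files("corrtf.data").joinpath(_RESOURCE)
    with importlib.resources.as_file(resource) as path:
        table = RegionTable.from_tsv(path)
    if len(table) != 116:
        raise RegionConfigError(f"packaged table has {len(table)} regions, expected 116")
    if mapping_override is not None:
        table = table.with_overrides(_read_override(mapping_override))
    return table


def network_of(region_index: int, table: RegionTable) -> str:
    """Functional-network label of ``region_index`` in ``table``."""
    return table.network_of(region_index)
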