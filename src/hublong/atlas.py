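"""Parcellation handling: network labels, a-priori hub partition, tumor overlap.

The cortical parcellation assigns each of N regions to one functional
network.  Hubs are defined a priori as the default-mode network (DMN)
together with the fronto-parietal network (FTPN); every other network is
"no-hub" (primary sensory, salience, cingulo-opercular, attention, ...).
No centrality measure is computed: the partition is fixed by network label.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HUB_NETWORKS",
    "KNOWN_NETWORKS",
    "Parcellation",
    "TumorOverlap",
    "load_parcellation",
    "reference_parcellation",
    "tumor_overlap",
]

#: network label -> hub class.  DMN and FTPN are the a-priori hubs.
HUB_NETWORKS = {"Default": "DMN", "FrontoParietal": "FTPN"}

#: all network labels the loader accepts (the 13 reference networks).
KNOWN_NETWORKS = frozenset(
    {
        "Default",
        "FrontoParietal",
        "Visual",
        "Auditory",
        "SMhand",
        "SMmouth",
        "Salience",
        "CinguloOperc",
        "CinguloParietal",
        "RetrosplenialTemporal",
        "VentralAttn",
        "DorsalAttn",
        "None",
    }
)

HUB_CLASSES = ("DMN", "FTPN", "NOHUB")


def _hub_class(network: str) -> str:
    return HUB_NETWORKS.get(network, "NOHUB")


@dataclass(frozen=True)
class Parcellation:
    """A labelled cortical parcellation.

    ``table`` has one row per region with columns ``region_id`` (1..N,
    contiguous), ``region_name``, ``network``, ``hub_class`` and
    ``n_voxels``.
    """

    table: pd.DataFrame

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    def regions_of(self, hub_class: str) -> np.ndarray:
        """Region ids in one hub class (``DMN``, ``FTPN`` or ``NOHUB``)."""
        if hub_class not in HUB_CLASSES:
            raise ValueError(f"unknown hub class {hub_class!r}; expected one of {HUB_CLASSES}")
        mask = self.table["hub_class"] == hub_class
        return self.table.loc[mask, "region_id"].to_numpy()

    @property
    def hub_region_ids(self) -> np.ndarray:
        """DMN ∪ FTPN, treated downstream as a single extended hub network."""
        mask = self.table["hub_class"].isin(("DMN", "FTPN"))
        return self.table.loc[mask, "region_id"].to_numpy()

    @property
    def nohub_region_ids(self) -> np.ndarray:
        return self.regions_of("NOHUB")

    def hub_class_counts(self) -> dict[str, int]:
        counts = self.table["hub_class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in HUB_CLASSES}


@dataclass(frozen=True)
class TumorOverlap:
    """Percent of atlas voxels labelled tumor, per hub class and overall."""

    pct_hubs: float
    pct_nohubs: float
    pct_total: float


def _build_parcellation(df: pd.DataFrame, source: str = "<table>") -> Parcellation:
    required = ["region_id", "region_name", "network", "n_voxels"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    df = df[required].copy()
    df["region_id"] = df["region_id"].astype(int)
    df["n_voxels"] = df["n_voxels"].astype(int)

    dupes = df.loc[df["region_id"].duplicated(), "region_id"].unique()
    if len(dupes):
        raise ValueError(f"{source}: duplicate region_id values {sorted(dupes.tolist())}")
    n = len(df)
    expected = np.arange(1, n + 1)
    got = np.sort(df["region_id"].to_numpy())
    if not np.array_equal(got, expected):
        raise ValueError(f"{source}: region_ids must be contiguous 1..{n}")
    unknown = sorted(set(df["network"]) - KNOWN_NETWORKS)
    if unknown:
        raise ValueError(
            f"{source}: unknown network label(s) {unknown}; allowed labels: "
            f"{sorted(KNOWN_NETWORKS)}"
        )
    if (df["n_voxels"] < 0).any():
        raise ValueError(f"{source}: n_voxels must be nonnegative")

    df = df.sort_values("region_id").reset_index(drop=True)
    df["hub_class"] = df["network"].map(_hub_class)
    return Parcellation(df)


def load_parcellation(label_table_path: str | Path) -> Parcellation:
    """Load a parcellation label table (TSV with a header row).

    Required columns: ``region_id``, ``region_name``, ``network``,
    ``n_voxels``.  The hub class of each region is derived from its
    network label.  Lines starting with ``#`` are ignored.
    """
    path = Path(label_table_path)
    # "None" is a legitimate network label; disable NA sniffing on it
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[""])
    return _build_parcellation(df, source=str(path))


def parcellation_from_frame(df: pd.DataFrame) -> Parcellation:
    """Build a :class:`Parcellation` from an in-memory label table."""
    return _build_parcellation(df)


def reference_parcellation() -> Parcellation:
    """The packaged 333-region reference parcellation.

    Network names and per-network region counts follow the reference
    cortical parcellation; region names and voxel counts in the packaged
    table are synthetic stand-ins (the real voxel geometry is not shipped).
    """
    ref = importlib.resources.files("hublong.data") / "gordon333_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_parcellation(path)


def tumor_overlap(parc: Parcellation, tumor_voxels_per_region: dict[int, int]) -> TumorOverlap:
    """Percent of hub / no-hub / all atlas voxels overlapping tumor tissue.

    ``tumor_voxels_per_region`` maps region_id to the number of that
    region's voxels labelled tumor; regions not listed count as zero.
    Each tumor count must not exceed the region's size.
    """
    table = parc.table.set_index("region_id")
    counts = pd.Series(0, index=table.index, dtype=float)
    for rid, cnt in tumor_voxels_per_region.items():
        if rid not in table.index:
            raise ValueError(f"tumor count for unknown region_id {rid}")
        if cnt < 0:
            raise ValueError(f"negative tumor voxel count for region {rid}")
        if cnt > table.loc[rid, "n_voxels"]:
            raise ValueError(
                f"tumor voxels ({cnt}) exceed region size "
                f"({table.loc[rid, 'n_voxels']}) for region {rid}"
            )
        counts.loc[rid] = cnt

    is_hub = table["hub_class"].isin(("DMN", "FTPN"))
    v_hub = float(table.loc[is_hub, "n_voxels"].sum())
    v_nohub = float(table.loc[~is_hub, "n_voxels"].sum())
    t_hub = float(counts[is_hub].sum())
    t_nohub = float(counts[~is_hub].sum())

    def pct(t: float, v: float) -> float:
        return 100.0 * t / v if v > 0 else 0.0

    return TumorOverlap(
        pct_hubs=pct(t_hub, v_hub),
        pct_nohubs=pct(t_nohub, v_nohub),
        pct_total=pct(t_hub + t_nohub, v_hub + v_nohub),
    )
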