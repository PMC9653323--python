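"""Spatial connectomic profiles: the five block-mean FC metrics.

From a globally normalized FC matrix and the hub partition, five scalars
summarize each subject-visit: mean FC (i) within DMN, (ii) within FTPN,
(iii) within hubs (DMN ∪ FTPN as one extended network, including the
DMN-FTPN cross pairs), (iv) between hubs and no-hubs, and (v) within
no-hubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Parcellation
from .connectome import ConnectivityMatrix

__all__ = ["SpatialProfile", "PROFILE_METRICS", "block_mean", "compute_profile", "profiles_to_long"]

#: canonical metric order used across tables and models
PROFILE_METRICS = (
    "within_dmn",
    "within_ftpn",
    "within_hubs",
    "within_nohubs",
    "between_hubs_nohubs",
)


@dataclass(frozen=True)
class SpatialProfile:
    """Five FC metrics for one subject-visit (NaN = undefined metric)."""

    subject_id: str
    months: float
    within_dmn: float
    within_ftpn: float
    within_hubs: float
    within_nohubs: float
    between_hubs_nohubs: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in PROFILE_METRICS}


def block_mean(fc: ConnectivityMatrix, set_a, set_b) -> float:
    """Mean FC over a block of region pairs.

    If ``set_a == set_b`` (as sets), averages over the unordered within-set
    pairs i<j; if the sets are disjoint, over all cross pairs.  Overlapping
    but unequal sets have no single meaning and are rejected.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if not a or not b:
        raise ValueError("region sets must be non-empty")
    ia = fc.index_of(a)
    ib = fc.index_of(b)
    if a == b:
        if len(a) < 2:
            raise ValueError("a within-set mean needs at least 2 regions")
        sub = fc.values[np.ix_(ia, ia)]
        iu = np.triu_indices(len(a), k=1)
        return float(sub[iu].mean())
    if set(a) & set(b):
        raise ValueError("region sets must be identical or disjoint")
    return float(fc.values[np.ix_(ia, ib)].mean())


def _safe_block_mean(fc: ConnectivityMatrix, set_a, set_b, min_within: int = 2) -> float:
    a, b = set(set_a), set(set_b)
    if a == b and len(a) < min_within:
        return math.nan
    if a != b and (not a or not b):
        return math.nan
    return block_mean(fc, a, b)


def compute_profile(
    fc_norm: ConnectivityMatrix,
    parc: Parcellation,
    *,
    subject_id: str = "",
    months: float = float("nan"),
) -> SpatialProfile:
    """The five spatial connectomic metrics of one normalized FC matrix.

    Only regions present in the matrix contribute (regions dropped as
    empty simply shrink the class sets).  A within-class metric whose
    class retains fewer than 2 regions is reported as NaN, never as zero.
    """
    if not fc_norm.normalized:
        raise ValueError("profiles are defined on globally normalized matrices")
    present = set(fc_norm.region_ids)
    dmn = set(parc.regions_of("DMN")) & present
    ftpn = set(parc.regions_of("FTPN")) & present
    hubs = dmn | ftpn
    nohubs = set(parc.regions_of("NOHUB")) & present
    unknown = present - (hubs | nohubs)
    if unknown:
        raise ValueError(f"matrix regions absent from parcellation: {sorted(unknown)}")

    subject = subject_id
    between = math.nan
    if hubs and nohubs:
        between = block_mean(fc_norm, hubs, nohubs)
    return SpatialProfile(
        subject_id=subject,
        months=months,
        within_dmn=_safe_block_mean(fc_norm, dmn, dmn),
        within_ftpn=_safe_block_mean(fc_norm, ftpn, ftpn),
        within_hubs=_safe_block_mean(fc_norm, hubs, hubs),
        within_nohubs=_safe_block_mean(fc_norm, nohubs, nohubs),
        between_hubs_nohubs=between,
    )


def profiles_to_long(profiles: list[SpatialProfile]) -> pd.DataFrame:
    """Long-format table: subject_id, months, metric, value (NaN rows kept).

    This is the canonical hand-off to the longitudinal models; missing
    metrics propagate as missing observations, never imputed.
    """
    rows = []
    for p in profiles:
        for m, v in p.as_dict().items():
            rows.append({"subject_id": p.subject_id, "months": p.months, "metric": m, "value": v})
    return pd.DataFrame(rows, columns=["subject_id", "months", "metric", "value"])
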