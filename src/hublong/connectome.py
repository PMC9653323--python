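"""Per-session functional-connectivity matrices.

A session is one subject-visit T×N matrix of region-averaged BOLD-like
signal.  The FC matrix is the absolute Pearson correlation between region
time series (values in [0, 1]); each subject-session matrix is then
divided by its own whole-brain mean FC (the mean over the N(N-1)/2 unique
off-diagonal pairs) so that profiles are comparable across subjects
despite global FC differences.  The diagonal never enters any average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SessionTimeSeries",
    "ConnectivityMatrix",
    "extract_region_series",
    "fc_matrix",
    "global_normalize",
    "read_session_tsv",
    "write_session_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class SessionTimeSeries:
    """One subject-visit's parcel-level signal: T time points × N regions."""

    subject_id: str
    months: float
    data: np.ndarray  # (T, N)
    region_ids: list[int]
    empty_regions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a T×N matrix")
        if self.data.shape[1] != len(self.region_ids):
            raise ValueError("number of columns must match region_ids")
        if self.months < 0:
            raise ValueError("months since surgery must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative FC matrix over an ordered region list."""

    values: np.ndarray
    region_ids: list[int]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match region_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def offdiag_mean(self) -> float:
        """Mean over the unique off-diagonal pairs (the whole-brain mean FC)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return float(self.values[iu].mean())

    def index_of(self, region_ids) -> np.ndarray:
        pos = {rid: i for i, rid in enumerate(self.region_ids)}
        try:
            return np.array([pos[r] for r in region_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"region {e.args[0]} not present in this matrix") from e


def extract_region_series(
    voxel_data: np.ndarray,
    voxel_labels: np.ndarray,
    gm_prob: np.ndarray,
    gm_threshold: float = 0.5,
    *,
    subject_id: str = "",
    months: float = 0.0,
    region_ids: list[int] | None = None,
) -> SessionTimeSeries:
    """Average voxel signals into region time series under a GM mask.

    Parameters
    ----------
    voxel_data : (V, T) array of voxel signals.
    voxel_labels : (V,) integer region id per voxel (0 = unlabelled).
    gm_prob : (V,) gray-matter probability per voxel, in [0, 1].
    gm_threshold : voxels with ``gm_prob < gm_threshold`` are excluded.
    region_ids : regions to extract; defaults to the sorted nonzero labels.

    A region whose voxels all fall below the GM threshold is flagged empty
    (its column is NaN) and later dropped from the FC matrix.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    voxel_labels = np.asarray(voxel_labels)
    gm_prob = np.asarray(gm_prob, dtype=float)
    if voxel_data.ndim != 2:
        raise ValueError("voxel_data must be a V×T matrix")
    if gm_prob.min() < 0 or gm_prob.max() > 1:
        raise ValueError("gm_prob values must lie in [0, 1]")
    if voxel_labels.shape[0] != voxel_data.shape[0] or gm_prob.shape[0] != voxel_data.shape[0]:
        raise ValueError("voxel_labels and gm_prob must have one entry per voxel")

    if region_ids is None:
        region_ids = sorted(int(r) for r in np.unique(voxel_labels) if r != 0)
    if not region_ids:
        raise ValueError("no regions to extract")

    keep = gm_prob >= gm_threshold
    T = voxel_data.shape[1]
    out = np.full((T, len(region_ids)), np.nan)
    empty: list[int] = []
    for j, rid in enumerate(region_ids):
        sel = keep & (voxel_labels == rid)
        if sel.any():
            out[:, j] = voxel_data[sel].mean(axis=0)
        else:
            empty.append(rid)
    if len(empty) == len(region_ids):
        raise ValueError("all regions are empty after GM masking")
    if empty:
        logger.warning(
            "subject %s, %.1f months: %d region(s) empty after GM masking: %s",
            subject_id, months, len(empty), empty,
        )
    return SessionTimeSeries(subject_id, months, out, list(region_ids), empty)


def fc_matrix(ts: SessionTimeSeries) -> ConnectivityMatrix:
    """Absolute Pearson correlation between all region time series.

    Regions flagged empty are dropped (row and column removed); a
    zero-variance series that is *not* flagged empty is an error, because
    its correlations are undefined.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to estimate correlations")
    keep = [i for i, rid in enumerate(ts.region_ids) if rid not in ts.empty_regions]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-empty regions")
    data = ts.data[:, keep]
    kept_ids = [ts.region_ids[i] for i in keep]
    sd = data.std(axis=0)
    dead = [kept_ids[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(
            f"zero-variance time series for region(s) {dead}; "
            "flag them as empty to drop them"
        )
    r = np.corrcoef(data, rowvar=False)
    vals = np.abs(r)
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    if ts.empty_regions:
        logger.info(
            "subject %s: dropped %d empty region(s) from FC matrix",
            ts.subject_id, len(ts.empty_regions),
        )
    return ConnectivityMatrix(vals, kept_ids, normalized=False)


def global_normalize(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide off-diagonal FC by the subject's whole-brain mean FC.

    After normalization the off-diagonal mean is exactly 1, so the
    operation is idempotent.  The diagonal is left untouched (it is
    excluded from every aggregation).
    """
    mean = fc.offdiag_mean()
    if mean <= 0:
        raise ValueError("whole-brain mean FC must be positive to normalize")
    vals = fc.values / mean
    np.fill_diagonal(vals, np.diag(fc.values))
    return ConnectivityMatrix(vals, list(fc.region_ids), normalized=True)


# ---------------------------------------------------------------------------
# TSV round-trip helpers

def write_session_tsv(ts: SessionTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=[str(r) for r in ts.region_ids])
    df.insert(0, "volume", np.arange(ts.n_timepoints))
    df.to_csv(path, sep="\t", index=False)


def read_session_tsv(path: str | Path, subject_id: str, months: float) -> SessionTimeSeries:
    df = pd.read_csv(path, sep="\t")
    region_cols = [c for c in df.columns if c != "volume"]
    data = df[region_cols].to_numpy(dtype=float)
    region_ids = [int(c) for c in region_cols]
    empty = [region_ids[j] for j in np.flatnonzero(np.isnan(data).all(axis=0))]
    return SessionTimeSeries(subject_id, months, data, region_ids, empty)


def write_matrix_tsv(fc: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fc.values, index=fc.region_ids, columns=fc.region_ids)
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, normalized: bool = False) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    region_ids = [int(c) for c in df.columns]
    return ConnectivityMatrix(df.to_numpy(dtype=float), region_ids, normalized=normalized)
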