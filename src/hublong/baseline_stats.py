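"""Baseline group comparisons (LGG vs HGG demographic/clinical table).

Continuous variables are compared with a pooled-variance two-sample
t-test (df = n1 + n2 - 2) or, for skewed variables such as extent of
resection, a Mann-Whitney U with normal approximation and tie correction.
Categorical variables use Pearson chi-square tests without continuity
correction: a 2x2 independence test when both group margins vary, and a
one-sample goodness-of-fit against equal frequencies for whole-cohort
splits (e.g. tumor lateralization left vs right).  No multiple-testing
correction is applied at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "pooled_t",
    "chi2_independence",
    "chi2_gof",
    "mann_whitney_z",
    "baseline_table",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def _summarize(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations per group")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def pooled_t(a, b) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from raw values or summaries.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-sided p.
    """
    ga, gb = _summarize(a), _summarize(b)
    df = ga.n + gb.n - 2
    sp2 = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / df
    if sp2 == 0:
        if ga.mean == gb.mean:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (ga.mean - gb.mean) / np.sqrt(sp2 * (1 / ga.n + 1 / gb.n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 count table.

    No Yates continuity correction.  Returns ``(chi2, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if obs.sum() <= 0:
        raise ValueError("empty table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("a zero marginal makes the test undefined")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def chi2_gof(counts, expected_props=None) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed counts to expected proportions.

    Defaults to equal proportions.  Returns ``(chi2, df, p)`` with
    df = k - 1.
    """
    obs = np.asarray(counts, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    if expected_props is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_props, dtype=float)
        if props.size != obs.size:
            raise ValueError("expected_props must match counts in length")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("expected_props must sum to 1")
    expected = n * props
    if (expected == 0).any():
        raise ValueError("zero expected count makes the test undefined")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, int(df), p


def mann_whitney_z(a, b) -> tuple[float, float]:
    """Mann-Whitney U via normal approximation with tie correction.

    Returns ``(z, p)`` two-sided; z is signed so that a tendency for
    ``a`` to exceed ``b`` gives z > 0.  With every value tied across both
    groups the statistic is 0 and p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Table-1-shaped cohort summary


def _fmt_group(vals: pd.Series) -> str:
    return f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline LGG-vs-HGG comparison table from a cohort covariate frame.

    Expects columns ``grade`` (LGG/HGG), ``lateralization`` (LEFT/RIGHT),
    ``age``, ``sex`` (M/F), ``tumor_volume``, ``idh`` (0/1), ``eor`` and
    optionally ``pct_overlap_hubs`` / ``pct_overlap_nohubs``.
    """
    lgg = cohort[cohort["grade"] == "LGG"]
    hgg = cohort[cohort["grade"] == "HGG"]
    rows = []

    def add(variable, stat_lgg, stat_hgg, statistic, p):
        rows.append(
            {
                "variable": variable,
                "lgg": stat_lgg,
                "hgg": stat_hgg,
                "statistic": statistic,
                "p_value": round(p, 4),
            }
        )

    t, df, p = pooled_t(lgg["age"], hgg["age"])
    add("age", _fmt_group(lgg["age"]), _fmt_group(hgg["age"]), f"t({df}) = {t:.2f}", p)

    males = [int((g["sex"] == "M").sum()) for g in (lgg, hgg)]
    females = [int((g["sex"] == "F").sum()) for g in (lgg, hgg)]
    chi2, _, p = chi2_independence([[males[0], females[0]], [males[1], females[1]]])
    add("sex (# males)", str(males[0]), str(males[1]), f"chi2 = {chi2:.2f}", p)

    n_left = int((cohort["lateralization"] == "LEFT").sum())
    n_right = int((cohort["lateralization"] == "RIGHT").sum())
    chi2, _, p = chi2_gof([n_left, n_right])
    add(
        "lateralization (# left)",
        str(int((lgg["lateralization"] == "LEFT").sum())),
        str(int((hgg["lateralization"] == "LEFT").sum())),
        f"chi2 = {chi2:.2f}",
        p,
    )

    t, df, p = pooled_t(lgg["tumor_volume"], hgg["tumor_volume"])
    add(
        "tumor volume (cm3)",
        _fmt_group(lgg["tumor_volume"]),
        _fmt_group(hgg["tumor_volume"]),
        f"t({df}) = {t:.2f}",
        p,
    )

    if "idh" in cohort.columns:
        mut = [int(g["idh"].sum()) for g in (lgg, hgg)]
        wt = [int((1 - g["idh"]).sum()) for g in (lgg, hgg)]
        try:
            chi2, _, p = chi2_independence([[mut[0], wt[0]], [mut[1], wt[1]]])
            add("IDH mutation (# mutated)", str(mut[0]), str(mut[1]), f"chi2 = {chi2:.2f}", p)
        except ValueError:
            add("IDH mutation (# mutated)", str(mut[0]), str(mut[1]), "NA", float("nan"))

    if "eor" in cohort.columns:
        z, p = mann_whitney_z(lgg["eor"], hgg["eor"])
        add("extent of resection (%)", _fmt_group(lgg["eor"]), _fmt_group(hgg["eor"]), f"Z = {z:.2f}", p)

    for col, label in (
        ("pct_overlap_hubs", "tumor overlap hubs (%)"),
        ("pct_overlap_nohubs", "tumor overlap no-hubs (%)"),
    ):
        if col in cohort.columns:
            t, df, p = pooled_t(lgg[col], hgg[col])
            add(label, _fmt_group(lgg[col]), _fmt_group(hgg[col]), f"t({df}) = {t:.2f}", p)

    return pd.DataFrame(rows)
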