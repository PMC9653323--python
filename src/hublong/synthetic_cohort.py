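"""Synthetic glioma cohorts with the study's longitudinal structure.

The generator emulates a 28-patient cohort (11 low-grade / 17 high-grade
gliomas; 15 left- / 13 right-lateralized) observed at surgery baseline
and up to four follow-up windows (coded at bin midpoints 2, 4.5, 7.5 and
12 months), with per-visit dropout calibrated so the expected total is
about 73 observations.  Two routes are provided:

* the *time-series* route draws T x N BOLD-like sessions from zero-mean
  multivariate normals whose block correlation structure drifts with
  time x lateralization (hubs gain, no-hubs lose FC in right-lateralized
  patients) and time x grade (DMN gains in LGG), exercising the full
  connectome pipeline;
* the *fast* route emits normalized spatial-profile tables directly from
  a linear model on the profile scale, for statistics-only studies where
  thousands of replicate cohorts are needed.

Every draw flows from one integer seed; the returned truth record holds
the generating parameters and the implied fixed-effect coefficients of
the downstream mixed models.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Parcellation, parcellation_from_frame, tumor_overlap
from .connectome import SessionTimeSeries
from .spatial_profile import PROFILE_METRICS

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "CognitiveTestConfig",
    "TruthRecord",
    "default_config",
    "null_config",
    "synthetic_parcellation",
    "simulate_cohort",
    "simulate_session",
    "simulate_profiles_fast",
    "simulate_cognition",
]

#: visit schedule: baseline plus follow-up bin midpoints (months)
DEFAULT_VISITS = (0.0, 2.0, 4.5, 7.5, 12.0)


@dataclass(frozen=True)
class CognitiveTestConfig:
    """Generating model of one neuropsychological score."""

    domain: str
    base: float
    b_time: float = 0.0
    b_time_grade: float = 0.0  # extra slope for LGG
    b_time_lat: float = 0.0  # extra slope for LEFT
    fc_links: dict[str, float] = field(default_factory=dict)  # metric -> beta on metric*months
    intercept_sd: float = 1.0
    resid_sd: float = 1.0
    orientation: int = 1  # -1 for timed tests where higher = worse


def _default_tests() -> dict[str, CognitiveTestConfig]:
    return {
        "rey_figure": CognitiveTestConfig("memory", base=18.0, b_time=0.75, intercept_sd=5.0, resid_sd=5.0),
        "rey_word_list": CognitiveTestConfig("memory", base=9.0, b_time_lat=0.18, intercept_sd=2.0, resid_sd=2.0),
        "digit_span": CognitiveTestConfig(
            "memory", base=5.5, fc_links={"within_dmn": 0.32}, intercept_sd=0.6, resid_sd=0.6
        ),
        "corsi": CognitiveTestConfig("memory", base=4.8, b_time_grade=0.07, intercept_sd=0.6, resid_sd=0.55),
        "naming": CognitiveTestConfig(
            "language", base=45.0, b_time_grade=-0.09,
            fc_links={"between_hubs_nohubs": 10.1}, intercept_sd=2.0, resid_sd=2.0,
        ),
        "fluency": CognitiveTestConfig("language", base=38.0, b_time=-0.55, intercept_sd=5.5, resid_sd=5.5),
        "tmt_a": CognitiveTestConfig(
            "attention_executive", base=45.0, fc_links={"within_ftpn": -2.8},
            intercept_sd=8.0, resid_sd=8.0, orientation=-1,
        ),
        "tmt_b": CognitiveTestConfig(
            "attention_executive", base=110.0, fc_links={"within_dmn": -25.9},
            intercept_sd=29.0, resid_sd=28.0, orientation=-1,
        ),
    }


def _metric_map(dmn, ftpn, hubs, nohubs, between) -> dict[str, float]:
    return {
        "within_dmn": dmn,
        "within_ftpn": ftpn,
        "within_hubs": hubs,
        "within_nohubs": nohubs,
        "between_hubs_nohubs": between,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs; the defaults are the emulated study conditions."""

    n_subjects: int = 28
    n_lgg: int = 11  # remainder are HGG
    n_left: int = 15  # remainder right-lateralized
    n_left_lgg: int = 7  # left-lateralized among LGG

    visits: tuple[float, ...] = DEFAULT_VISITS
    follow_up_keep_prob: float = 0.36  # expected total observations ~= 73
    guarantee_follow_up: bool = True  # every subject keeps >= 1 follow-up

    # time-series route
    n_regions: int = 60
    network_sizes: tuple[tuple[str, int], ...] = (
        ("Default", 12),
        ("FrontoParietal", 10),
        ("Visual", 19),
        ("SMhand", 19),
    )
    n_timepoints: int = 275
    tr_seconds: float = 2.6
    r_hub: float = 0.45
    r_nohub: float = 0.30
    r_between: float = 0.18
    d_hub_right: float = 0.008  # per month, right-lateralized hub drift
    d_hub_left: float = 0.0
    d_dmn_grade: float = 0.004  # extra DMN drift per month in LGG
    d_nohub_right: float = -0.006
    d_between_right: float = 0.004
    correlation_bound: float = 0.97

    # fast route: the normalized-profile linear model
    profile_mu: dict[str, float] = field(
        default_factory=lambda: _metric_map(1.30, 1.25, 1.20, 0.95, 0.92)
    )
    profile_slope_right: dict[str, float] = field(
        default_factory=lambda: _metric_map(0.006, 0.0, 0.005, -0.001, 0.0023)
    )
    profile_slope_left: dict[str, float] = field(
        default_factory=lambda: _metric_map(0.0, 0.0, 0.0, 0.0, 0.0)
    )
    profile_slope_grade: dict[str, float] = field(
        default_factory=lambda: _metric_map(0.004, 0.0, 0.0, 0.0, 0.0)
    )
    profile_intercept_sd: dict[str, float] = field(
        default_factory=lambda: _metric_map(0.10, 0.10, 0.10, 0.02, 0.01)
    )
    profile_resid_sd: dict[str, float] = field(
        default_factory=lambda: _metric_map(0.030, 0.030, 0.025, 0.005, 0.010)
    )

    # covariate distributions (Table-1-like)
    age_lgg: tuple[float, float] = (41.0, 15.0)
    age_hgg: tuple[float, float] = (54.0, 12.0)
    volume_lgg: tuple[float, float] = (13.7, 3.3)
    volume_hgg: tuple[float, float] = (40.3, 24.0)
    eor_lgg: tuple[float, float] = (91.8, 11.3)
    eor_hgg: tuple[float, float] = (96.7, 9.6)
    n_males_lgg: int = 9
    n_males_hgg: int = 13
    n_idh_lgg: int = 3
    n_idh_hgg: int = 3
    n_mgmt_lgg: int = 0
    n_mgmt_hgg: int = 6
    who_grades_lgg: tuple[int, ...] = (1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2)
    who_grades_hgg: tuple[int, ...] = (3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4)
    voxel_volume_mm3: float = 76.8  # 4 x 4 x 4.8 mm acquisition grid

    cognitive_tests: dict[str, CognitiveTestConfig] = field(default_factory=_default_tests)

    def expected_fixed_effects(self) -> dict[str, dict[str, float]]:
        """Implied mixed-model coefficients of the fast-route generator.

        With LEFT = 1 / LGG = 1 coding and reference group RIGHT/HGG:
        ``time`` is the right-group slope, ``time:lateralization`` the
        left-right slope contrast and ``time:grade`` the LGG-HGG contrast.
        """
        out = {}
        for m in PROFILE_METRICS:
            out[m] = {
                "time": self.profile_slope_right[m],
                "time:lateralization": self.profile_slope_left[m] - self.profile_slope_right[m],
                "time:grade": self.profile_slope_grade[m],
            }
        return out


def default_config(**overrides) -> SyntheticConfig:
    return dataclasses.replace(SyntheticConfig(), **overrides)


def null_config(**overrides) -> SyntheticConfig:
    """The no-effect generator: every time-related slope is zero."""
    zeros = _metric_map(0.0, 0.0, 0.0, 0.0, 0.0)
    cfg = SyntheticConfig(
        d_hub_right=0.0, d_hub_left=0.0, d_dmn_grade=0.0,
        d_nohub_right=0.0, d_between_right=0.0,
        profile_slope_right=dict(zeros), profile_slope_left=dict(zeros),
        profile_slope_grade=dict(zeros),
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class TruthRecord:
    """Everything needed to compute expected values of downstream fits."""

    config: SyntheticConfig
    expected_fc_effects: dict[str, dict[str, float]]
    cognitive_truth: dict[str, dict]
    session_correlations: dict[tuple[str, float], dict[str, float]] = field(default_factory=dict)
    psd_repairs: int = 0


# ---------------------------------------------------------------------------
# cohort structure


def synthetic_parcellation(config: SyntheticConfig) -> Parcellation:
    """Small parcellation with the same schema as the reference atlas."""
    rng = np.random.default_rng(12)  # fixed: atlas geometry is not a random draw per cohort
    rows = []
    rid = 0
    for net, size in config.network_sizes:
        for k in range(1, size + 1):
            rid += 1
            rows.append(
                {
                    "region_id": rid,
                    "region_name": f"{net}_{k:02d}",
                    "network": net,
                    "n_voxels": int(rng.integers(120, 400)),
                }
            )
    if rid != config.n_regions:
        raise ValueError("network_sizes must sum to n_regions")
    return parcellation_from_frame(pd.DataFrame(rows))


def _exact_binary(rng, n: int, n_pos: int, pos, neg) -> np.ndarray:
    vals = np.array([pos] * n_pos + [neg] * (n - n_pos), dtype=object)
    rng.shuffle(vals)
    return vals


def simulate_cohort(
    config: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw the cohort covariate table, the visit schedule and the truth.

    Group counts match the configured splits exactly; continuous
    covariates are drawn from the configured group distributions.  The
    same seed always yields identical tables.
    """
    if not (0 <= config.n_lgg <= config.n_subjects):
        raise ValueError("infeasible grade split")
    if not (0 <= config.n_left <= config.n_subjects):
        raise ValueError("infeasible lateralization split")
    n_hgg = config.n_subjects - config.n_lgg
    n_left_hgg = config.n_left - config.n_left_lgg
    if not (0 <= config.n_left_lgg <= config.n_lgg) or not (0 <= n_left_hgg <= n_hgg):
        raise ValueError("infeasible joint grade x lateralization split")
    if len(config.who_grades_lgg) != config.n_lgg or len(config.who_grades_hgg) != n_hgg:
        raise ValueError("who_grades lists must match group sizes")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10]))
    rows = []
    parc = synthetic_parcellation(config)
    sizes = parc.table.set_index("region_id")["n_voxels"]

    group_plan = [("LGG", config.n_lgg, config.n_left_lgg), ("HGG", n_hgg, n_left_hgg)]
    idx = 0
    for grade, n_g, n_left_g in group_plan:
        lat = _exact_binary(rng, n_g, n_left_g, "LEFT", "RIGHT")
        sex = _exact_binary(
            rng, n_g,
            config.n_males_lgg if grade == "LGG" else config.n_males_hgg, "M", "F",
        )
        idh = _exact_binary(
            rng, n_g, config.n_idh_lgg if grade == "LGG" else config.n_idh_hgg, 1, 0
        )
        mgmt = _exact_binary(
            rng, n_g, config.n_mgmt_lgg if grade == "LGG" else config.n_mgmt_hgg, 1, 0
        )
        who = np.array(config.who_grades_lgg if grade == "LGG" else config.who_grades_hgg)
        rng.shuffle(who)
        age_mu, age_sd = config.age_lgg if grade == "LGG" else config.age_hgg
        vol_mu, vol_sd = config.volume_lgg if grade == "LGG" else config.volume_hgg
        eor_mu, eor_sd = config.eor_lgg if grade == "LGG" else config.eor_hgg
        for j in range(n_g):
            idx += 1
            sid = f"sub-{idx:02d}"
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 85))
            vol = float(np.clip(rng.normal(vol_mu, vol_sd), 1.0, None))
            eor = float(np.clip(rng.normal(eor_mu, eor_sd), 40, 100))
            rows.append(
                {
                    "subject_id": sid,
                    "grade": grade,
                    "lateralization": lat[j],
                    "age": round(age, 1),
                    "sex": sex[j],
                    "tumor_volume": round(vol, 1),
                    "idh": int(idh[j]),
                    "methylation": int(mgmt[j]),
                    "who_grade": int(who[j]),
                    "eor": round(eor, 1),
                }
            )

    cohort = pd.DataFrame(rows).sample(frac=1.0, random_state=int(seed) % (2**31)).reset_index(drop=True)

    # per-subject tumor-overlap percentages from parcel-level tumor voxels
    pct_hubs, pct_nohubs = [], []
    for _, r in cohort.iterrows():
        n_tumor = int(round(r["tumor_volume"] * 1000.0 / config.voxel_volume_mm3))
        regions = rng.choice(parc.region_ids, size=4, replace=False)
        counts: dict[int, int] = {}
        remaining = n_tumor
        for rid in regions:
            if remaining <= 0:
                break
            take = int(min(remaining, 0.5 * sizes.loc[rid]))
            counts[int(rid)] = take
            remaining -= take
        ov = tumor_overlap(parc, counts)
        pct_hubs.append(ov.pct_hubs)
        pct_nohubs.append(ov.pct_nohubs)
    cohort["pct_overlap_hubs"] = np.round(pct_hubs, 3)
    cohort["pct_overlap_nohubs"] = np.round(pct_nohubs, 3)

    # visit schedule: baseline always observed, follow-ups thinned
    visit_rows = []
    for _, r in cohort.iterrows():
        follow = list(config.visits[1:])
        keep = rng.random(len(follow)) < config.follow_up_keep_prob
        if config.guarantee_follow_up and follow and not keep.any():
            keep[rng.integers(len(follow))] = True
        months = [config.visits[0]] + [m for m, k in zip(follow, keep) if k]
        for m in months:
            visit_rows.append({"subject_id": r["subject_id"], "months": float(m)})
    visits = pd.DataFrame(visit_rows)

    truth = TruthRecord(
        config=config,
        expected_fc_effects=config.expected_fixed_effects(),
        cognitive_truth={
            name: dataclasses.asdict(tc) for name, tc in config.cognitive_tests.items()
        },
    )
    return cohort, visits, truth


# ---------------------------------------------------------------------------
# time-series route


def _block_correlation(
    config: SyntheticConfig, parc: Parcellation, months: float, grade: str, lateral: str
) -> tuple[np.ndarray, bool]:
    """Target correlation matrix for one session; returns (C, repaired)."""
    n = parc.n_regions
    right = lateral == "RIGHT"
    lgg = grade == "LGG"

    r_hub = config.r_hub + months * (config.d_hub_right if right else config.d_hub_left)
    r_dmn = r_hub + months * (config.d_dmn_grade if lgg else 0.0)
    r_nohub = config.r_nohub + months * (config.d_nohub_right if right else 0.0)
    r_between = config.r_between + months * (config.d_between_right if right else 0.0)

    b = config.correlation_bound
    vals = np.clip([r_hub, r_dmn, r_nohub, r_between], -b, b)
    if not np.allclose(vals, [r_hub, r_dmn, r_nohub, r_between]):
        logger.warning("block correlation clipped to ±%.2f at %.1f months", b, months)
    r_hub, r_dmn, r_nohub, r_between = vals

    hub_idx = np.isin(parc.region_ids, parc.hub_region_ids)
    dmn_idx = np.isin(parc.region_ids, parc.regions_of("DMN"))
    C = np.full((n, n), r_between)
    C[np.ix_(hub_idx, hub_idx)] = r_hub
    C[np.ix_(dmn_idx, dmn_idx)] = r_dmn
    C[np.ix_(~hub_idx, ~hub_idx)] = r_nohub
    np.fill_diagonal(C, 1.0)

    repaired = False
    eigmin = np.linalg.eigvalsh(C)[0]
    if eigmin < -1e-10:
        w, v = np.linalg.eigh(C)
        w = np.clip(w, 1e-6, None)
        C = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        repaired = True
        logger.warning("correlation matrix repaired to nearest PSD at %.1f months", months)
    return C, repaired


def simulate_session(
    subject: pd.Series | dict,
    months: float,
    config: SyntheticConfig,
    truth: TruthRecord | None = None,
    *,
    seed: int,
    parc: Parcellation | None = None,
) -> SessionTimeSeries:
    """Draw one T x N BOLD-like session for a subject at a given visit.

    The draw is a zero-mean multivariate normal whose correlation matrix
    has hub/no-hub block values drifting with time x lateralization and
    time x grade.  The per-session seed should be derived deterministically
    from the cohort seed (the CLI and tests use
    ``SeedSequence([seed, subject_index, visit_index])``).
    """
    parc = parc if parc is not None else synthetic_parcellation(config)
    sub = dict(subject)
    C, repaired = _block_correlation(config, parc, months, sub["grade"], sub["lateralization"])
    if truth is not None:
        if repaired:
            truth.psd_repairs += 1
        hubs = np.isin(parc.region_ids, parc.hub_region_ids)
        dmn = np.isin(parc.region_ids, parc.regions_of("DMN"))
        truth.session_correlations[(sub["subject_id"], float(months))] = {
            "r_dmn": float(C[np.ix_(dmn, dmn)][0, 1]),
            "r_hub": float(C[np.ix_(hubs, hubs)][-1, 0]),
            "r_nohub": float(C[np.ix_(~hubs, ~hubs)][0, 1]),
            "r_between": float(C[hubs][:, ~hubs][0, 0]),
        }
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(parc.n_regions))
    data = rng.standard_normal((config.n_timepoints, parc.n_regions)) @ L.T
    return SessionTimeSeries(sub["subject_id"], float(months), data, list(parc.region_ids))


# ---------------------------------------------------------------------------
# fast route: profile tables straight from the linear model


def simulate_profiles_fast(
    config: SyntheticConfig, seed: int, cohort: pd.DataFrame | None = None,
    visits: pd.DataFrame | None = None, truth: TruthRecord | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Long-format profile table drawn directly on the profile scale.

    value = mu_m + subject intercept + months * slope_m(group) + noise,
    where slope_m(group) composes the right/left lateralization slopes
    and the LGG grade increment.  Returns (profiles_long, cohort, truth);
    the implied mixed-model coefficients are in
    ``truth.expected_fc_effects``.
    """
    if cohort is None or visits is None or truth is None:
        cohort, visits, truth = simulate_cohort(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x20]))
    info = cohort.set_index("subject_id")
    rows = []
    for sid in cohort["subject_id"]:
        sub = info.loc[sid]
        left = sub["lateralization"] == "LEFT"
        lgg = sub["grade"] == "LGG"
        months = visits.loc[visits["subject_id"] == sid, "months"].to_numpy()
        for m in PROFILE_METRICS:
            slope = (
                (config.profile_slope_left[m] if left else config.profile_slope_right[m])
                + (config.profile_slope_grade[m] if lgg else 0.0)
            )
            b_i = rng.normal(0.0, config.profile_intercept_sd[m])
            eps = rng.normal(0.0, config.profile_resid_sd[m], size=months.size)
            vals = config.profile_mu[m] + b_i + slope * months + eps
            for mo, v in zip(months, vals):
                rows.append({"subject_id": sid, "months": float(mo), "metric": m, "value": float(v)})
    profiles = pd.DataFrame(rows)
    return profiles, cohort, truth


# ---------------------------------------------------------------------------
# cognition


def simulate_cognition(
    profiles_long: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SyntheticConfig,
    seed: int,
) -> pd.DataFrame:
    """Cognitive scores linked to the FC profiles.

    score = base + subject intercept + b_time * months
          + b_time_grade * months * [LGG] + b_time_lat * months * [LEFT]
          + sum_m b_link(m) * metric_m * months + noise.

    Timed tests (TMT family) are generated with ``orientation = -1``
    conventions baked into their negative link coefficients: a positive
    FC-performance association shows up as a negative interaction on the
    time scale (lower completion time = better).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x30]))
    wide = profiles_long.pivot_table(
        index=["subject_id", "months"], columns="metric", values="value"
    ).reset_index()
    info = cohort.set_index("subject_id")
    rows = []
    for test, tc in config.cognitive_tests.items():
        icpt = {sid: rng.normal(0.0, tc.intercept_sd) for sid in cohort["subject_id"]}
        for _, r in wide.iterrows():
            sid = r["subject_id"]
            months = float(r["months"])
            sub = info.loc[sid]
            mu = tc.base + icpt[sid] + tc.b_time * months
            mu += tc.b_time_grade * months * (sub["grade"] == "LGG")
            mu += tc.b_time_lat * months * (sub["lateralization"] == "LEFT")
            missing = False
            for metric, b in tc.fc_links.items():
                v = r.get(metric, np.nan)
                if pd.isna(v):
                    missing = True
                    break
                mu += b * v * months
            if missing:
                logger.info("missing profile for %s at %.1f months: %s skipped", sid, months, test)
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "months": months,
                    "test": test,
                    "score": float(mu + rng.normal(0.0, tc.resid_sd)),
                }
            )
    return pd.DataFrame(rows)
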