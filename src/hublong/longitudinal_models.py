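"""Longitudinal linear mixed models linking FC profiles, tumor features
and cognition.

Three model families are fitted, all with a random intercept per subject
(REML) and the same nuisance covariates (age, sex, baseline tumor volume,
IDH mutation, MGMT methylation, WHO grade):

1. FC outcomes: each of the five spatial connectomic metrics regressed on
   time, time x tumor grade and time x tumor lateralization.
2. Cognitive outcomes: each neuropsychological score on the same terms.
3. FC -> cognition: each score on time plus four time x FC-metric
   interactions (within DMN, within FTPN, within no-hubs, between
   hubs-no-hubs).

Coding: grade LGG = 1 / HGG = 0 and lateralization LEFT = 1 / RIGHT = 0,
so a positive time x grade term means faster increase in LGG and a
positive time x lateralization term means faster increase with
left-lateralized tumors.  Wald tests use a t reference with residual
degrees of freedom; Benjamini-Hochberg FDR is applied per term within
each model family (the five FC models, or the models of one cognitive
domain).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spatial_profile import PROFILE_METRICS

logger = logging.getLogger(__name__)

__all__ = [
    "NUISANCE_COVARIATES",
    "COGNITIVE_DOMAINS",
    "FC_PREDICTOR_METRICS",
    "ModelSpec",
    "TermResult",
    "ModelFit",
    "bh_fdr",
    "cohens_d_from_t",
    "fit_lmm",
    "fc_outcome_models",
    "cognition_outcome_models",
    "fc_predicts_cognition_models",
    "fits_to_frame",
]

#: nuisance covariates entering every model (when present in the data)
NUISANCE_COVARIATES = ("age", "sex", "tumor_volume", "idh", "methylation", "who_grade")

#: neuropsychological test -> cognitive domain (the FDR families for
#: the cognition model tables)
COGNITIVE_DOMAINS = {
    "rey_word_list": "memory",
    "rey_figure": "memory",
    "digit_span": "memory",
    "corsi": "memory",
    "naming": "language",
    "fluency": "language",
    "tmt_a": "attention_executive",
    "tmt_b": "attention_executive",
}

#: the four FC metrics used as longitudinal predictors of cognition
FC_PREDICTOR_METRICS = ("within_dmn", "within_ftpn", "within_nohubs", "between_hubs_nohubs")

_GRADE_CODE = {"LGG": 1.0, "HGG": 0.0}
_LAT_CODE = {"LEFT": 1.0, "RIGHT": 0.0}
_SEX_CODE = {"M": 1.0, "F": 0.0}


@dataclass(frozen=True)
class ModelSpec:
    """One mixed model: outcome, fixed terms of interest, nuisance set."""

    outcome_name: str
    fixed_terms: tuple[str, ...]
    nuisance: tuple[str, ...] = NUISANCE_COVARIATES
    family: str = ""


@dataclass
class TermResult:
    beta: float
    se: float
    tval: float
    pval: float
    std_beta: float
    cohens_d: float
    qval: float = math.nan


@dataclass
class ModelFit:
    outcome_name: str
    terms: dict[str, TermResult]
    sigma2_random: float
    sigma2_resid: float
    n_obs: int
    n_subjects: int
    df_resid: int
    converged: bool
    degenerate: str = ""
    family: str = ""
    nuisance_used: tuple[str, ...] = field(default_factory=tuple)


def bh_fdr(pvals, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within each family.

    ``family_labels`` partitions the p-values into independent correction
    families; ``None`` treats all inputs as one family.  Output order
    matches input order; q >= p and q is monotone in p within a family.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        family_labels = np.zeros(p.size)
    fam = np.asarray(family_labels)
    if fam.size != p.size:
        raise ValueError("family_labels must match pvals in length")
    q = np.full(p.size, math.nan)
    for f in pd.unique(fam):
        idx = np.flatnonzero(fam == f)
        sub = p[idx]
        ok = ~np.isnan(sub)
        if not ok.any():
            continue
        ps = sub[ok]
        m = ps.size
        order = np.argsort(ps, kind="stable")
        ranked = ps[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest rank down
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(ranked, 1.0)
        out = np.full(sub.size, math.nan)
        out[ok] = qs
        q[idx] = out
    return q


def cohens_d_from_t(tval: float, df_resid: int) -> float:
    """Approximate Cohen's d attached to a fixed-effect Wald t."""
    if df_resid <= 0:
        return math.nan
    return 2.0 * tval / math.sqrt(df_resid)


# ---------------------------------------------------------------------------
# design construction


def _code_column(df: pd.DataFrame, col: str) -> pd.Series:
    s = df[col]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        for mapping in (_GRADE_CODE, _LAT_CODE, _SEX_CODE):
            if set(s.dropna().unique()) <= set(mapping):
                return s.map(mapping).astype(float)
        raise ValueError(f"cannot numerically code column {col!r}")
    return s.astype(float)


def _term_column(df: pd.DataFrame, term: str) -> pd.Series:
    if term == "time":
        return df["months"].astype(float)
    if term == "time:grade":
        return df["months"].astype(float) * _code_column(df, "grade")
    if term == "time:lateralization":
        return df["months"].astype(float) * _code_column(df, "lateralization")
    if term.startswith("time:fc:"):
        metric = term.removeprefix("time:fc:")
        if metric not in df.columns:
            raise ValueError(f"FC metric column {metric!r} missing from data")
        return df["months"].astype(float) * df[metric].astype(float)
    raise ValueError(f"unknown fixed term {term!r}")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.flatnonzero(diag < max(tol, 1e-10))]


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one linear mixed model with a per-subject random intercept.

    ``data`` is a wide frame with one row per subject-visit holding the
    outcome column, ``subject_id``, ``months``, the grouping covariates
    and any nuisance columns.  Rows with a missing outcome or predictor
    are dropped (unbalanced design).  Estimation is REML; per-term Wald
    tests use a t reference with residual df = n_obs - n_fixed.

    Degenerate data (constant outcome, exact linear outcome) short-circuit
    to a flagged least-squares fit rather than a failed variance
    optimisation.
    """
    nuisance = tuple(c for c in spec.nuisance if c in data.columns)
    design = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in spec.fixed_terms:
        design[term] = _term_column(data, term)
    for cov in nuisance:
        design[cov] = _code_column(data, cov)

    y = data[spec.outcome_name].astype(float)
    groups = data["subject_id"]
    keep = y.notna() & design.notna().all(axis=1)
    y, design, groups = y[keep], design[keep], groups[keep]

    n_obs = len(y)
    n_subjects = groups.nunique()
    if n_obs == 0:
        raise ValueError(f"{spec.outcome_name}: no complete observations")
    visits = groups.value_counts()
    if (visits >= 2).sum() < 2:
        raise ValueError(f"{spec.outcome_name}: need >= 2 subjects with >= 2 visits")

    # a rank-deficient design is an error when a term of interest is involved;
    # redundant nuisance covariates are dropped instead (small cohorts can
    # make binary covariates coincide by chance)
    while True:
        X = design.to_numpy(dtype=float)
        names = list(design.columns)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        bad = _collinear_columns(X, names)
        bad_terms = [b for b in bad if b in spec.fixed_terms]
        if bad_terms or not bad:
            raise ValueError(
                f"{spec.outcome_name}: rank-deficient design; collinear terms: "
                f"{bad_terms or bad}"
            )
        logger.warning(
            "%s: dropping collinear nuisance covariate(s) %s", spec.outcome_name, bad
        )
        design = design.drop(columns=bad)
        nuisance = tuple(c for c in nuisance if c not in bad)

    k = X.shape[1]
    df_resid = max(n_obs - k, 1)

    # degenerate short-circuits: constant or exactly linear outcome
    beta_ols, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    resid_ols = y.to_numpy() - X @ beta_ols
    y_scale = max(float(np.var(y)), 1.0)
    if float(resid_ols @ resid_ols) / n_obs < 1e-14 * y_scale:
        terms = {
            t: TermResult(float(beta_ols[names.index(t)]), 0.0, 0.0, 1.0, 0.0, 0.0)
            for t in spec.fixed_terms
        }
        for t, tr in terms.items():
            x = design[t].to_numpy()
            sy = float(np.std(y))
            tr.std_beta = tr.beta * float(np.std(x)) / sy if sy > 0 else 0.0
        return ModelFit(
            spec.outcome_name, terms, 0.0, 0.0, n_obs, n_subjects, df_resid,
            converged=True, degenerate="perfect_fit", family=spec.family,
            nuisance_used=nuisance,
        )

    # center/scale predictors for the variance optimisation (an exact linear
    # reparameterization: slopes and tests map back without approximation)
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0)
    scale = np.where(col_sd > 0, col_sd, 1.0)
    Xs = (X - np.where(col_sd > 0, col_mean, 0.0)) / scale
    Xs[:, names.index("Intercept")] = 1.0
    scale[names.index("Intercept")] = 1.0

    res = None
    caught: list[warnings.WarningMessage] = []
    for method in ("bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = sm.MixedLM(y.to_numpy(), Xs, groups=groups.to_numpy())
                res = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if res is None:
        raise ValueError(f"{spec.outcome_name}: variance optimisation failed for every optimizer")
    converged = bool(getattr(res, "converged", True)) and not any(
        "did not converge" in str(w.message).lower() for w in caught
    )

    params = np.asarray(res.fe_params) / scale
    bse = np.asarray(res.bse_fe) / scale
    sigma2_random = float(np.asarray(res.cov_re)[0, 0])
    sigma2_resid = float(res.scale)
    sy = float(np.std(y))

    terms: dict[str, TermResult] = {}
    for t in spec.fixed_terms:
        i = names.index(t)
        beta, se = float(params[i]), float(bse[i])
        tval = beta / se if se > 0 else 0.0
        pval = float(2 * stats.t.sf(abs(tval), df_resid))
        sx = float(np.std(design[t]))
        std_beta = beta * sx / sy if sy > 0 else 0.0
        terms[t] = TermResult(beta, se, tval, pval, std_beta, cohens_d_from_t(tval, df_resid))

    return ModelFit(
        spec.outcome_name, terms, sigma2_random, sigma2_resid, n_obs, n_subjects,
        df_resid, converged=converged, family=spec.family, nuisance_used=nuisance,
    )


# ---------------------------------------------------------------------------
# model families


def _merge_cohort(obs: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    cols = ["subject_id", "grade", "lateralization"] + [
        c for c in NUISANCE_COVARIATES if c in cohort.columns
    ]
    return obs.merge(cohort[cols], on="subject_id", how="left", validate="many_to_one")


def _apply_family_fdr(fits: list[ModelFit]) -> None:
    """BH q-values per fixed term, within each model family."""
    all_terms = sorted({t for f in fits for t in f.terms})
    for term in all_terms:
        entries = [(f, f.terms[term]) for f in fits if term in f.terms]
        fams = [f.family for f, _ in entries]
        ps = [tr.pval for _, tr in entries]
        qs = bh_fdr(ps, fams)
        for (_, tr), q in zip(entries, qs):
            tr.qval = float(q)


def fc_outcome_models(
    profiles_long: pd.DataFrame,
    cohort: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("time", "time:grade", "time:lateralization"),
) -> list[ModelFit]:
    """One mixed model per spatial connectomic metric.

    The FDR family for each term is the set of (up to five) FC models, so
    a q-value answers "does this term survive correction across the five
    connectomic responses".
    """
    fits = []
    metrics = [m for m in PROFILE_METRICS if m in set(profiles_long["metric"])]
    for metric in metrics:
        obs = profiles_long.loc[profiles_long["metric"] == metric, ["subject_id", "months", "value"]]
        obs = obs.rename(columns={"value": metric})
        data = _merge_cohort(obs, cohort)
        spec = ModelSpec(metric, fixed_terms, family="fc_profile")
        fits.append(fit_lmm(data, spec))
    _apply_family_fdr(fits)
    return fits


def cognition_outcome_models(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("time", "time:grade", "time:lateralization"),
    domains: dict[str, str] | None = None,
) -> list[ModelFit]:
    """One mixed model per neuropsychological test.

    FDR families are cognitive domains (memory, language,
    attention/executive), applied per term across the tests of a domain.
    """
    domains = COGNITIVE_DOMAINS if domains is None else domains
    fits = []
    for test in pd.unique(scores["test"]):
        obs = scores.loc[scores["test"] == test, ["subject_id", "months", "score"]]
        obs = obs.rename(columns={"score": test})
        data = _merge_cohort(obs, cohort)
        spec = ModelSpec(test, fixed_terms, family=domains.get(test, test))
        fits.append(fit_lmm(data, spec))
    _apply_family_fdr(fits)
    return fits


def fc_predicts_cognition_models(
    scores: pd.DataFrame,
    profiles_long: pd.DataFrame,
    cohort: pd.DataFrame,
    fc_metrics: tuple[str, ...] = FC_PREDICTOR_METRICS,
    domains: dict[str, str] | None = None,
) -> list[ModelFit]:
    """Per cognitive test: time plus four time x FC-metric interactions.

    FC metrics and scores are joined per subject-visit; visits lacking a
    profile contribute no rows.  FDR families are cognitive domains.
    """
    domains = COGNITIVE_DOMAINS if domains is None else domains
    wide = profiles_long.pivot_table(
        index=["subject_id", "months"], columns="metric", values="value"
    ).reset_index()
    missing = [m for m in fc_metrics if m not in wide.columns]
    if missing:
        raise ValueError(f"profile table lacks FC metric(s) {missing}")
    fixed_terms = ("time",) + tuple(f"time:fc:{m}" for m in fc_metrics)
    fits = []
    for test in pd.unique(scores["test"]):
        obs = scores.loc[scores["test"] == test, ["subject_id", "months", "score"]]
        obs = obs.rename(columns={"score": test})
        data = obs.merge(wide, on=["subject_id", "months"], how="inner")
        data = _merge_cohort(data, cohort)
        spec = ModelSpec(test, fixed_terms, family=domains.get(test, test))
        fits.append(fit_lmm(data, spec))
    _apply_family_fdr(fits)
    return fits


def fits_to_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Tidy per-term results table (one row per model x fixed term)."""
    rows = []
    for f in fits:
        for term, tr in f.terms.items():
            rows.append(
                {
                    "response": f.outcome_name,
                    "term": term,
                    "estimate": tr.beta,
                    "se": tr.se,
                    "t": tr.tval,
                    "p": tr.pval,
                    "std_beta": tr.std_beta,
                    "cohens_d": tr.cohens_d,
                    "q_fdr": tr.qval,
                    "sigma2_random": f.sigma2_random,
                    "n_obs": f.n_obs,
                    "n_subjects": f.n_subjects,
                    "converged": f.converged,
                    "degenerate": f.degenerate,
                    "family": f.family,
                }
            )
    return pd.DataFrame(rows)
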