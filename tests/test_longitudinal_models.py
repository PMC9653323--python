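import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hublong.longitudinal_models import (
    ModelSpec,
    bh_fdr,
    cognition_outcome_models,
    cohens_d_from_t,
    fc_outcome_models,
    fc_predicts_cognition_models,
    fit_lmm,
    fits_to_frame,
)
from hublong.synthetic_cohort import (
    CognitiveTestConfig,
    default_config,
    simulate_cognition,
    simulate_profiles_fast,
)

VISITS = (0.0, 2.0, 4.5, 7.5, 12.0)


def make_long(seed, icpt_sd=1.0, resid_sd=0.1, slope_lat=0.3, slope_time=0.05, n_sub=28):
    """Random-intercept data with a known time x lateralization effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sub):
        lat = "LEFT" if i < n_sub // 2 else "RIGHT"
        b = rng.normal(0, icpt_sd)
        for m in VISITS:
            y = 1.0 + b + slope_time * m + slope_lat * m * (lat == "LEFT")
            y += rng.normal(0, resid_sd)
            rows.append(dict(subject_id=f"s{i:02d}", months=float(m), lateralization=lat, y=y))
    return pd.DataFrame(rows)


SPEC_LAT = ModelSpec("y", ("time", "time:lateralization"), nuisance=())


def gls_oracle(df, icpt_sd, resid_sd):
    """Generalized least squares with known variance components."""
    X = np.column_stack(
        [np.ones(len(df)), df["months"], df["months"] * (df["lateralization"] == "LEFT")]
    )
    y = df["y"].to_numpy()
    n = len(df)
    V = resid_sd**2 * np.eye(n)
    for sid in df["subject_id"].unique():
        idx = np.flatnonzero((df["subject_id"] == sid).to_numpy())
        V[np.ix_(idx, idx)] += icpt_sd**2
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


class TestFitLmm:
    def test_noiseless_linear_data_recovered_exactly(self):
        rows = [
            dict(subject_id=f"s{i}", months=float(m), y=1.0 + 0.5 * m)
            for i in range(6)
            for m in VISITS
        ]
        fit = fit_lmm(pd.DataFrame(rows), ModelSpec("y", ("time",), nuisance=()))
        assert fit.degenerate == "perfect_fit"
        assert fit.terms["time"].beta == pytest.approx(0.5, abs=1e-9)
        assert fit.sigma2_random == pytest.approx(0.0)

    def test_interaction_recovered_within_wald_ci_and_matches_gls(self):
        df = make_long(0, icpt_sd=1.0, resid_sd=0.1, slope_lat=0.3)
        fit = fit_lmm(df, SPEC_LAT)
        tr = fit.terms["time:lateralization"]
        assert abs(tr.beta - 0.3) < 1.96 * tr.se
        beta_gls = gls_oracle(df, icpt_sd=1.0, resid_sd=0.1)
        assert tr.beta == pytest.approx(beta_gls[2], abs=0.5 * tr.se)

    def test_zero_between_subject_variance_matches_ols(self):
        df = make_long(2, icpt_sd=0.0, resid_sd=0.5)
        fit = fit_lmm(df, SPEC_LAT)
        X = np.column_stack(
            [np.ones(len(df)), df["months"], df["months"] * (df["lateralization"] == "LEFT")]
        )
        beta_ols, *_ = np.linalg.lstsq(X, df["y"], rcond=None)
        assert fit.terms["time"].beta == pytest.approx(beta_ols[1], abs=1e-6)
        assert fit.terms["time:lateralization"].beta == pytest.approx(beta_ols[2], abs=1e-6)

    def test_constant_outcome_flagged_degenerate(self):
        rows = [
            dict(subject_id=f"s{i}", months=float(m), y=3.0)
            for i in range(4)
            for m in VISITS
        ]
        fit = fit_lmm(pd.DataFrame(rows), ModelSpec("y", ("time",), nuisance=()))
        assert fit.degenerate == "perfect_fit"
        assert fit.terms["time"].beta == pytest.approx(0.0)
        assert fit.terms["time"].std_beta == 0.0

    def test_collinear_terms_named_in_error(self):
        df = make_long(0)
        df["lateralization"] = "LEFT"  # interaction now duplicates time
        with pytest.raises(ValueError, match="time:lateralization"):
            fit_lmm(df, SPEC_LAT)

    def test_missing_rows_dropped_not_imputed(self):
        df = make_long(1)
        df.loc[df.sample(frac=0.2, random_state=0).index, "y"] = np.nan
        fit = fit_lmm(df, SPEC_LAT)
        assert fit.n_obs == int(df["y"].notna().sum())

    def test_needs_repeated_measurements(self):
        df = make_long(0).groupby("subject_id").head(1)
        with pytest.raises(ValueError, match="2 visits"):
            fit_lmm(df, SPEC_LAT)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_two_tests_one_domain(self):
        q = bh_fdr([0.01, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.04])

    def test_permutation_invariant(self, rng):
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        np.testing.assert_allclose(q[perm], q_perm)

    def test_families_corrected_independently(self):
        p = [0.01, 0.02, 0.01, 0.02]
        fam = ["a", "a", "b", "b"]
        q = bh_fdr(p, fam)
        np.testing.assert_allclose(q[:2], bh_fdr([0.01, 0.02]))
        np.testing.assert_allclose(q[2:], bh_fdr([0.01, 0.02]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_statsmodels_reference(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 15))
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(size=30)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_empty_input(self):
        assert bh_fdr([]).size == 0


class TestEffectSizes:
    @pytest.mark.parametrize("t,df,want", [(0.0, 20, 0.0), (2.0, 16, 1.0)])
    def test_cohens_d_from_t(self, t, df, want):
        assert cohens_d_from_t(t, df) == pytest.approx(want)

    def test_nonpositive_df_undefined(self):
        assert np.isnan(cohens_d_from_t(1.0, 0))


class TestModelFamilies:
    def test_single_metric_family_q_equals_p(self):
        cfg = default_config()
        prof, cohort, _ = simulate_profiles_fast(cfg, 5)
        prof = prof[prof["metric"] == "within_dmn"]
        fits = fc_outcome_models(prof, cohort)
        assert len(fits) == 1
        for tr in fits[0].terms.values():
            assert tr.qval == pytest.approx(tr.pval)

    def test_fc_family_has_five_models_three_terms(self):
        prof, cohort, _ = simulate_profiles_fast(default_config(), 6)
        frame = fits_to_frame(fc_outcome_models(prof, cohort))
        assert frame["response"].nunique() == 5
        assert set(frame["term"]) == {"time", "time:grade", "time:lateralization"}
        assert (frame["q_fdr"] >= frame["p"] - 1e-12).all()

    def test_cognition_learning_effect_recovered(self):
        cfg = default_config()
        prof, cohort, _ = simulate_profiles_fast(cfg, 7)
        scores = simulate_cognition(prof, cohort, cfg, 7)
        fits = cognition_outcome_models(scores, cohort)
        rey = next(f for f in fits if f.outcome_name == "rey_figure")
        tr = rey.terms["time"]
        # generated with a +0.75/month learning slope
        assert abs(tr.beta - 0.75) < 3 * tr.se
        assert tr.beta > 0

    def test_constant_scores_flagged_degenerate(self):
        cfg = default_config()
        prof, cohort, _ = simulate_profiles_fast(cfg, 8)
        visits = prof[["subject_id", "months"]].drop_duplicates()
        scores = visits.assign(test="flat", score=10.0)
        fits = cognition_outcome_models(scores, cohort)
        assert fits[0].degenerate == "perfect_fit"
        assert fits[0].terms["time"].beta == pytest.approx(0.0)

    def test_fc_cognition_link_signs_recovered(self):
        """Positive DMN-digit span link and negative FTPN-TMT link."""
        cfg = default_config()
        est_dmn, est_tmt = [], []
        for r in range(10):
            prof, cohort, _ = simulate_profiles_fast(cfg, 900 + r)
            scores = simulate_cognition(prof, cohort, cfg, 900 + r)
            scores = scores[scores["test"].isin(["digit_span", "tmt_a"])]
            fits = fc_predicts_cognition_models(scores, prof, cohort)
            by_name = {f.outcome_name: f for f in fits}
            est_dmn.append(by_name["digit_span"].terms["time:fc:within_dmn"].beta)
            est_tmt.append(by_name["tmt_a"].terms["time:fc:within_ftpn"].beta)
        assert np.mean(est_dmn) > 0
        assert np.mean(est_tmt) < 0

    def test_zero_link_interactions_centered_on_zero(self):
        tests = {
            "probe": CognitiveTestConfig("memory", base=10.0, intercept_sd=1.0, resid_sd=1.0)
        }
        cfg = default_config(cognitive_tests=tests)
        est = []
        for r in range(25):
            prof, cohort, _ = simulate_profiles_fast(cfg, 3000 + r)
            scores = simulate_cognition(prof, cohort, cfg, 3000 + r)
            fits = fc_predicts_cognition_models(scores, prof, cohort)
            est.append(fits[0].terms["time:fc:within_dmn"].beta)
        est = np.array(est)
        assert abs(est.mean()) < 3 * est.std(ddof=1) / np.sqrt(len(est))

    def test_zero_effect_nuisance_barely_moves_estimates(self):
        """Dropping a covariate generated with no effect is inconsequential."""
        cfg = default_config()
        diffs, ses = [], []
        for r in range(12):
            prof, cohort, _ = simulate_profiles_fast(cfg, 5000 + r)
            prof = prof[prof["metric"] == "within_hubs"]
            full = fc_outcome_models(prof, cohort)[0]
            reduced = fc_outcome_models(prof, cohort.drop(columns="age"))[0]
            diffs.append(
                full.terms["time:lateralization"].beta
                - reduced.terms["time:lateralization"].beta
            )
            ses.append(full.terms["time:lateralization"].se)
        assert abs(np.mean(diffs)) < np.mean(ses) / np.sqrt(len(diffs))
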