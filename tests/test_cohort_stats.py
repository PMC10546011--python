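"""Fluency aggregation, chained-equation imputation, and severity models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _brute import normal_equations_ols
from sgdem.cohort_stats import (
    COHORT_COLUMNS,
    aggregate_fluency_z,
    fit_severity_model,
    impute_fluency,
    summarize_cohort,
)
from sgdem.errors import (
    CannotImputeError,
    CollinearPredictorsError,
    DegenerateFluencyError,
)
from sgdem.synthetic_data import (
    CohortGenParams,
    apply_missingness,
    generate_cohort,
)


def _tiny_cohort(sem, phon):
    n = len(sem)
    return pd.DataFrame(
        {"semantic_fluency": sem, "phonemic_fluency": phon},
        index=range(n),
    )


class TestFluencyAggregate:
    def test_hand_computed_z_sum(self):
        # sample SD of [8,10,12] and [5,7,9] is 2; third row is +1 SD on both
        c = _tiny_cohort([8, 10, 12], [5, 7, 9])
        z = aggregate_fluency_z(c)
        assert z.iloc[2] == pytest.approx(2.0)
        assert z.iloc[0] == pytest.approx(-2.0)

    def test_participant_at_both_means_scores_zero(self):
        c = _tiny_cohort([8, 10, 12], [5, 7, 9])
        assert aggregate_fluency_z(c).iloc[1] == pytest.approx(0.0)

    def test_opposite_deviations_cancel(self):
        c = _tiny_cohort([8, 10, 12], [9, 7, 5])
        assert aggregate_fluency_z(c).iloc[2] == pytest.approx(0.0)

    def test_zero_sd_is_degenerate(self):
        with pytest.raises(DegenerateFluencyError):
            aggregate_fluency_z(_tiny_cohort([7, 7, 7], [5, 6, 7]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            aggregate_fluency_z(_tiny_cohort([8, np.nan, 12], [5, 7, 9]))


class TestImputeFluency:
    def test_complete_cohort_returns_identical_copies(self, default_cohort):
        completed = impute_fluency(default_cohort, m=3, seed=9)
        assert len(completed) == 3
        for table in completed:
            pd.testing.assert_frame_equal(table, default_cohort.reset_index(drop=True))

    def test_bit_reproducible_from_seed(self, default_cohort):
        holey = apply_missingness(default_cohort, 0.25, seed=4)
        a = impute_fluency(holey, m=4, seed=77)
        b = impute_fluency(holey, m=4, seed=77)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = impute_fluency(holey, m=4, seed=78)
        assert not all(x.equals(y) for x, y in zip(a, c))

    def test_pmm_draws_come_from_observed_values(self, default_cohort):
        holey = apply_missingness(default_cohort, 0.3, seed=5)
        for table in impute_fluency(holey, m=2, seed=1):
            for col in ("semantic_fluency", "phonemic_fluency"):
                mask = holey[col].isna().to_numpy()
                observed = set(holey[col].dropna())
                assert set(table.loc[mask, col]) <= observed

    def test_observed_cells_never_touched(self, default_cohort):
        holey = apply_missingness(default_cohort, 0.25, seed=6)
        for table in impute_fluency(holey, m=2, seed=2):
            for col in ("semantic_fluency", "phonemic_fluency"):
                obs = holey[col].notna()
                assert (table.loc[obs, col] == holey.loc[obs, col]).all()

    def test_fully_missing_variable_cannot_be_imputed(self, default_cohort):
        broken = default_cohort.copy()
        broken["semantic_fluency"] = np.nan
        with pytest.raises(CannotImputeError):
            impute_fluency(broken, m=2, seed=0)

    def test_fewer_than_three_observed_cannot_be_imputed(self, default_cohort):
        broken = default_cohort.copy()
        broken.loc[broken.index[2:], "phonemic_fluency"] = np.nan
        with pytest.raises(CannotImputeError):
            impute_fluency(broken, m=2, seed=0)

    def test_pooled_estimates_track_full_data_estimates(self):
        """MCAR deletion then MICE: pooled slopes sit inside the
        Monte-Carlo band of the full-data slopes over 200 replicates."""
        full, pooled = [], []
        for rep in range(200):
            cohort, _ = generate_cohort(CohortGenParams(n=128, seed=3000 + rep))
            full.append(
                fit_severity_model([cohort], "mmse", "lcc")
                .predictors["mean_lcc"].estimate
            )
            holey = apply_missingness(cohort, 0.25, seed=rep)
            completed = impute_fluency(holey, m=5, seed=rep)
            pooled.append(
                fit_severity_model(completed, "mmse", "lcc")
                .predictors["mean_lcc"].estimate
            )
        lo, hi = np.quantile(full, [0.025, 0.975])
        assert lo < np.mean(pooled) < hi


class TestSeverityModel:
    def test_zero_noise_recovers_generating_coefficients(self):
        params = CohortGenParams(
            n=60, seed=8, noise_sd={"mmse": 0.0, "mdrs": 0.0, "bds": 0.0}
        )
        cohort, _ = generate_cohort(params)
        res = fit_severity_model([cohort], "mmse", "lcc")
        beta = params.coefficients["mmse"]
        names = ["intercept", "hdrs", "onset_age", "education", "fluency_z", "mean_lcc"]
        for b, name in zip(beta, names):
            assert res.predictors[name].estimate == pytest.approx(b, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_outcome_gives_zero_slopes_and_r2(self, default_cohort):
        c = default_cohort.copy()
        c["mmse"] = 21.0
        res = fit_severity_model([c], "mmse", "lcc")
        for name, s in res.predictors.items():
            if name != "intercept":
                assert s.estimate == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            cohort, _ = generate_cohort(
                CohortGenParams(n=int(rng.integers(20, 50)), seed=int(rng.integers(1e6)))
            )
            res = fit_severity_model([cohort], "mdrs", "lsc")
            sub = cohort.copy()
            sub["fluency_z"] = aggregate_fluency_z(sub)
            X = np.column_stack(
                [
                    np.ones(len(sub)),
                    sub[["hdrs", "onset_age", "education", "fluency_z", "mean_lsc"]],
                ]
            )
            beta, se, r2, f = normal_equations_ols(X, sub["mdrs"].to_numpy())
            got = [s.estimate for s in res.predictors.values()]
            np.testing.assert_allclose(got, beta, rtol=1e-8)
            np.testing.assert_allclose(
                [s.se for s in res.predictors.values()], se, rtol=1e-8
            )
            assert res.r_squared == pytest.approx(r2, rel=1e-8)
            assert res.f_stat == pytest.approx(f, rel=1e-8)

    def test_ci_matches_t_critical_times_se(self, default_cohort):
        from scipy import stats

        res = fit_severity_model([default_cohort], "mmse", "lcc")
        tcrit = stats.t.ppf(0.975, res.df_resid)
        for s in res.predictors.values():
            assert s.ci95_low == pytest.approx(s.estimate - tcrit * s.se)
            assert s.ci95_high == pytest.approx(s.estimate + tcrit * s.se)

    def test_rubin_with_m1_equals_single_fit(self, default_cohort):
        single = fit_severity_model([default_cohort], "bds", "lsc")
        pooled = fit_severity_model([default_cohort.copy()], "bds", "lsc")
        for name in single.predictors:
            a, b = single.predictors[name], pooled.predictors[name]
            assert (a.estimate, a.se, a.t, a.p) == (b.estimate, b.se, b.t, b.p)
        assert single.df_resid == len(default_cohort) - 6

    def test_pooled_se_at_least_mean_within_se(self, default_cohort):
        """Between-imputation variance can only widen pooled SEs."""
        holey = apply_missingness(default_cohort, 0.25, seed=3)
        completed = impute_fluency(holey, m=5, seed=21)
        pooled = fit_severity_model(completed, "mmse", "lcc")
        singles = [
            fit_severity_model([t], "mmse", "lcc") for t in completed
        ]
        for name, s in pooled.predictors.items():
            mean_within_var = np.mean(
                [f.predictors[name].se ** 2 for f in singles]
            )
            assert s.se ** 2 >= mean_within_var - 1e-12

    def test_outcome_missingness_uses_complete_cases(self, default_cohort):
        c = default_cohort.copy()
        c.loc[c.index[:40], "mdrs"] = np.nan
        res = fit_severity_model([c], "mdrs", "lcc")
        assert res.n_used == len(c) - 40
        assert res.df_resid == res.n_used - 6

    def test_collinear_predictors_are_named(self, default_cohort):
        c = default_cohort.copy()
        c["mean_lcc"] = 2.0 * c["education"]  # exact linear dependence
        with pytest.raises(CollinearPredictorsError) as exc:
            fit_severity_model([c], "mmse", "lcc")
        assert {"education", "mean_lcc"} <= set(exc.value.columns)

    def test_r2_invariant_to_predictor_rescaling(self, default_cohort):
        res = fit_severity_model([default_cohort], "mmse", "lcc")
        scaled = default_cohort.copy()
        scaled["mean_lcc"] = scaled["mean_lcc"] * 10.0
        res2 = fit_severity_model([scaled], "mmse", "lcc")
        assert res2.r_squared == pytest.approx(res.r_squared, rel=1e-10)
        assert res2.predictors["mean_lcc"].estimate == pytest.approx(
            res.predictors["mean_lcc"].estimate / 10.0, rel=1e-8
        )


class TestSummarize:
    def test_hand_computed_summary(self):
        c = pd.DataFrame(
            {col: [np.nan] * 3 for col in COHORT_COLUMNS if col != "participant_id"}
        )
        c["participant_id"] = ["a", "b", "c"]
        c["age"] = [1.0, 2.0, 3.0]
        out = summarize_cohort(c)
        row = out.loc["age"]
        assert (row["mean"], row["sd"], row["min"], row["max"]) == (2, 1, 1, 3)
        assert out.loc["mmse", "n_missing"] == 3

    def test_single_record_has_undefined_sd(self):
        c = pd.DataFrame({"participant_id": ["a"], "age": [70.0]})
        out = summarize_cohort(c)
        assert np.isnan(out.loc["age", "sd"])
        assert out.loc["age", "min"] == out.loc["age", "max"] == 70.0

    def test_generator_means_within_three_se(self):
        """Large synthetic cohort reproduces its own generating means."""
        from sgdem.synthetic_data import COHORT_DEFAULTS

        cohort, _ = generate_cohort(CohortGenParams(n=500, seed=77))
        out = summarize_cohort(cohort)
        for col in ("age", "education", "hdrs", "semantic_fluency"):
            mean, sd, lo, hi = COHORT_DEFAULTS[col]
            from scipy import stats as spstats

            a, b = (lo - mean) / sd, (hi - mean) / sd
            expect = spstats.truncnorm.mean(a, b, loc=mean, scale=sd)
            se = out.loc[col, "sd"] / np.sqrt(500)
            assert abs(out.loc[col, "mean"] - expect) < 3 * se

    def test_cell_and_participant_missing_counts_both_reported(self, default_cohort):
        holey = apply_missingness(default_cohort, 0.25, seed=9)
        out = summarize_cohort(holey)
        cells = out.attrs["fluency_missing_cells"]
        people = out.attrs["fluency_missing_participants"]
        assert cells == holey[["semantic_fluency", "phonemic_fluency"]].isna().sum().sum()
        assert people <= cells <= 2 * people
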