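"""Cohort-level statistics: fluency aggregation, imputation, regressions.

The analysis cohort is a pandas DataFrame with one row per participant and
the columns

    participant_id, age, education, onset_age, mmse, mdrs, bds, hdrs,
    semantic_fluency, phonemic_fluency, mean_lcc, mean_lsc

(empty cell = missing).  Severity outcomes are MMSE (0-30), MDRS (0-144)
and BDS (0-28, higher = worse everyday functioning); HDRS (depression) and
age of dementia onset enter every model as controls.

Pipeline per outcome x connectedness measure:

1. missing fluency counts are multiply imputed by chained equations with
   predictive-mean matching (m completed tables);
2. within each completed table the aggregate verbal-fluency score is the
   sum of the two sample z-scores;
3. OLS of the outcome on {HDRS, onset age, education, fluency aggregate,
   mean LCC or mean LSC} over complete cases for the outcome;
4. estimates/SEs pooled across imputations by Rubin's rules with the
   Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from sgdem.errors import (
    CannotImputeError,
    CollinearPredictorsError,
    DegenerateFluencyError,
)

#: canonical cohort CSV column order
COHORT_COLUMNS = [
    "participant_id",
    "age",
    "education",
    "onset_age",
    "mmse",
    "mdrs",
    "bds",
    "hdrs",
    "semantic_fluency",
    "phonemic_fluency",
    "mean_lcc",
    "mean_lsc",
]

FLUENCY_COLUMNS = ["semantic_fluency", "phonemic_fluency"]
OUTCOMES = ["mmse", "mdrs", "bds"]
MEASURE_COLUMN = {"lcc": "mean_lcc", "lsc": "mean_lsc"}

#: predictors of every severity model, in reporting order (measure appended)
CONTROL_PREDICTORS = ["hdrs", "onset_age", "education", "fluency_z"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


# --- fluency aggregate ----------------------------------------------------


def aggregate_fluency_z(cohort: pd.DataFrame) -> pd.Series:
    """Aggregate verbal-fluency score: z(semantic) + z(phonemic).

    z-scores use the analysis sample's own mean and SD (ddof=1).  All
    fluency values must be present (call after imputation).
    """
    z_total = pd.Series(0.0, index=cohort.index)
    for col in FLUENCY_COLUMNS:
        x = cohort[col]
        if x.isna().any():
            raise ValueError(f"{col} has missing values; impute first")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateFluencyError(f"{col} has zero sample SD")
        z_total = z_total + (x - x.mean()) / sd
    return z_total


# --- chained-equation imputation (predictive-mean matching) ---------------


def _pmm_impute_once(
    df: pd.DataFrame,
    miss_mask: dict[str, np.ndarray],
    predictors: dict[str, list[str]],
    rng: np.random.Generator,
    n_iter: int,
    donor_pool: int,
    engine: str,
) -> pd.DataFrame:
    """One chained-equations chain; returns a completed copy of ``df``."""
    work = df.copy()
    # initialize missing cells with random draws from the observed values
    for var, mask in miss_mask.items():
        obs_vals = df.loc[~mask, var].to_numpy(float)
        work.loc[mask, var] = rng.choice(obs_vals, size=int(mask.sum()))

    for _ in range(n_iter):
        for var, mask in miss_mask.items():
            if not mask.any():
                continue
            X = np.column_stack(
                [np.ones(len(work))]
                + [work[p].to_numpy(float) for p in predictors[var]]
            )
            y = work[var].to_numpy(float)
            X_obs, y_obs = X[~mask], y[~mask]
            n_obs, k = X_obs.shape
            beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
            resid = y_obs - X_obs @ beta_hat
            df_resid = max(n_obs - k, 1)
            # proper imputation: draw sigma^2 and beta from their posterior
            sigma2 = resid @ resid / rng.chisquare(df_resid)
            xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
            beta_star = rng.multivariate_normal(
                beta_hat, sigma2 * xtx_inv, method="svd"
            )
            yhat_obs = X_obs @ beta_hat
            yhat_mis = X[mask] @ beta_star
            # type-1 PMM: match each missing case to its nearest observed
            # predictions and copy a random donor's observed value
            filled = np.empty(len(yhat_mis))
            for i, ym in enumerate(yhat_mis):
                d = np.abs(yhat_obs - ym)
                pool = np.argsort(d, kind="stable")[: min(donor_pool, len(d))]
                donor = rng.choice(pool)
                if engine == "pmm":
                    filled[i] = y_obs[donor]
                else:  # normal-model draw
                    filled[i] = ym + rng.normal(0.0, np.sqrt(sigma2))
            work.loc[mask, var] = filled
    return work


def impute_fluency(
    cohort: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    n_iter: int = 10,
    donor_pool: int = 5,
    engine: str = "pmm",
) -> list[pd.DataFrame]:
    """Multiply impute missing fluency counts by chained equations.

    Each incomplete fluency variable is iteratively regressed on the other
    analysis variables (the fully observed numeric covariates plus the
    other fluency variable at its current working values) over originally
    observed cases, with regression parameters drawn from their posterior;
    imputations are drawn by predictive-mean matching with a donor pool of
    ``donor_pool`` (``engine="norm"`` draws from the normal model
    instead).  ``n_iter`` chained sweeps per chain, ``m`` independent
    chains seeded from ``seed`` — the output is bit-reproducible.

    Returns ``m`` completed copies; with no missing data, ``m`` identical
    copies of the input.

    Raises
    ------
    CannotImputeError
        If a fluency variable is entirely missing or has fewer than 3
        observed values.
    """
    if engine not in {"pmm", "norm"}:
        raise ValueError("engine must be 'pmm' or 'norm'")
    cohort = cohort.reset_index(drop=True)
    miss_mask = {
        var: cohort[var].isna().to_numpy() for var in FLUENCY_COLUMNS
    }
    for var, mask in miss_mask.items():
        n_obs = int((~mask).sum())
        if n_obs == 0:
            raise CannotImputeError(f"{var} is entirely missing")
        if n_obs < 3:
            raise CannotImputeError(
                f"{var} has only {n_obs} observed values (< 3)"
            )

    if not any(mask.any() for mask in miss_mask.values()):
        return [cohort.copy() for _ in range(m)]

    numeric = [c for c in COHORT_COLUMNS if c != "participant_id" and c in cohort.columns]
    complete_cols = [
        c
        for c in numeric
        if c not in FLUENCY_COLUMNS and not cohort[c].isna().any()
    ]
    predictors = {
        "semantic_fluency": complete_cols + ["phonemic_fluency"],
        "phonemic_fluency": complete_cols + ["semantic_fluency"],
    }

    root = np.random.default_rng(seed)
    chains = root.spawn(m)
    return [
        _pmm_impute_once(
            cohort, miss_mask, predictors, rng, n_iter, donor_pool, engine
        )
        for rng in chains
    ]


# --- regression -----------------------------------------------------------


@dataclass
class PredictorStats:
    estimate: float
    se: float
    ci95_low: float
    ci95_high: float
    t: float
    p: float
    df: float


@dataclass
class RegressionResult:
    """Pooled OLS summary for one outcome x connectedness measure."""

    outcome: str
    connectedness_measure: str
    predictors: dict[str, PredictorStats]
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    n_used: int
    pooled_over_m: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": self.outcome,
                "measure": self.connectedness_measure,
                "predictor": name,
                "estimate": s.estimate,
                "se": s.se,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "t": s.t,
                "p": s.p,
            }
            for name, s in self.predictors.items()
        ]
        df = pd.DataFrame(rows)
        df["r_squared"] = self.r_squared
        df["f_stat"] = self.f_stat
        df["df_model"] = self.df_model
        df["df_resid"] = self.df_resid
        df["n_used"] = self.n_used
        df["m"] = self.pooled_over_m
        return df


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        bad = []
        for j, name in enumerate(X.columns):
            others = np.delete(mat, j, axis=1)
            coef, res, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
            resid = mat[:, j] - others @ coef
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(mat[:, j]).max())):
                bad.append(str(name))
        raise CollinearPredictorsError(bad or list(map(str, X.columns)))


def _barnard_rubin_df(lam: float, m: int, nu_com: float) -> float:
    """Barnard-Rubin adjusted degrees of freedom for a pooled estimate."""
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
    if lam <= 0:
        return nu_com
    nu_old = (m - 1) / lam**2
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def fit_severity_model(
    completed: list[pd.DataFrame],
    outcome: str,
    measure: str,
) -> RegressionResult:
    """Fit (and pool) the severity regression over completed cohort tables.

    Per completed table: restrict to complete cases for the outcome,
    compute the fluency aggregate z within that analysis set, and fit OLS
    of the outcome on an intercept, HDRS, onset age, education, the
    fluency aggregate, and the chosen connectedness grand mean.  With
    ``m > 1`` tables, estimates and SEs are combined by Rubin's rules;
    R^2 and the overall F are averaged across completed tables (exact for
    ``m = 1``).

    Raises
    ------
    CollinearPredictorsError
        If the design matrix is rank deficient (names the columns).
    """
    if measure not in MEASURE_COLUMN:
        raise ValueError(f"measure must be one of {sorted(MEASURE_COLUMN)}")
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    meas_col = MEASURE_COLUMN[measure]
    m = len(completed)

    names = ["intercept"] + CONTROL_PREDICTORS + [meas_col]
    params = np.empty((m, len(names)))
    variances = np.empty((m, len(names)))
    r2s = np.empty(m)
    fs = np.empty(m)
    n_used = df_resid = 0

    for i, table in enumerate(completed):
        sub = table.loc[table[outcome].notna()].copy()
        needed = ["hdrs", "onset_age", "education", meas_col]
        sub = sub.loc[sub[needed].notna().all(axis=1)]
        n_used = len(sub)
        if n_used < len(names) + 2:
            raise ValueError(
                f"only {n_used} complete cases for {outcome}; need at least "
                f"{len(names) + 2}"
            )
        sub["fluency_z"] = aggregate_fluency_z(sub)
        X = sub[CONTROL_PREDICTORS + [meas_col]].astype(float)
        X = sm.add_constant(X, prepend=True)
        _check_rank(X)
        fit = sm.OLS(sub[outcome].astype(float), X).fit()
        params[i] = fit.params.to_numpy()
        variances[i] = fit.bse.to_numpy() ** 2
        # constant outcome: zero total variance explained, not NaN
        r2s[i] = fit.rsquared if np.isfinite(fit.rsquared) else 0.0
        fs[i] = fit.fvalue if np.isfinite(fit.fvalue) else 0.0
        df_resid = int(fit.df_resid)

    qbar = params.mean(axis=0)
    wbar = variances.mean(axis=0)
    if m > 1:
        b = params.var(axis=0, ddof=1)
        total = wbar + (1 + 1 / m) * b
        lam = np.where(total > 0, (1 + 1 / m) * b / total, 0.0)
        dfs = np.array(
            [_barnard_rubin_df(l, m, df_resid) for l in lam]
        )
    else:
        total = wbar
        dfs = np.full(len(names), float(df_resid))

    se = np.sqrt(total)
    tvals = np.divide(qbar, se, out=np.zeros_like(qbar), where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)
    tcrit = stats.t.ppf(0.975, dfs)

    predictors = {
        name: PredictorStats(
            estimate=float(qbar[j]),
            se=float(se[j]),
            ci95_low=float(qbar[j] - tcrit[j] * se[j]),
            ci95_high=float(qbar[j] + tcrit[j] * se[j]),
            t=float(tvals[j]),
            p=float(pvals[j]),
            df=float(dfs[j]),
        )
        for j, name in enumerate(names)
    }
    return RegressionResult(
        outcome=outcome,
        connectedness_measure=measure,
        predictors=predictors,
        r_squared=float(r2s.mean()),
        f_stat=float(fs.mean()),
        df_model=len(names) - 1,
        df_resid=df_resid,
        n_used=n_used,
        pooled_over_m=m,
    )


def fit_all_models(
    completed: list[pd.DataFrame],
    outcomes: list[str] = OUTCOMES,
    measures: tuple[str, ...] = ("lcc", "lsc"),
) -> pd.DataFrame:
    """All outcome x measure regressions stacked into one long table."""
    frames = [
        fit_severity_model(completed, outcome, measure).to_frame()
        for measure in measures
        for outcome in outcomes
    ]
    return pd.concat(frames, ignore_index=True)


# --- descriptives ---------------------------------------------------------

#: descriptive-table row order (demographics, severity, language measures)
SUMMARY_ORDER = [
    "age",
    "education",
    "onset_age",
    "mmse",
    "mdrs",
    "bds",
    "hdrs",
    "semantic_fluency",
    "phonemic_fluency",
    "mean_lcc",
    "mean_lsc",
]


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (ddof=1), min-max and missing count per measure.

    Also reports participant-level fluency missingness (rows missing at
    least one fluency value) alongside the per-cell counts, since the two
    summaries differ whenever both cells of one participant are missing.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for col in SUMMARY_ORDER:
        if col not in cohort.columns:
            continue
        x = cohort[col].astype(float)
        obs = x.dropna()
        rows.append(
            {
                "measure": col,
                "mean": obs.mean() if len(obs) else np.nan,
                "sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
                "min": obs.min() if len(obs) else np.nan,
                "max": obs.max() if len(obs) else np.nan,
                "n_missing": int(x.isna().sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("measure")
    out.attrs["n_participants"] = len(cohort)
    fluency = [c for c in FLUENCY_COLUMNS if c in cohort.columns]
    if fluency:
        out.attrs["fluency_missing_cells"] = int(
            cohort[fluency].isna().to_numpy().sum()
        )
        out.attrs["fluency_missing_participants"] = int(
            cohort[fluency].isna().any(axis=1).sum()
        )
    return out
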