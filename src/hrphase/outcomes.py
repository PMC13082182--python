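"""Disease-focused outcome models.

Covers type 2 diabetes case definition by unlimited-depth descendant
closure of a single concept, HbA1c processing (range filter, maximum
before the end of wearable monitoring, >5.6% elevated flag), logistic
risk models for binary outcomes, sex-stratified Cox proportional
hazards on the age scale, and standard two-group comparisons (Welch's
t or Mann-Whitney U with Cohen's d).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import pingouin as pg
from scipy import stats

from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from .phewas import ConditionOntology, _fit_logit
from .results import AssociationResult, GroupComparison

__all__ = [
    "flag_t2dm",
    "max_hba1c_before_end",
    "logistic_risk",
    "cox_age_at_diagnosis",
    "compare_groups",
    "empirical_logit_by_decile",
]

LOGISTIC_COVARIATES = ["weekly_steps", "age", "y_chromosome",
                       "pc1", "pc2", "pc3", "pc4", "pc5"]
COX_COVARIATES = ["weekly_steps", "pc1", "pc2", "pc3", "pc4", "pc5"]


def flag_t2dm(occurrences: pd.DataFrame, ontology: ConditionOntology,
              concept_id, participant_ids: np.ndarray | pd.Series) -> pd.Series:
    """Binary indicator: any occurrence of the concept or ANY descendant.

    Uses unlimited-depth closure, unlike the PheWAS definition which is
    bounded at two degrees.
    """
    members = ontology.descendants(concept_id, max_depth=None)
    cases = set(occurrences.loc[occurrences["concept_id"].isin(members),
                                "participant_id"])
    pids = pd.Index(np.asarray(participant_ids), name="participant_id")
    return pd.Series(pids.isin(cases).astype(int), index=pids, name="t2dm")


def max_hba1c_before_end(labs: pd.DataFrame, monitoring_end: pd.Series,
                         bounds: tuple[float, float] = (1.0, 30.0),
                         elevated_threshold: float = 5.6) -> pd.DataFrame:
    """Per-participant maximum HbA1c strictly before monitoring end.

    Measurements outside ``bounds`` (inclusive) are removed first; then
    only measurements dated strictly before each participant's
    monitoring end qualify.  Participants with no qualifying
    measurement are absent from the output (missing, excluded from
    HbA1c models).  ``elevated`` is strict: value > threshold.

    Parameters
    ----------
    labs : columns participant_id, date, hba1c_pct.
    monitoring_end : Series of end timestamps indexed by participant_id.
    """
    lo, hi = bounds
    df = labs.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[(df["hba1c_pct"] >= lo) & (df["hba1c_pct"] <= hi)]
    end = monitoring_end.reindex(df["participant_id"]).to_numpy()
    df = df[df["date"].to_numpy() < end]
    if df.empty:
        return pd.DataFrame(columns=["max_hba1c", "elevated"])
    out = df.groupby("participant_id")["hba1c_pct"].max().to_frame("max_hba1c")
    out["elevated"] = out["max_hba1c"] > elevated_threshold
    return out


def logistic_risk(cohort: pd.DataFrame, outcome: pd.Series, exposure: str,
                  age_col: str = "age", cov_type: str = "HC1",
                  m_tests: int = 1) -> AssociationResult:
    """Logistic model of a binary outcome on one exposure plus covariates.

    Exposure is a cohort column (phase in hours, or an SNV dosage);
    covariates are weekly steps, age (``age_col`` selects study-end vs
    monitoring-end age), Y-chromosome presence and PC1-5.  Returns the
    log-odds per unit exposure with robust SE and 95% CI.
    """
    df = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    df = df.join(outcome.rename("_outcome"), how="inner")
    df = df.dropna(subset=["_outcome", exposure])
    y = df["_outcome"].astype(float).to_numpy()
    n = len(df)
    if n == 0 or len(np.unique(y)) < 2:
        return AssociationResult(exposure, np.nan, np.nan, np.nan, np.nan, n,
                                 converged=False, flag="constant_outcome")
    covs = [c for c in LOGISTIC_COVARIATES if c != "age"]
    if age_col in df.columns:
        covs.append(age_col)
    covs = [c for c in covs if c != exposure and c in df.columns]
    X = sm.add_constant(df[[exposure] + covs].astype(float))
    fit, flag = _fit_logit(y, X, cov_type=cov_type)
    if fit is None:
        return AssociationResult(exposure, np.nan, np.nan, np.nan, np.nan, n,
                                 converged=False, flag=flag)
    beta = float(fit.params[exposure])
    p = float(fit.pvalues[exposure])
    ci = fit.conf_int().loc[exposure]
    return AssociationResult(
        target=exposure, beta=beta, se=float(fit.bse[exposure]), p=p,
        p_adjusted=min(1.0, p * m_tests), n=n,
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        converged=flag == "", flag=flag)


def build_survival_records(cohort: pd.DataFrame, t2dm_flags: pd.Series,
                           occurrences: pd.DataFrame,
                           ontology: ConditionOntology, concept_id,
                           age_at_censor: str = "age") -> pd.DataFrame:
    """Assemble SurvivalRecords: event age or censoring age per participant.

    Event age is the earliest occurrence of the concept or any
    descendant; non-events are right-censored at ``age_at_censor``
    (the lesser of age at death or study end, already folded into that
    column).
    """
    members = ontology.descendants(concept_id, max_depth=None)
    occ = occurrences[occurrences["concept_id"].isin(members)]
    first_dx = occ.groupby("participant_id")["age_at_occurrence"].min()
    df = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort.copy()
    df = df.join(t2dm_flags.rename("event"), how="left")
    df["event"] = df["event"].fillna(0).astype(bool)
    df["age_at_event_or_censor"] = df[age_at_censor].astype(float)
    dx = first_dx.reindex(df.index)
    df.loc[df["event"] & dx.notna(), "age_at_event_or_censor"] = dx[df["event"] & dx.notna()]
    return df


def cox_age_at_diagnosis(records: pd.DataFrame, exposure: str,
                         duration_col: str = "age_at_event_or_censor",
                         event_col: str = "event",
                         strata: str | None = "y_chromosome",
                         covariates: list[str] | None = None,
                         check_ph: bool = True) -> dict:
    """Sex-stratified Cox model of age at diagnosis.

    Partial likelihood on the age scale with strata on Y-chromosome
    presence; covariates are the exposure, weekly steps and PC1-5.
    Returns the hazard ratio per unit exposure with 95% CI and a
    scaled-Schoenfeld proportional-hazards check for the exposure.
    """
    if covariates is None:
        covariates = [c for c in COX_COVARIATES if c != exposure]
    cols = [duration_col, event_col, exposure] + covariates
    if strata is not None:
        cols.append(strata)
    df = records[cols].dropna().copy()
    if df[event_col].sum() == 0:
        raise ValueError("no events in survival records")
    df[event_col] = df[event_col].astype(int)
    if strata is not None and df[strata].dtype == bool:
        df[strata] = df[strata].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col,
            strata=[strata] if strata is not None else None)
    beta = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    ci = cph.confidence_intervals_.loc[exposure]
    out = {
        "exposure": exposure,
        "log_hr": beta,
        "hr": float(np.exp(beta)),
        "se": se,
        "hr_ci_low": float(np.exp(ci.iloc[0])),
        "hr_ci_high": float(np.exp(ci.iloc[1])),
        "p": float(cph.summary.loc[exposure, "p"]),
        "n": int(len(df)),
        "n_events": int(df[event_col].sum()),
        "model": cph,
    }
    if check_ph:
        try:
            ph = proportional_hazard_test(cph, df, time_transform="rank")
            pval = float(ph.summary.loc[exposure, "p"].iloc[0]
                         if hasattr(ph.summary.loc[exposure, "p"], "iloc")
                         else ph.summary.loc[exposure, "p"])
            out["ph_test_p"] = pval
            out["ph_ok"] = pval > 0.05
        except Exception as exc:  # PH test failure must not kill the fit
            out["ph_test_p"] = np.nan
            out["ph_ok"] = None
            out["ph_error"] = str(exc)
    return out


def filter_post_monitoring(records: pd.DataFrame,
                           age_at_monitoring_start: pd.Series,
                           event_col: str = "event",
                           duration_col: str = "age_at_event_or_censor") -> pd.DataFrame:
    """Keep non-cases plus cases first diagnosed after monitoring began."""
    start = age_at_monitoring_start.reindex(records.index)
    keep = (~records[event_col].astype(bool)) | (records[duration_col] > start)
    return records[keep]


def compare_groups(values1, values2, scale: str = "normal") -> GroupComparison:
    """Two-group comparison with Cohen's d (pooled SD) and 95% CI.

    ``scale='normal'`` uses a two-tailed Welch's t test, anything else
    a Mann-Whitney U test.  The d CI uses the standard
    normal-approximation standard error of d (as implemented in
    pingouin's ``compute_esci``).
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    flag = ""
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        d, lo, hi = (0.0, 0.0, 0.0) if x.mean() == y.mean() else (np.inf, np.nan, np.nan)
        flag = "zero_variance"
        if scale == "normal":
            test, statn, p = "welch_t", np.nan, 1.0 if x.mean() == y.mean() else 0.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            test, statn, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        return GroupComparison(d, lo, hi, test, statn, p, x.size, y.size, flag)
    d = float(pg.compute_effsize(x, y, eftype="cohen"))
    lo, hi = pg.compute_esci(stat=d, nx=x.size, ny=y.size, eftype="cohen",
                             confidence=0.95)
    if scale == "normal":
        res = stats.ttest_ind(x, y, equal_var=False)
        test = "welch_t"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann_whitney"
    return GroupComparison(d, float(lo), float(hi), test,
                           float(res.statistic), float(res.pvalue),
                           x.size, y.size, flag)


def empirical_logit_by_decile(exposure: pd.Series, outcome: pd.Series,
                              n_bins: int = 10) -> pd.DataFrame:
    """Linearity-of-log-odds diagnostic: empirical logit per exposure decile.

    Replaces by-eye visualization with a table: mean exposure and
    log(odds) (with a 0.5 continuity correction) in each quantile bin.
    """
    df = pd.DataFrame({"exposure": exposure, "outcome": outcome}).dropna()
    df["bin"] = pd.qcut(df["exposure"], q=n_bins, duplicates="drop")
    rows = []
    for b, grp in df.groupby("bin", observed=True):
        cases = grp["outcome"].sum()
        n = len(grp)
        rows.append({
            "bin": str(b),
            "mean_exposure": float(grp["exposure"].mean()),
            "n": int(n),
            "n_cases": int(cases),
            "empirical_logit": float(np.log((cases + 0.5) / (n - cases + 0.5))),
        })
    return pd.DataFrame(rows)
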