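"""Clinical outcome analysis and the clinical-utility evaluation measure.

Five outcomes are compared across clusters: rate of MMSE decline
(points/year, per-patient OLS slope), time from diagnosis to assisted living
and to death (Kaplan-Meier curves, log-rank tests, Cox proportional
hazards), healthcare utilisation (consultations and missed appointments per
year) and duration of cholinesterase-inhibitor treatment.

Clinical utility contrasts the predictive value of cluster membership with
that of each individual clustering feature: adjusted R-squared of a linear
model for MMSE decline, and a Cox model for time to assisted living. If the
cluster labels outrank every single feature they add predictive value beyond
the features themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# MMSE decline
# --------------------------------------------------------------------------- #

def mmse_slopes(mmse_series: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-patient OLS slope of MMSE score versus years (points/year).

    Patients with fewer than two visits, or a zero time span, are excluded
    (their count is returned and logged). Negative slopes indicate decline.
    """
    slopes = {}
    excluded = 0
    for pid, grp in mmse_series.groupby("patient_id", sort=False):
        t = grp["years_from_diagnosis"].to_numpy(dtype=float)
        y = grp["score"].to_numpy(dtype=float)
        if len(t) < 2 or np.ptp(t) == 0:
            excluded += 1
            continue
        slope = np.polyfit(t, y, 1)[0]
        slopes[pid] = float(slope)
    if excluded:
        logger.info("mmse_slopes: excluded %d patients with <2 usable scores", excluded)
    return pd.Series(slopes, name="mmse_slope"), excluded


# --------------------------------------------------------------------------- #
# Survival machinery
# --------------------------------------------------------------------------- #

def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood 95% confidence band."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if not events.any():
        warnings.warn("no events observed; survival curve is flat at 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "lower": ci.iloc[:, 0].to_numpy(),
        "upper": ci.iloc[:, 1].to_numpy(),
    })
    return out


def log_rank(times, events, groups) -> tuple[float, float]:
    """Chi-square log-rank test across two or more groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank requires at least two groups")
    if not events.any():
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    log_likelihood: float
    flagged: bool = False  # monotone likelihood / separation


def cox_hazard(covariates, times, events, robust: bool = False) -> CoxResult:
    """Cox proportional-hazards fit (Breslow ties), HR = exp(coef).

    ``covariates`` is a Series (single predictor) or DataFrame (e.g. one-hot
    cluster membership against a reference cluster). Monotone likelihood or
    separation is flagged and the affected confidence bounds reported as
    unbounded rather than raised.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("cox model requires at least one event")
    df = covariates.reset_index(drop=True).astype(float).copy()
    cols = list(df.columns)
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = events.astype(int)

    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event", robust=robust)
        except ConvergenceError:
            flagged = True
        flagged = flagged or any("convergence" in str(w.message).lower()
                                 or "monotone" in str(w.message).lower()
                                 for w in caught)
    if flagged and not hasattr(cph, "params_"):
        inf = {c: np.inf for c in cols}
        return CoxResult({c: np.nan for c in cols}, {c: 0.0 for c in cols}, inf,
                         log_likelihood=-np.inf, flagged=True)

    hr = np.exp(cph.params_)
    ci = np.exp(cph.confidence_intervals_)
    return CoxResult(
        hazard_ratios={c: float(hr[c]) for c in cols},
        ci_lower={c: float(ci.iloc[i, 0]) for i, c in enumerate(cols)},
        ci_upper={c: float(ci.iloc[i, 1]) for i, c in enumerate(cols)},
        log_likelihood=float(cph.log_likelihood_),
        flagged=flagged,
    )


# --------------------------------------------------------------------------- #
# Clinical utility
# --------------------------------------------------------------------------- #

@dataclass
class UtilityReport:
    table: pd.DataFrame          # per predictor: adj R2, cox ll, HRs
    r2_ranking: list[str]
    cox_ranking: list[str]
    cluster_top_r2: bool
    cluster_top_cox: bool
    skipped: list[str]


def _predictor_blocks(features: FeatureMatrix) -> dict[str, pd.DataFrame]:
    """One design block per parent variable; one-hot groups drop a reference
    level (the most frequent) to avoid collinearity."""
    blocks = {}
    for parent in features.parents:
        cols = features.columns_for(parent)
        block = features.values[cols]
        if len(cols) > 1:
            ref = block.sum().idxmax()
            block = block.drop(columns=[ref])
        blocks[parent] = block.astype(float)
    return blocks


def _cluster_block(labels: np.ndarray, index) -> pd.DataFrame:
    """One-hot cluster membership with the largest cluster as reference."""
    labels = np.asarray(labels)
    vals, counts = np.unique(labels, return_counts=True)
    ref = vals[np.argmax(counts)]
    data = {
        f"cluster_{v}": (labels == v).astype(float) for v in vals if v != ref
    }
    return pd.DataFrame(data, index=index)


def adjusted_r2(y: np.ndarray, X: pd.DataFrame) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared_adj)


def utility_comparison(
    features: FeatureMatrix,
    cluster_labels,
    outcome_table: pd.DataFrame,
    mmse_slope: pd.Series | None = None,
) -> UtilityReport:
    """Rank cluster membership against every individual feature.

    For each parent variable and for cluster membership: a univariable linear
    model of the MMSE slope (adjusted R-squared) and a Cox model of time to
    assisted living (partial log-likelihood and hazard ratios). Constant
    predictors are skipped with a log entry.
    """
    labels = np.asarray(cluster_labels)
    patients = features.values.index
    if mmse_slope is None:
        mmse_slope = outcome_table["mmse_slope"]
    slope = mmse_slope.reindex(patients)
    times = outcome_table["time_to_assisted_living"].reindex(patients)
    events = outcome_table["assisted_living_event"].reindex(patients).astype(bool)

    blocks = _predictor_blocks(features)
    blocks["cluster membership"] = _cluster_block(labels, patients)

    rows = []
    skipped = []
    slope_mask = slope.notna().to_numpy()
    for name, block in blocks.items():
        if block.shape[1] == 0 or (block.nunique() <= 1).all():
            skipped.append(name)
            logger.info("utility_comparison: skipping constant predictor %r", name)
            continue
        r2 = adjusted_r2(slope[slope_mask].to_numpy(), block.loc[slope_mask])
        cox = cox_hazard(block, times.to_numpy(), events.to_numpy())
        hr_repr = cox.hazard_ratios
        rows.append({
            "predictor": name,
            "adjusted_r2": r2,
            "cox_log_likelihood": cox.log_likelihood,
            "hazard_ratios": hr_repr,
            "hr_ci_lower": cox.ci_lower,
            "hr_ci_upper": cox.ci_upper,
            "cox_flagged": cox.flagged,
        })
    table = pd.DataFrame(rows).set_index("predictor")
    r2_rank = list(table["adjusted_r2"].sort_values(ascending=False).index)
    cox_rank = list(table["cox_log_likelihood"].sort_values(ascending=False).index)
    return UtilityReport(
        table=table,
        r2_ranking=r2_rank,
        cox_ranking=cox_rank,
        cluster_top_r2=r2_rank[0] == "cluster membership",
        cluster_top_cox=cox_rank[0] == "cluster membership",
        skipped=skipped,
    )


# --------------------------------------------------------------------------- #
# Per-cluster outcome summaries
# --------------------------------------------------------------------------- #

def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    m = float(x.mean()) if len(x) else np.nan
    if len(x) < 2:
        return m, np.nan, np.nan
    half = stats.norm.ppf(0.5 + level / 2) * x.std(ddof=1) / np.sqrt(len(x))
    return m, m - half, m + half


@dataclass
class OutcomeSummary:
    means: pd.DataFrame                       # cluster x (outcome mean/lo/hi)
    km_curves: pd.DataFrame                   # tidy: outcome, cluster, time, ...
    pairwise_logrank: pd.DataFrame            # outcome, cluster_a, cluster_b, stat, p


def outcome_summary(
    outcome_table: pd.DataFrame,
    cluster_labels,
    mmse_slope: pd.Series | None = None,
) -> OutcomeSummary:
    """Per-cluster means with 95% CIs plus KM curves and pairwise log-rank."""
    labels = pd.Series(np.asarray(cluster_labels), index=outcome_table.index, name="cluster")
    df = outcome_table.copy()
    if mmse_slope is not None:
        df["mmse_slope"] = mmse_slope.reindex(df.index)

    rate_cols = [c for c in ("consultations_per_year", "missed_per_year",
                             "chei_duration", "mmse_slope") if c in df.columns]
    rows = []
    for cl, grp in df.groupby(labels):
        for col in rate_cols:
            m, lo, hi = _mean_ci(grp[col].to_numpy())
            rows.append({"cluster": cl, "outcome": col, "mean": m,
                         "ci_lower": lo, "ci_upper": hi, "n": len(grp)})
    means = pd.DataFrame(rows)

    km_rows = []
    lr_rows = []
    survival_specs = [
        ("death", "time_to_death", "death_event"),
        ("assisted_living", "time_to_assisted_living", "assisted_living_event"),
    ]
    clusters = sorted(labels.unique())
    for name, tcol, ecol in survival_specs:
        if tcol not in df.columns:
            continue
        for cl, grp in df.groupby(labels):
            curve = km_estimate(grp[tcol], grp[ecol])
            curve.insert(0, "cluster", cl)
            curve.insert(0, "outcome", name)
            km_rows.append(curve)
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                ga, gb = df[labels == a], df[labels == b]
                res = logrank_test(
                    ga[tcol], gb[tcol],
                    event_observed_A=ga[ecol], event_observed_B=gb[ecol],
                )
                lr_rows.append({"outcome": name, "cluster_a": a, "cluster_b": b,
                                "statistic": float(res.test_statistic),
                                "p": float(res.p_value)})
    km_curves = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame()
    pairwise = pd.DataFrame(lr_rows)
    return OutcomeSummary(means=means, km_curves=km_curves, pairwise_logrank=pairwise)
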