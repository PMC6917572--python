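"""Statistical comparison layer: correlations, group tests, colocalization
and survival analysis.

Conventions: all tests are two-sided with significance at 0.05; rank
correlations use average ranks for ties; Cox models use the Efron
approximation for tied event times (the lifelines default); cases with
missing covariates are dropped case-wise in multivariable fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "SurvivalFit",
    "spearman",
    "covariate_association",
    "single_cell_colocalization",
    "survival_compare",
]


@dataclass
class SurvivalFit:
    """Two-group survival comparison summary."""

    hazard_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    logrank_p: float
    n: int
    n_events: int
    km_curves: dict[str, pd.DataFrame]
    risk_table: pd.DataFrame
    warnings: list[str]

    def __post_init__(self) -> None:
        if self.hazard_ratio is not None:
            if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
                raise ValueError("CI must bracket the hazard ratio")
            if self.hazard_ratio <= 0:
                raise ValueError("hazard ratio must be positive")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p value.

    Missing values are removed pairwise; at least 3 complete pairs are
    required. Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, p = sps.spearmanr(x[keep], y[keep])
    return float(rho), float(p)


def covariate_association(score, group) -> tuple[float, float, str]:
    """Association between a continuous score and a categorical covariate.

    Wilcoxon rank-sum (Mann-Whitney U, exact when feasible) for two groups,
    Kruskal-Wallis H for more. Scores are used unbinned. Missing scores or
    group labels are dropped pairwise.

    Returns (statistic, p, test_name).
    """
    score = pd.Series(np.asarray(score, dtype=float))
    group = pd.Series(group)
    keep = score.notna() & group.notna()
    score, group = score[keep], group[keep]
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [score[group == g].to_numpy() for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if len(levels) == 2:
        method = "exact" if max(map(len, samples)) <= 25 else "asymptotic"
        res = sps.mannwhitneyu(samples[0], samples[1], method=method)
        return float(res.statistic), float(res.pvalue), "wilcoxon_ranksum"
    res = sps.kruskal(*samples)
    return float(res.statistic), float(res.pvalue), "kruskal_wallis"


def single_cell_colocalization(
    cells: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    sample_n: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Single-cell coexpression of two markers from nuclear mean intensities.

    When more than ``sample_n`` cells are available, a seeded uniform
    downsample without replacement is taken first (as done for scatter
    visualization); the Spearman correlation is computed on the (sub)sample.

    Parameters
    ----------
    cells : DataFrame with one row per cell and one column per marker
        (nuclear mean intensity).

    Returns (rho, p, scatter_table).
    """
    for m in (marker_a, marker_b):
        if m not in cells.columns:
            raise ValueError(f"marker column missing: {m}")
    sub = cells[[marker_a, marker_b]].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 cells")
    if len(sub) > sample_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(sub), size=sample_n, replace=False)
        sub = sub.iloc[np.sort(idx)]
    rho, p = spearman(sub[marker_a], sub[marker_b])
    return rho, p, sub.reset_index(drop=True)


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    tab = kmf.survival_function_.reset_index()
    tab.columns = ["time_months", "survival"]
    return tab


def survival_compare(
    table: pd.DataFrame,
    label_col: str,
    time_col: str = "time_months",
    event_col: str = "event",
    horizon_months: float = 60.0,
    covariates: list[str] | None = None,
    risk_table_interval: float = 12.0,
) -> SurvivalFit:
    """Two-group survival comparison at a fixed horizon.

    Applies administrative censoring at ``horizon_months``, estimates
    Kaplan-Meier curves per group with a risk table, compares groups with
    the log-rank test, and fits a Cox proportional-hazards model (Efron
    ties): univariable on the group indicator, multivariable when
    ``covariates`` are given (categorical covariates are dummy-coded;
    missing covariate rows are dropped).

    The reported hazard ratio is for the second group level (sorted order)
    relative to the first; with labels "negative"/"positive" this is
    positive-vs-negative, so pass labels accordingly or relevel upstream.
    When a group has no events the HR is reported missing with a warning
    while the KM curves are still produced.
    """
    df = table[[c for c in {label_col, time_col, event_col, *(covariates or [])}]].copy()
    df = df.dropna(subset=[label_col, time_col, event_col])
    levels = sorted(df[label_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"label column must have exactly 2 levels, got {levels}")

    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=float) > 0
    over = time > horizon_months
    time = np.minimum(time, horizon_months)
    event = event & ~over
    df = df.assign(_time=time, _event=event.astype(int))

    warnings: list[str] = []
    km_curves: dict[str, pd.DataFrame] = {}
    risk_rows = []
    times_grid = np.arange(0.0, horizon_months + risk_table_interval, risk_table_interval)
    for lvl in levels:
        sub = df[df[label_col].astype(str) == lvl]
        kmf = KaplanMeierFitter(label=str(lvl))
        kmf.fit(sub["_time"], sub["_event"])
        km_curves[str(lvl)] = _km_table(kmf)
        at_risk = [(sub["_time"] >= t).sum() for t in times_grid]
        risk_rows.append(pd.Series(at_risk, index=times_grid, name=str(lvl)))
    risk_table = pd.DataFrame(risk_rows)
    risk_table.columns.name = "time_months"

    lr = _lifelines_logrank(
        df.loc[df[label_col].astype(str) == levels[0], "_time"],
        df.loc[df[label_col].astype(str) == levels[1], "_time"],
        event_observed_A=df.loc[df[label_col].astype(str) == levels[0], "_event"],
        event_observed_B=df.loc[df[label_col].astype(str) == levels[1], "_event"],
    )

    hr = ci_low = ci_high = None
    group_ind = (df[label_col].astype(str) == levels[1]).astype(float)
    events_per_group = df.groupby(df[label_col].astype(str))["_event"].sum()
    if (events_per_group > 0).all():
        X = pd.DataFrame({"_group": group_ind})
        dropped = 0
        if covariates:
            for cov in covariates:
                col = df[cov]
                if col.dtype.kind in "biufc":
                    X[cov] = col.astype(float)
                else:
                    dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
                    X = pd.concat([X, dummies.astype(float)], axis=1)
            keep = X.notna().all(axis=1)
            dropped = int((~keep).sum())
            X = X[keep]
        else:
            keep = X.index
        fit_df = X.assign(_time=df.loc[X.index, "_time"], _event=df.loc[X.index, "_event"])
        cph = CoxPHFitter()
        cph.fit(fit_df, duration_col="_time", event_col="_event")
        hr = float(np.exp(cph.params_["_group"]))
        ci = cph.confidence_intervals_.loc["_group"]
        ci_low, ci_high = float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))
        if dropped:
            warnings.append(f"dropped {dropped} cases with missing covariates")
    else:
        warnings.append("a group has no events; hazard ratio not estimable")

    return SurvivalFit(
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        logrank_p=float(lr.p_value),
        n=len(df),
        n_events=int(df["_event"].sum()),
        km_curves=km_curves,
        risk_table=risk_table,
        warnings=warnings,
    )
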