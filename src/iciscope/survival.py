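"""Survival analysis: Kaplan-Meier curves, log-rank tests, univariate Cox.

Log-rank tests and Cox fits are delegated to lifelines. The product-limit
estimator is computed directly so the conventions the workflow relies on
are explicit: risk sets count subjects censored at an event time as still
at risk at that time, and uncertainty is the Greenwood variance. The
univariate-Cox prognostic gene screen used before PCA scoring lives here
too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMCurve:
    """Product-limit survival estimate, defined at observed event times."""

    times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def median_survival(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.inf


def _check_surv(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if (data["time"] < 0).any():
        raise ValueError("negative survival times")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return data


def km_estimate(data: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``data`` needs columns ``time`` and ``event``. S(t) is the product of
    (1 - d_i/n_i) over event times up to t, with the Greenwood variance
    S(t)^2 * sum d_i / (n_i (n_i - d_i)); subjects censored exactly at an
    event time are counted at risk at that time.
    """
    data = _check_surv(data)
    if len(data) == 0:
        raise ValueError("empty survival data")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy(dtype=int)
    event_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in event_times], dtype=float)
    n_event = np.array([((t == u) & (e == 1)).sum() for u in event_times],
                       dtype=float)
    surv = np.cumprod(1.0 - n_event / n_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_risk > n_event,
                            n_event / (n_risk * (n_risk - n_event)), 0.0)
    se = surv * np.sqrt(np.cumsum(gw_terms))
    return KMCurve(times=event_times, survival=surv, greenwood_se=se,
                   n_risk=n_risk.astype(int), n_event=n_event.astype(int))


def logrank_test(data: pd.DataFrame, groups: pd.Series
                 ) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df = k-1, p)."""
    data = _check_surv(data)
    groups = groups.reindex(data.index)
    if groups.isna().any():
        raise ValueError("every subject needs a group label")
    k = groups.nunique()
    if k < 2:
        raise ValueError("need at least 2 groups")
    if data["event"].sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(data["time"], groups, data["event"])
    return float(res.test_statistic), k - 1, float(res.p_value)


def cox_univariate(data: pd.DataFrame, covariate: pd.Series
                   ) -> tuple[float, float, float]:
    """Univariate Cox proportional-hazards fit; returns (beta, se, p).

    Non-convergence (e.g. a monotone partial likelihood from perfect
    separation) is flagged by returning NaN for all three values.
    """
    data = _check_surv(data)
    x = covariate.reindex(data.index)
    if x.isna().any():
        raise ValueError("covariate missing for some subjects")
    if data["event"].sum() < 2:
        raise ValueError("need at least 2 events")
    if x.nunique() < 2:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"time": data["time"], "event": data["event"],
                       "x": x.to_numpy(dtype=float)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError):
        return np.nan, np.nan, np.nan
    s = cph.summary.loc["x"]
    return float(s["coef"]), float(s["se(coef)"]), float(s["p"])


def prognostic_gene_filter(expr: pd.DataFrame, clinical: pd.DataFrame,
                           genes: list[str] | None = None,
                           alpha: float = 0.05) -> list[str]:
    """Keep genes whose (z-scored) expression is prognostic at p < alpha
    in a univariate Cox model; no multiplicity correction is applied
    (the raw 0.05 screen)."""
    if genes is None:
        genes = list(expr.index)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    samples = [s for s in clinical.index if s in expr.columns]
    clin = clinical.loc[samples]
    kept = []
    for g in genes:
        x = expr.loc[g, samples].astype(float)
        if x.std() == 0:
            warnings.warn(f"constant gene {g!r} skipped", stacklevel=2)
            continue
        z = (x - x.mean()) / x.std()
        _, _, p = cox_univariate(clin, z)
        if np.isnan(p):
            warnings.warn(f"Cox fit did not converge for {g!r}; excluded",
                          stacklevel=2)
            continue
        if p < alpha:
            kept.append(g)
    if not kept:
        warnings.warn("no gene passed the prognostic screen", stacklevel=2)
    return kept


def stratified_km(data: pd.DataFrame, strata_labels: pd.Series
                  ) -> tuple[dict[str, KMCurve], tuple[float, int, float]]:
    """Per-stratum KM curves plus an overall k-group log-rank test.

    Typical use: 2x2 strata from TMB-high/low crossed with ICI-high/low.
    """
    data = _check_surv(data)
    strata = strata_labels.reindex(data.index)
    if strata.isna().any():
        raise ValueError("every subject needs a stratum label")
    levels = strata.unique().tolist()
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty strata")
    curves = {str(s): km_estimate(data.loc[strata == s]) for s in levels}
    return curves, logrank_test(data, strata)
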