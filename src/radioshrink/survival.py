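"""Survival stratification and validation.

Patients are mapped to three response groups from their predicted pCR and
concentric-shrinkage probabilities, then compared with Kaplan-Meier curves,
log-rank tests (including the selection-biased minimum-p optimal cutoff),
and Cox proportional-hazards models with a likelihood-ratio assessment of
the imaging exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

ADMIN_CENSOR_MONTHS = 120.0


@dataclass(frozen=True)
class StratificationThresholds:
    """Probability cutoffs for group assignment. The reference defaults are
    the operating points reported for the prognostic validation workflow."""

    cs_threshold: float = 0.6708
    pcr_threshold: float = 0.2444

    def __post_init__(self) -> None:
        for v in (self.cs_threshold, self.pcr_threshold):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


def censor_at(records: pd.DataFrame, horizon: float = ADMIN_CENSOR_MONTHS,
              time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Administrative censoring: any time beyond ``horizon`` is truncated to
    the horizon with event = 0 — events after the follow-up window are not
    observed within it. Times inside the window are untouched."""
    out = records.copy()
    if (out[time_col] < 0).any():
        raise ValueError("negative survival times")
    beyond = out[time_col] > horizon
    out.loc[beyond, time_col] = horizon
    out.loc[beyond, event_col] = 0
    return out


def stratify(scores: pd.DataFrame, thresholds: StratificationThresholds
             ) -> pd.Series:
    """Group 3 iff p_pcr >= pcr_threshold; group 2 iff not group 3 and
    p_cs >= cs_threshold; group 1 otherwise. Boundary values go to the
    higher (responding) group."""
    p_cs = scores["cs"].to_numpy(dtype=float)
    p_pcr = scores["pcr"].to_numpy(dtype=float)
    if ((p_cs < 0) | (p_cs > 1) | (p_pcr < 0) | (p_pcr > 1)).any():
        raise ValueError("scores must be probabilities in [0, 1]")
    group = np.ones(len(scores), dtype=int)
    group[p_cs >= thresholds.cs_threshold] = 2
    group[p_pcr >= thresholds.pcr_threshold] = 3
    return pd.Series(group, index=scores.index, name="group")


def kaplan_meier(records: pd.DataFrame, time_col: str = "time",
                 event_col: str = "event") -> pd.DataFrame:
    """Product-limit estimator with the simultaneous-death tie convention.

    Returns one row per distinct event time: (time, n_at_risk, n_events,
    n_censored, survival)."""
    if len(records) == 0:
        raise ValueError("no records")
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n_at_risk = len(t)
    for ti in np.unique(t):
        here = t == ti
        d = int(e[here].sum())
        c = int(here.sum()) - d
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append({"time": float(ti), "n_at_risk": n_at_risk,
                     "n_events": d, "n_censored": c, "survival": s})
        n_at_risk -= int(here.sum())
    return pd.DataFrame(rows)


def logrank_test(groups: list[pd.DataFrame], time_col: str = "time",
                 event_col: str = "event") -> dict:
    """K-sample log-rank test over the pooled event times.

    Returns the chi-square statistic, degrees of freedom (K-1) and p-value.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    times = [g[time_col].to_numpy(dtype=float) for g in groups]
    events = [g[event_col].to_numpy(dtype=int) for g in groups]
    k = len(groups)
    all_times = np.unique(np.concatenate([t[e == 1] for t, e in zip(times, events)]))
    observed = np.zeros(k)
    expected = np.zeros(k)
    var_acc = np.zeros((k, k))
    for ti in all_times:
        n_at = np.array([float((t >= ti).sum()) for t in times])
        d = np.array([float(((t == ti) & (e == 1)).sum())
                      for t, e in zip(times, events)])
        n_tot = n_at.sum()
        d_tot = d.sum()
        if n_tot <= 1 or d_tot == 0:
            continue
        observed += d
        expected += d_tot * n_at / n_tot
        # hypergeometric covariance of the group-wise death counts
        factor = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
        for a in range(k):
            for b in range(k):
                if a == b:
                    var_acc[a, b] += factor * n_at[a] * (n_tot - n_at[a]) / n_tot ** 2
                else:
                    var_acc[a, b] -= factor * n_at[a] * n_at[b] / n_tot ** 2
    z = (observed - expected)[:-1]
    V = var_acc[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(V) @ z)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return {"statistic": chi2, "df": df, "p_value": p,
            "observed": observed, "expected": expected}


def optimal_cutoff_logrank(score: pd.Series, records: pd.DataFrame,
                           time_col: str = "time", event_col: str = "event",
                           pct_range: tuple[float, float] = (10.0, 90.0)) -> dict:
    """Score threshold minimizing the two-group log-rank p.

    Candidates are the observed score values between the 10th and 90th
    percentiles; ties in p go to the lower threshold. The full p-vs-threshold
    trace is returned — the minimal p is selection-biased and must not be
    read as a calibrated significance level.
    """
    s = np.asarray(score, dtype=float)
    if len(s) < 20:
        raise ValueError("optimal cutoff search needs at least 20 patients")
    if np.all(s == s[0]):
        raise ValueError("score is constant; no cutoff exists")
    lo, hi = np.percentile(s, pct_range)
    candidates = np.unique(s[(s >= lo) & (s <= hi)])
    rows = []
    best = None
    for thr in candidates:
        high = s >= thr
        if high.all() or not high.any():
            continue
        res = logrank_test([records[~high], records[high]],
                           time_col=time_col, event_col=event_col)
        rows.append({"threshold": float(thr), "p_value": res["p_value"]})
        # strict improvement only: candidates ascend, so ties keep the
        # lower threshold
        if best is None or res["p_value"] < best[1]:
            best = (float(thr), res["p_value"])
    if best is None:
        raise ValueError("no admissible cutoff in the candidate range")
    return {"threshold": best[0], "p_value": best[1],
            "trace": pd.DataFrame(rows)}


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    lr_p: float | None
    summary: pd.DataFrame
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


def cox_fit(records: pd.DataFrame, covariates: list[str], exposure: str,
            time_col: str = "time", event_col: str = "event") -> CoxResult:
    """Cox proportional-hazards fit for one exposure, optionally adjusted.

    Reports the exposure's hazard ratio with 95% CI and Wald p, plus the
    likelihood-ratio p against the nested model without the exposure
    (univariate mode: against the null model). Warns when events are fewer
    than ten per fitted coefficient.
    """
    cols = [time_col, event_col, exposure] + list(covariates)
    df = records[cols].copy()
    warn: list[str] = []
    n_events = int(df[event_col].sum())
    n_coef = 1 + len(covariates)
    if n_events < 10 * n_coef:
        warn.append(f"only {n_events} events for {n_coef} coefficients")
        log.warning(warn[-1])
    full = CoxPHFitter()
    try:
        full.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # complete separation / non-convergence
        return CoxResult(np.nan, np.nan, np.nan, np.nan, None,
                         pd.DataFrame(), converged=False,
                         warnings=warn + [f"fit failed: {exc}"])
    row = full.summary.loc[exposure]
    if covariates:
        reduced = CoxPHFitter()
        reduced.fit(df.drop(columns=exposure), duration_col=time_col,
                    event_col=event_col)
        lr_stat = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
        lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), 1))
    else:
        lr_p = float(full.log_likelihood_ratio_test().p_value)
    return CoxResult(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        wald_p=float(row["p"]),
        lr_p=lr_p,
        summary=full.summary,
        warnings=warn,
    )


def three_group_analysis(assignment: pd.Series, records: pd.DataFrame,
                         time_col: str = "time", event_col: str = "event") -> dict:
    """KM curves per response group, the overall log-rank test, and all
    pairwise tests with Benjamini-Hochberg adjusted p-values."""
    groups = sorted(assignment.unique())
    census = assignment.value_counts().to_dict()
    if len(groups) < 3:
        raise ValueError(f"expected three nonempty groups, census: {census}")
    frames = {g: records.loc[assignment[assignment == g].index] for g in groups}
    km = {g: kaplan_meier(frames[g], time_col, event_col) for g in groups}
    overall = logrank_test([frames[g] for g in groups], time_col, event_col)
    pair_rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            res = logrank_test([frames[a], frames[b]], time_col, event_col)
            pair_rows.append({"group_a": a, "group_b": b,
                              "p_value": res["p_value"],
                              "statistic": res["statistic"]})
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_adjusted"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    return {"km": km, "overall": overall, "pairwise": pairwise,
            "census": census}
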