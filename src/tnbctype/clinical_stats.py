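"""Subtype-stratified clinical association and outcome statistics.

Contingency tests of clinical variables across subtypes, pathological
complete response (pCR) odds ratios of each subtype against the whole
unselected cohort, binomial confidence intervals for response rates,
Kaplan-Meier / logrank survival comparisons, and a Cox proportional
hazards model on a continuous covariate (the IM descriptor score) with
a likelihood-ratio test.

The odds-ratio reference is deliberately the entire unselected cohort
including the group itself (so the cohort's own OR is exactly 1); this
vs-whole-cohort convention is the forest-plot layout used in
neoadjuvant-response reporting and is not an independent 2x2 contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyResult",
    "OddsRatioResult",
    "contingency_test",
    "odds_ratio_vs_cohort",
    "binomial_ci",
    "km_fit",
    "cox_continuous",
    "subtype_outcome_report",
]


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass
class OddsRatioResult:
    label: str
    or_point: float
    ci_low: float
    ci_high: float
    a: float  # group successes
    b: float  # group failures
    c: float  # cohort successes
    d: float  # cohort failures


def contingency_test(table, method: str = "auto") -> ContingencyResult:
    """Pearson chi-square or Fisher exact test of an r x c count table.

    ``auto`` picks Fisher for a 2x2 table with any expected cell below
    5, otherwise the Pearson chi-square with no continuity correction.
    Rows or columns with zero margin are dropped with a warning.  The
    Fisher p is the exact conditional two-sided value (sum of table
    probabilities no larger than the observed one); Fisher is defined
    for 2x2 tables only.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("table cells must be nonnegative integers")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table needs at least 2 non-empty rows and columns")

    if method == "auto":
        expected = stats.contingency.expected_freq(t)
        if t.shape == (2, 2) and (expected < 5).any():
            method = "fisher"
        else:
            method = "chisq"
    if method == "chisq":
        chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
        return ContingencyResult(t.astype(int), float(chi2), int(dof),
                                 float(p), "chisq")
    if method == "fisher":
        if t.shape != (2, 2):
            raise ValueError("Fisher exact test supports 2x2 tables only")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return ContingencyResult(t.astype(int), float(odds), 1, float(p),
                                 "fisher")
    raise ValueError(f"unknown method {method!r}")


def odds_ratio_vs_cohort(group: Mapping[str, int], cohort: Mapping[str, int],
                         label: str = "", conf: float = 0.95
                         ) -> OddsRatioResult:
    """Odds ratio of a group's pCR odds against the whole cohort's.

    ``group`` / ``cohort`` carry ``n_pcr`` and ``n_total``.  OR =
    odds(group) / odds(cohort) with odds = p / (1 - p); a Haldane-
    Anscombe +0.5 is applied to all four implied cells when any is
    zero, and the CI is the Woolf log-scale interval.
    """
    a = float(group["n_pcr"])
    b = float(group["n_total"]) - a
    c = float(cohort["n_pcr"])
    d = float(cohort["n_total"]) - c
    if group["n_total"] <= 0 or cohort["n_total"] <= 0:
        raise ValueError("group and cohort totals must be positive")
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a / b) / (c / d)
    z = stats.norm.ppf(0.5 + conf / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_point) - z * se))
    hi = float(np.exp(np.log(or_point) + z * se))
    return OddsRatioResult(label, float(or_point), lo, hi, a, b, c, d)


def binomial_ci(successes: int, n: int, method: str = "wilson",
                conf: float = 0.95) -> tuple[float, float]:
    """Two-sided binomial CI for a rate, reported on the 0-100 scale."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method=sm_method)
    return float(100 * lo), float(100 * hi)


def km_fit(times: Sequence[float], events: Sequence[int],
           groups: Sequence | None = None, logrank: bool = True) -> dict:
    """Kaplan-Meier curves per group, medians, and a logrank comparison.

    The median is the first time at which the product-limit estimate
    drops to 0.5 or below (NaN if never reached).  The logrank test
    requires at least two groups; pass ``logrank=False`` for a single
    group.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    curves, medians = {}, {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() < 1:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame({
            "time": sf.index.values,
            "survival": sf.iloc[:, 0].values,
        })
        med = kmf.median_survival_time_
        medians[lab] = float(med) if np.isfinite(med) else np.nan
    out = {"curves": curves, "medians": medians,
           "logrank_stat": None, "logrank_p": None}
    if logrank:
        if len(labels) < 2:
            raise ValueError("logrank comparison requires at least two groups")
        res = multivariate_logrank_test(times, groups, events)
        out["logrank_stat"] = float(res.test_statistic)
        out["logrank_p"] = float(res.p_value)
    return out


def cox_continuous(covariate: Sequence[float], times: Sequence[float],
                   events: Sequence[int], tol: float = 1e-10,
                   max_iter: int = 50) -> dict:
    """Cox proportional hazards on one continuous covariate.

    Maximizes the Breslow partial likelihood by Newton-Raphson and
    reports the coefficient, hazard ratio, its standard error, and the
    likelihood-ratio p-value against the null model (1 df).  Requires a
    non-constant covariate and at least 10 events.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(x) == len(t) == len(e)):
        raise ValueError("covariate, times and events must align")
    if e.sum() < 10:
        raise ValueError(f"need at least 10 events, got {int(e.sum())}")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate is non-identifiable")
    # center for numerical stability; beta is translation-invariant
    xc = x - x.mean()
    order = np.argsort(t, kind="stable")
    xc, t, e = xc[order], t[order], e[order]
    ev_idx = np.flatnonzero(e == 1)
    # distinct event times with death counts and covariate sums
    ev_t = t[ev_idx]
    uniq, inv = np.unique(ev_t, return_inverse=True)
    d = np.bincount(inv).astype(float)
    s = np.bincount(inv, weights=xc[ev_idx])
    # risk-set entry index for each distinct event time
    first_at_risk = np.searchsorted(t, uniq, side="left")

    def _loglik(beta: float):
        w = np.exp(beta * xc)
        # reverse cumulative sums give risk-set aggregates at any time
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w * xc)[::-1])[::-1]
        S2 = np.cumsum((w * xc ** 2)[::-1])[::-1]
        s0, s1, s2 = S0[first_at_risk], S1[first_at_risk], S2[first_at_risk]
        ll = float(beta * s.sum() - (d * np.log(s0)).sum())
        grad = float(s.sum() - (d * s1 / s0).sum())
        hess = float(-(d * (s2 / s0 - (s1 / s0) ** 2)).sum())
        return ll, grad, hess

    beta = 0.0
    ll0, _, _ = _loglik(0.0)
    ll = ll0
    for _ in range(max_iter):
        ll, grad, hess = _loglik(beta)
        if hess >= 0:
            break
        step = -grad / hess
        # step-halving to keep the partial likelihood non-decreasing
        new_beta = beta + step
        new_ll = _loglik(new_beta)[0]
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = _loglik(new_beta)[0]
            halvings += 1
        if abs(new_beta - beta) < tol:
            beta = new_beta
            ll = new_ll
            break
        beta, ll = new_beta, new_ll
    ll, grad, hess = _loglik(beta)
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else np.nan
    lrt = 2.0 * (ll - ll0)
    return {
        "beta": float(beta),
        "hr": float(np.exp(beta)),
        "se": se,
        "loglik": float(ll),
        "loglik_null": float(ll0),
        "lrt_stat": float(max(lrt, 0.0)),
        "lrt_p": float(stats.chi2.sf(max(lrt, 0.0), df=1)),
        "n_events": int(e.sum()),
    }


_ENDPOINTS = {"os": ("os_time", "os_event"),
              "rfs": ("rfs_time", "rfs_event"),
              "drfs": ("drfs_time", "drfs_event")}


def subtype_outcome_report(cohort: pd.DataFrame, by: str = "subtype",
                           ci_method: str = "wilson", min_group: int = 5,
                           bonferroni: bool = False) -> dict:
    """Assemble the subtype-stratified response and survival report.

    Per group: pCR rate with a binomial CI and the odds ratio of pCR
    against the whole unselected cohort (forest-plot-ready).  Across
    groups: a contingency test of pCR x group.  For every survival
    endpoint present (OS / RFS / DRFS): an overall logrank across
    groups, group medians, and each-vs-rest logrank p-values (one group
    against all others pooled; unadjusted unless ``bonferroni``).
    Groups smaller than ``min_group`` are excluded from the OR/CI table
    with a warning.
    """
    if by not in cohort.columns:
        raise KeyError(f"grouping column {by!r} absent from cohort table")
    df = cohort.copy()
    groups = [g for g in df[by].dropna().unique()]
    report: dict = {"by": by, "groups": list(map(str, groups))}

    # --- pCR section -----------------------------------------------------
    if "pcr" in df.columns:
        resp = df[df["pcr"].notna()].copy()
        resp["pcr"] = resp["pcr"].astype(int)
        cohort_counts = {"n_pcr": int(resp["pcr"].sum()),
                         "n_total": int(len(resp))}
        rows = []
        for g in groups:
            sub = resp[resp[by] == g]
            n, k = len(sub), int(sub["pcr"].sum())
            row = {"group": str(g), "n": n, "n_pcr": k,
                   "pcr_rate_pct": 100.0 * k / n if n else np.nan,
                   "ci_low": np.nan, "ci_high": np.nan,
                   "or": np.nan, "or_low": np.nan, "or_high": np.nan}
            if n < min_group:
                warnings.warn(f"group {g!r} has {n} < {min_group} responders"
                              " evaluable; OR/CI omitted")
            elif n:
                row["ci_low"], row["ci_high"] = binomial_ci(k, n, ci_method)
                orr = odds_ratio_vs_cohort({"n_pcr": k, "n_total": n},
                                           cohort_counts, label=str(g))
                row["or"], row["or_low"], row["or_high"] = (
                    orr.or_point, orr.ci_low, orr.ci_high)
            rows.append(row)
        report["pcr_table"] = pd.DataFrame(rows)
        report["cohort_pcr"] = cohort_counts
        tab = pd.crosstab(resp[by], resp["pcr"]).reindex(columns=[0, 1],
                                                         fill_value=0)
        if tab.shape[0] >= 2:
            ct = contingency_test(tab.values, method="chisq")
            report["pcr_contingency_p"] = ct.p_value
            report["pcr_contingency_stat"] = ct.statistic
        else:
            report["pcr_contingency_p"] = np.nan

    # --- survival section ------------------------------------------------
    survival = {}
    for name, (tcol, ecol) in _ENDPOINTS.items():
        if tcol not in df.columns or ecol not in df.columns:
            continue
        sub = df[df[tcol].notna() & df[ecol].notna() & df[by].notna()]
        if sub[by].nunique() < 2 or len(sub) < 2:
            continue
        km = km_fit(sub[tcol].values, sub[ecol].astype(int).values,
                    sub[by].values)
        each_vs_rest = {}
        n_comp = sub[by].nunique()
        for g in sub[by].unique():
            ind = (sub[by] == g).astype(int).values
            res = km_fit(sub[tcol].values, sub[ecol].astype(int).values, ind)
            p = res["logrank_p"]
            if bonferroni:
                p = min(1.0, p * n_comp)
            each_vs_rest[str(g)] = {"p": p, "significant": bool(p < 0.05)}
        survival[name] = {
            "logrank_p": km["logrank_p"],
            "medians": {str(k): v for k, v in km["medians"].items()},
            "each_vs_rest": each_vs_rest,
        }
    report["survival"] = survival
    return report
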