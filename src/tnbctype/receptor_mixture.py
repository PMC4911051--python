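"""Receptor-status calling by per-marker two-component Gaussian mixtures.

The empirical log2 expression distribution of each receptor transcript
(ESR1 for ER, PGR for PR, ERBB2 for HER2) across a dataset is bimodal:
a low "negative" component and a high "positive" component.  Each marker
is fit with a 1-D two-component Gaussian mixture by EM, fit per dataset
(never pooled across datasets), and a sample's receptor status is called
from the posterior probability that its value came from the low
component.  A sample negative for all three markers is triple-negative
(TNBC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from tnbctype.io_formats import ExpressionMatrix

__all__ = [
    "MARKERS",
    "MixtureFit",
    "ReceptorCall",
    "fit_mixture_1d",
    "fit_marker_mixtures",
    "posterior_negative",
    "call_receptor_status",
    "identify_tnbc",
    "tnbc_percentage",
]

MARKERS = ("ESR1", "PGR", "ERBB2")

#: floor on component variance, log2 units squared
VAR_FLOOR = 1e-4
#: a fit is flagged unimodal when the means are closer than one pooled SD
#: or either mixing weight collapses below this value
MIN_WEIGHT = 0.05


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture, components ordered low/high."""

    marker: str
    mu_neg: float
    mu_pos: float
    sigma_neg: float
    sigma_pos: float
    w_neg: float
    w_pos: float
    loglik: float
    n_iter: int
    converged: bool
    unimodal_flag: bool
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0),
                                       repr=False, compare=False)

    def __post_init__(self) -> None:
        assert abs(self.w_neg + self.w_pos - 1.0) < 1e-9
        assert self.mu_neg <= self.mu_pos
        assert self.sigma_neg >= np.sqrt(VAR_FLOOR) - 1e-12
        assert self.sigma_pos >= np.sqrt(VAR_FLOOR) - 1e-12


@dataclass
class ReceptorCall:
    """Per-sample receptor status from mixture posteriors."""

    sample_id: str
    posterior_negative: dict[str, float]
    status: dict[str, str]
    is_tnbc: bool


def _em_run(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, w: np.ndarray,
            tol: float, max_iter: int):
    """One EM run; returns params, final loglik, history, iterations, flag."""
    n = x.size
    history = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.vstack([
            np.log(w[0]) + norm.logpdf(x, mu[0], sigma[0]),
            np.log(w[1]) + norm.logpdf(x, mu[1], sigma[1]),
        ])
        lse = logsumexp(logp, axis=0)
        ll = float(lse.sum())
        history.append(ll)
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        w = np.clip(w, 1e-12, None)
        w = w / w.sum()
        mu = resp @ x / nk
        var = np.array([(resp[k] * (x - mu[k]) ** 2).sum() / nk[k] for k in (0, 1)])
        sigma = np.sqrt(np.maximum(var, VAR_FLOOR))
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return mu, sigma, w, history[-1], np.asarray(history), it, converged


def fit_mixture_1d(values: Sequence[float], marker: str = "",
                   tol: float = 1e-8, max_iter: int = 500,
                   n_init: int = 5, seed: int = 0) -> MixtureFit:
    """Fit a two-component Gaussian mixture to 1-D log2 expression.

    EM is restarted from ``n_init`` starts (one quantile-based, the rest
    seeded random); the run with the best final log-likelihood is kept
    and components are relabeled so the low-mean component comes first.
    Requires at least 10 finite values.  A degenerate sample (all values
    equal) returns an unconverged fit with ``unimodal_flag`` set.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError(f"{marker or 'marker'}: non-finite expression values")
    if x.size < 10:
        raise ValueError(
            f"{marker or 'marker'}: need at least 10 values, got {x.size}")
    floor_sd = float(np.sqrt(VAR_FLOOR))
    if np.ptp(x) == 0.0:
        return MixtureFit(marker, float(x[0]), float(x[0]), floor_sd, floor_sd,
                          0.5, 0.5, loglik=np.nan, n_iter=0, converged=False,
                          unimodal_flag=True)

    rng = np.random.default_rng(seed)
    s0 = max(float(np.std(x)), floor_sd)
    starts = [(np.quantile(x, [0.25, 0.75]), np.array([s0 / 2, s0 / 2]),
               np.array([0.5, 0.5]))]
    for _ in range(max(0, n_init - 1)):
        mu0 = rng.choice(x, size=2, replace=False).astype(float)
        u = rng.uniform(0.2, 0.8)
        starts.append((mu0, np.array([s0 / 2, s0 / 2]), np.array([u, 1 - u])))

    best = None
    for mu0, sg0, w0 in starts:
        fit = _em_run(x, mu0.copy(), np.maximum(sg0, floor_sd), w0.copy(),
                      tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, sigma, w, ll, history, it, converged = best
    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    pooled_sd = float(np.sqrt(w[0] * sigma[0] ** 2 + w[1] * sigma[1] ** 2))
    unimodal = (mu[1] - mu[0]) < pooled_sd or float(w.min()) < MIN_WEIGHT
    return MixtureFit(marker, float(mu[0]), float(mu[1]), float(sigma[0]),
                      float(sigma[1]), float(w[0]), float(w[1]), ll, it,
                      converged, unimodal, history)


def fit_marker_mixtures(m: ExpressionMatrix,
                        markers: Sequence[str] = MARKERS,
                        seed: int = 0, **kwargs) -> dict[str, MixtureFit]:
    """Fit one mixture per marker gene of a (gene-level) matrix."""
    fits = {}
    for i, marker in enumerate(markers):
        fits[marker] = fit_mixture_1d(m.gene(marker).values, marker=marker,
                                      seed=seed + i, **kwargs)
    return fits


def posterior_negative(values, fit: MixtureFit) -> np.ndarray:
    """P(low component | value) under a fitted mixture (responsibilities)."""
    x = np.asarray(values, dtype=float)
    log_n = np.log(fit.w_neg) + norm.logpdf(x, fit.mu_neg, fit.sigma_neg)
    log_p = np.log(fit.w_pos) + norm.logpdf(x, fit.mu_pos, fit.sigma_pos)
    # 1 / (1 + exp(log_p - log_n)), stable in both tails
    return np.exp(log_n - np.logaddexp(log_n, log_p))


def call_receptor_status(m: ExpressionMatrix, fits: Mapping[str, MixtureFit],
                         threshold: float = 0.5) -> list[ReceptorCall]:
    """Call per-sample receptor status for every marker in ``fits``.

    A marker is negative when its posterior probability of the low
    component is at least ``threshold``; a sample is TNBC when all
    markers are negative.  Markers whose mixture is unimodal are called
    positive for every sample (conservative: avoids spurious TNBC) with
    a warning.
    """
    post = {}
    for marker, fit in fits.items():
        values = m.gene(marker)  # KeyError with marker name if absent
        if fit.unimodal_flag:
            warnings.warn(
                f"{marker}: mixture is effectively unimodal; calling all "
                f"samples positive for this marker")
            post[marker] = np.zeros(len(values))
        else:
            post[marker] = posterior_negative(values.values, fit)
    calls = []
    for j, sample in enumerate(m.sample_ids):
        pn = {marker: float(post[marker][j]) for marker in fits}
        status = {marker: ("negative" if p >= threshold else "positive")
                  for marker, p in pn.items()}
        calls.append(ReceptorCall(sample, pn, status,
                                  all(s == "negative" for s in status.values())))
    return calls


def identify_tnbc(calls: Iterable[ReceptorCall],
                  ihc: pd.DataFrame | None = None,
                  rule: str = "mixture_only") -> list[str]:
    """Return the sorted list of TNBC sample ids.

    ``ihc``, when given, is indexed by sample id with columns ``er_ihc``,
    ``pr_ihc``, ``her2_ihc`` holding "negative"/"positive" (missing
    entries allowed).  Rules:

    - ``mixture_only`` (default): expression-mixture calls alone.
    - ``ihc_and``: a sample must be triple-negative by both the mixture
      and the pathological annotation (samples without IHC fall back to
      the mixture call).
    - ``ihc_rescue``: the mixture call overrides IHC wherever a mixture
      call exists; IHC fills in samples without one.
    """
    calls = list(calls)
    if rule not in {"mixture_only", "ihc_and", "ihc_rescue"}:
        raise ValueError(f"unknown rule {rule!r}")
    mixture = {c.sample_id: c.is_tnbc for c in calls}

    def ihc_tn(sample: str):
        if ihc is None or sample not in ihc.index:
            return None
        row = ihc.loc[sample]
        vals = [row.get(c) for c in ("er_ihc", "pr_ihc", "her2_ihc")]
        if any(pd.isna(v) for v in vals):
            return None
        return all(str(v).lower() == "negative" for v in vals)

    out = set()
    if rule == "mixture_only":
        out = {s for s, tn in mixture.items() if tn}
    elif rule == "ihc_and":
        for s, tn in mixture.items():
            path = ihc_tn(s)
            if tn and (path is None or path):
                out.add(s)
    else:  # ihc_rescue
        out = {s for s, tn in mixture.items() if tn}
        if ihc is not None:
            for s in ihc.index:
                if s not in mixture and ihc_tn(s):
                    out.add(str(s))
    return sorted(out)


def tnbc_percentage(n_tnbc: int, n_total: int) -> float:
    """Percentage of TNBC samples, rounded to one decimal (e.g. 35.8)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_tnbc / n_total, 1)


def calls_to_frame(calls: Iterable[ReceptorCall]) -> pd.DataFrame:
    """Flatten receptor calls to the documented CSV layout."""
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id}
        for marker, p in c.posterior_negative.items():
            row[f"{marker.lower()}_post_neg"] = p
        row["is_tnbc"] = c.is_tnbc
        rows.append(row)
    return pd.DataFrame(rows)
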