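"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates what the subtyping workflow sees in real bulk
expression data: bimodal ESR1/PGR/ERBB2 receptor transcripts whose low
mode marks the negative state, centroid-structured subtype signal over
the tumor-intrinsic subtypes, convex additive admixture of an immune
and a stromal signature (infiltrating lymphocytes and tumor-associated
mesenchymal cells contaminating bulk profiles), TIL percentages rank-
correlated with the immune admixture, subtype-specific pCR rates and
exponential survival hazards.  Every generator is a pure function of
(config, seed).

The immune signature is built anti-correlated with the mesenchymal (M)
centroid and positively loaded on the IM centroid, so immune-rich
samples show high IM and depressed M correlations; the stromal
signature is loaded on the MSL centroid.  Defaults mirror the clinical
conditions the analyses target: a TNBC fraction of 0.30, intrinsic
subtype proportions 36/22/25/17 (BL1/BL2/M/LAR), an IM-TIL rank
correlation of 0.67, and pCR rates of 0.41/0.18/0.35/0.29.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tnbctype.centroid_subtyping import (CentroidSet, INTRINSIC4, SUBTYPES6)
from tnbctype.io_formats import ExpressionMatrix
from tnbctype.lcm_paired import PairedCompartment
from tnbctype.receptor_mixture import MARKERS

__all__ = [
    "MarkerMixtureParams",
    "CohortConfig",
    "generate_centroids",
    "generate_cohort",
    "generate_paired_lcm",
    "gaussian_copula_pair",
]


@dataclass(frozen=True)
class MarkerMixtureParams:
    """Generating two-component mixture for one receptor transcript."""

    mu_neg: float
    mu_pos: float
    sigma_neg: float = 0.8
    sigma_pos: float = 0.8


#: receptor separations of ~4.5-5 within-component SDs, the clean
#: bimodality receptor transcripts show on log2 microarray scales
DEFAULT_RECEPTORS: dict[str, MarkerMixtureParams] = {
    "ESR1": MarkerMixtureParams(mu_neg=5.5, mu_pos=9.5, sigma_neg=0.8, sigma_pos=0.8),
    "PGR": MarkerMixtureParams(mu_neg=4.5, mu_pos=8.5, sigma_neg=0.8, sigma_pos=0.8),
    "ERBB2": MarkerMixtureParams(mu_neg=7.0, mu_pos=11.0, sigma_neg=0.85, sigma_pos=0.85),
}


@dataclass
class CohortConfig:
    """Generator settings; defaults are the study conditions."""

    n_samples: int = 500
    tnbc_fraction: float = 0.30
    subtype_proportions: dict[str, float] = field(default_factory=lambda: {
        "BL1": 0.36, "BL2": 0.22, "M": 0.25, "LAR": 0.17})
    receptor_params: dict[str, MarkerMixtureParams] = field(
        default_factory=lambda: dict(DEFAULT_RECEPTORS))
    n_genes: int = 500
    signal_sd: float = 1.2
    noise_sd: float = 1.0
    #: Beta(a, b) mixing weight toward the immune signature, and its scale
    immune_admixture: tuple[float, float] = (2.0, 8.0)
    immune_scale: float = 1.5
    stroma_admixture: tuple[float, float] = (2.0, 8.0)
    stroma_scale: float = 1.5
    im_til_rho: float = 0.67
    pcr_rates: dict[str, float] = field(default_factory=lambda: {
        "BL1": 0.41, "BL2": 0.18, "M": 0.35, "LAR": 0.29})
    #: exponential hazards per year for overall survival; RFS and DRFS
    #: use fixed multiples of these
    survival_hazards: dict[str, float] = field(default_factory=lambda: {
        "BL1": 0.06, "BL2": 0.16, "M": 0.11, "LAR": 0.09})
    censor_horizon_years: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 50:
            raise ValueError("need n_samples >= 1 and n_genes >= 50")
        if not 0 <= self.tnbc_fraction <= 1:
            raise ValueError("tnbc_fraction must be in [0, 1]")
        props = np.array(list(self.subtype_proportions.values()))
        if abs(props.sum() - 1.0) > 1e-8 or (props < 0).any():
            raise ValueError("subtype proportions must be nonnegative and sum to 1")
        for name, r in self.pcr_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"pCR rate for {name} outside [0, 1]")
        for name, h in self.survival_hazards.items():
            if h <= 0:
                raise ValueError(f"hazard for {name} must be positive")
        if not -1 < self.im_til_rho < 1:
            raise ValueError("im_til_rho must be in (-1, 1)")


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.linalg.norm(v)


def generate_centroids(n_genes: int, subtype_names: Sequence[str] = SUBTYPES6,
                       seed: int = 0
                       ) -> tuple[CentroidSet, np.ndarray, np.ndarray]:
    """Centroids plus immune and stromal contamination signatures.

    Centroid weight vectors are built from an orthonormal basis (pairwise
    correlations ~0, well under 0.3 in magnitude).  The immune signature
    loads +0.55 on the IM centroid and -0.65 on the M centroid (immune
    infiltration and mesenchymal state are opposite biologies); the
    stromal signature loads +0.75 on the MSL centroid.
    """
    if n_genes < 50:
        raise ValueError("need n_genes >= 50")
    rng = np.random.default_rng(seed)
    k = len(subtype_names)
    raw = rng.standard_normal((n_genes, k + 2))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    basis = q * np.sqrt(n_genes)  # unit-variance-ish orthogonal columns
    weights = pd.DataFrame(
        basis[:, :k], columns=list(subtype_names),
        index=[f"SYG{i + 1:05d}" for i in range(n_genes)])

    names = list(subtype_names)
    im_vec = _unit(weights["IM"].values) if "IM" in names else _unit(basis[:, 0])
    m_vec = _unit(weights["M"].values) if "M" in names else _unit(basis[:, 1])
    msl_vec = _unit(weights["MSL"].values) if "MSL" in names else _unit(basis[:, 2])
    z1 = _unit(basis[:, k])
    z2 = _unit(basis[:, k + 1])
    a_im, a_m = 0.55, 0.65
    immune = a_im * im_vec - a_m * m_vec + np.sqrt(1 - a_im**2 - a_m**2) * z1
    a_msl = 0.75
    stroma = a_msl * msl_vec + np.sqrt(1 - a_msl**2) * z2
    scale = np.sqrt(n_genes)
    return (CentroidSet(weights), immune * scale, stroma * scale)


def gaussian_copula_pair(n: int, rho_s: float, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform pair with a target Spearman correlation via a Gaussian copula."""
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Pearson r giving Spearman rho_s
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    return stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])


def generate_cohort(cfg: CohortConfig | None = None, **overrides) -> dict:
    """Generate a full synthetic cohort.

    Returns ``expression`` (ExpressionMatrix: centroid genes plus the
    three receptor transcripts), ``truth`` (per-sample TNBC flag,
    intrinsic subtype, admixture levels), ``receptor_truth`` (latent
    negative/positive status per marker), ``clinical`` (the documented
    clinical CSV schema), ``til`` and ``centroids``.
    """
    if cfg is None:
        cfg = CohortConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    centroids, immune_sig, stroma_sig = generate_centroids(
        cfg.n_genes, SUBTYPES6, seed=cfg.seed + 1)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    subtype_names = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in subtype_names])
    subtype = rng.choice(subtype_names, size=n, p=probs)
    is_tnbc = rng.random(n) < cfg.tnbc_fraction

    # immune admixture and TIL share a Gaussian copula at the target rho
    u_imm, u_til = gaussian_copula_pair(n, cfg.im_til_rho, rng)
    a, b = cfg.immune_admixture
    imm_w = stats.beta.ppf(u_imm, a, b)
    til_pct = 100.0 * stats.beta.ppf(u_til, 1.3, 8.0)  # right-skewed, median ~11%
    sa, sb = cfg.stroma_admixture
    str_w = rng.beta(sa, sb, size=n)

    W = centroids.weights
    sub_idx = np.array([W.columns.get_loc(s) for s in subtype])
    X = (cfg.signal_sd * W.values[:, sub_idx]
         + cfg.immune_scale * np.outer(immune_sig, imm_w)
         + cfg.stroma_scale * np.outer(stroma_sig, str_w)
         + cfg.noise_sd * rng.standard_normal((cfg.n_genes, n)))

    # receptor rows: TNBC samples are negative for every marker; other
    # samples are guaranteed at least one positive marker
    status = {}
    pos_prob = {"ESR1": 0.8, "PGR": 0.65, "ERBB2": 0.3}
    for marker in MARKERS:
        status[marker] = np.where(is_tnbc, False,
                                  rng.random(n) < pos_prob[marker])
    none_pos = ~is_tnbc & ~np.any([status[mk] for mk in MARKERS], axis=0)
    status["ESR1"] = status["ESR1"] | none_pos
    marker_rows = {}
    for marker in MARKERS:
        p = cfg.receptor_params[marker]
        vals = np.where(status[marker],
                        rng.normal(p.mu_pos, p.sigma_pos, size=n),
                        rng.normal(p.mu_neg, p.sigma_neg, size=n))
        marker_rows[marker] = vals

    df = pd.DataFrame(X, index=W.index, columns=sample_ids)
    for marker in MARKERS:
        df.loc[marker] = marker_rows[marker]
    expression = ExpressionMatrix(df, platform_note="synthetic log2 cohort")

    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "is_tnbc": is_tnbc,
        "subtype": subtype,
        "immune_admixture": imm_w,
        "stroma_admixture": str_w,
    })
    receptor_truth = pd.DataFrame(
        {"sample_id": sample_ids,
         **{f"{mk.lower()}_negative": ~status[mk] for mk in MARKERS}})

    # clinical annotations keyed to the latent subtype
    pcr_p = np.array([cfg.pcr_rates[s] for s in subtype])
    pcr = (rng.random(n) < pcr_p).astype(float)
    age = rng.normal(52.0, 10.0, size=n) + np.where(subtype == "LAR", 8.0, 0.0)
    grade_probs = {"BL1": [0.01, 0.13, 0.86], "BL2": [0.03, 0.17, 0.80],
                   "M": [0.01, 0.27, 0.72], "LAR": [0.10, 0.28, 0.62]}
    grade = np.array([rng.choice([1, 2, 3], p=grade_probs[s]) for s in subtype])
    stage_probs = {"BL1": [0.12, 0.81, 0.07, 0.00], "BL2": [0.18, 0.52, 0.30, 0.00],
                   "M": [0.20, 0.68, 0.07, 0.05], "LAR": [0.22, 0.56, 0.22, 0.00]}
    stage = np.array([rng.choice([1, 2, 3, 4], p=stage_probs[s]) for s in subtype])
    node_p = {"BL1": 0.32, "BL2": 0.33, "M": 0.21, "LAR": 0.47}
    node_positive = rng.random(n) < np.array([node_p[s] for s in subtype])
    tumor_size = np.clip(rng.normal(25.0, 8.0, size=n), 3.0, None)
    met = {}
    met_p = {"brain": {s: 0.11 for s in subtype_names},
             "bone": {"BL1": 0.14, "BL2": 0.15, "M": 0.13, "LAR": 0.46},
             "lung": {"BL1": 0.25, "BL2": 0.25, "M": 0.46, "LAR": 0.24}}
    for site, probs_s in met_p.items():
        met[site] = rng.random(n) < np.array([probs_s[s] for s in subtype])

    def _surv(mult: float):
        lam = mult * np.array([cfg.survival_hazards[s] for s in subtype])
        event_t = rng.exponential(1.0 / lam)
        censor_t = rng.uniform(0.0, cfg.censor_horizon_years, size=n)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        return time, event

    os_time, os_event = _surv(1.0)
    rfs_time, rfs_event = _surv(1.4)
    drfs_time, drfs_event = _surv(1.2)

    clinical = pd.DataFrame({
        "sample_id": sample_ids, "subtype": subtype, "pcr": pcr,
        "age": age, "grade": grade, "stage": stage,
        "node_positive": node_positive.astype(int),
        "tumor_size_mm": tumor_size,
        "met_brain": met["brain"].astype(int),
        "met_bone": met["bone"].astype(int),
        "met_lung": met["lung"].astype(int),
        "os_time": os_time, "os_event": os_event,
        "rfs_time": rfs_time, "rfs_event": rfs_event,
        "drfs_time": drfs_time, "drfs_event": drfs_event,
        "im_score": (imm_w - imm_w.mean()) / max(imm_w.std(), 1e-12),
    })
    til = pd.DataFrame({"sample_id": sample_ids, "til_percent": til_pct})
    return {
        "expression": expression, "truth": truth,
        "receptor_truth": receptor_truth, "clinical": clinical,
        "til": til, "centroids": centroids,
        "immune_signature": immune_sig, "stroma_signature": stroma_sig,
        "config": cfg,
    }


def generate_paired_lcm(n_pairs: int = 10, n_genes: int = 500,
                        n_spiked: int = 50, compartment_fc: float = 2.0,
                        stroma_msl_boost: float = 1.0, seed: int = 0) -> dict:
    """Matched tumor/stroma profile pairs with known structure.

    Each patient has a shared baseline; the stromal compartment receives
    an additive MSL-centroid signal (``stroma_msl_boost``, standardized
    units) and an additive ``compartment_fc`` (log2 units) on the spiked
    genes, whose identities are recorded as truth.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    centroids, _, _ = generate_centroids(n_genes, SUBTYPES6, seed=seed + 1)
    W = centroids.weights
    genes = list(W.index)
    spiked = sorted(rng.choice(genes, size=n_spiked, replace=False).tolist())
    spike_mask = np.isin(genes, spiked)

    subtype = rng.choice(list(INTRINSIC4), size=n_pairs)
    cols, pairs = {}, []
    msl = W["MSL"].values
    for i in range(n_pairs):
        base = 0.5 * rng.standard_normal(n_genes) + 7.0  # patient baseline
        sig = 1.2 * W[subtype[i]].values
        tumor = base + sig + 0.3 * rng.standard_normal(n_genes)
        stroma = (base + sig + stroma_msl_boost * msl
                  + compartment_fc * spike_mask
                  + 0.3 * rng.standard_normal(n_genes))
        t_id, s_id = f"T{i + 1}", f"S{i + 1}"
        cols[t_id] = tumor
        cols[s_id] = stroma
        pairs.append(PairedCompartment(f"P{i + 1}", t_id, s_id))
    df = pd.DataFrame(cols, index=genes)
    return {
        "expression": ExpressionMatrix(df, platform_note="synthetic paired LCM"),
        "pairs": pairs,
        "spiked_genes": spiked,
        "tumor_subtypes": dict(zip((p.patient_id for p in pairs), subtype)),
        "centroids": centroids,
    }
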