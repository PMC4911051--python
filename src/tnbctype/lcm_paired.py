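"""Matched tumor-epithelium / stroma analysis (laser-capture dissection).

Covers the paired-compartment workflow: per-gene differential expression
between compartments with fold-change and FDR gates, hypergeometric
gene-set over-representation of the resulting gene lists, subtype-call
concordance across the compartments of each patient, and an exact
Wilcoxon signed-rank test for paired descriptor scores (e.g. the MSL
correlation of stroma vs tumor in each pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tnbctype.io_formats import ExpressionMatrix

__all__ = [
    "PairedCompartment",
    "differential_expression",
    "overrepresentation_test",
    "paired_subtype_concordance",
    "wilcoxon_signed_rank_exact",
    "read_gmt",
    "load_pairs",
    "compartment_separation",
]

_VAR_FLOOR = 1e-12


@dataclass
class PairedCompartment:
    """Matched tumor/stroma profiles from one patient."""

    patient_id: str
    tumor_profile: str
    stroma_profile: str
    tumor_call: str | None = None
    stroma_call: str | None = None
    tumor_msl: float = np.nan
    stroma_msl: float = np.nan

    def __post_init__(self) -> None:
        if self.tumor_profile == self.stroma_profile:
            raise ValueError(
                f"patient {self.patient_id}: tumor and stroma sample ids "
                f"must differ")


def load_pairs(path: str | Path) -> list[PairedCompartment]:
    """Read a pairs CSV (patient_id, tumor_sample, stroma_sample)."""
    tab = pd.read_csv(path)
    for col in ("patient_id", "tumor_sample", "stroma_sample"):
        if col not in tab.columns:
            raise ValueError(f"{path}: pairs table lacks column {col!r}")
    return [PairedCompartment(str(r.patient_id), str(r.tumor_sample),
                              str(r.stroma_sample))
            for r in tab.itertuples()]


def differential_expression(m: ExpressionMatrix, group_a: Sequence[str],
                            group_b: Sequence[str], paired: bool = False,
                            fc_cut: float = 2.0, q_cut: float = 0.01
                            ) -> pd.DataFrame:
    """Per-gene two-sided t test of group A vs group B on log2 values.

    ``log2fc`` is mean(A) - mean(B) (a difference of 1 is a two-fold
    change; no unlogging).  ``paired`` uses a paired t on matched-order
    columns, otherwise Welch.  P-values are BH-adjusted across all
    tested genes and a gene ``passes`` when |log2fc| >= log2(fc_cut) and
    q < q_cut.  Genes with zero within-group variance are handled via a
    variance floor and flagged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if paired and len(group_a) != len(group_b):
        raise ValueError("paired analysis requires equal group sizes")
    A = m.df[group_a].values
    B = m.df[group_b].values
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    flagged = np.zeros(len(log2fc), dtype=bool)

    if paired:
        d = A - B
        n = d.shape[1]
        sd = d.std(axis=1, ddof=1)
        flagged = sd ** 2 < _VAR_FLOOR
        sd = np.sqrt(np.maximum(sd ** 2, _VAR_FLOOR))
        t = d.mean(axis=1) / (sd / np.sqrt(n))
        df = np.full_like(t, n - 1.0)
    else:
        na, nb = A.shape[1], B.shape[1]
        va = np.maximum(A.var(axis=1, ddof=1), _VAR_FLOOR)
        vb = np.maximum(B.var(axis=1, ddof=1), _VAR_FLOOR)
        flagged = (A.var(axis=1, ddof=1) < _VAR_FLOOR) & \
                  (B.var(axis=1, ddof=1) < _VAR_FLOOR)
        se2 = va / na + vb / nb
        t = log2fc / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    passes = (np.abs(log2fc) >= np.log2(fc_cut)) & (q < q_cut)
    return pd.DataFrame({
        "gene_id": m.gene_ids, "log2fc": log2fc, "t_stat": t,
        "p_value": p, "q_value": q, "passes": passes, "flagged": flagged,
    })


def overrepresentation_test(de_genes: Iterable[str],
                            gene_sets: Mapping[str, Iterable[str]],
                            universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    Each set is intersected with the universe; the tail probability of
    observing at least the seen overlap between the differential list
    and the set is computed, then BH-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes)
    stray = de - universe
    if stray:
        raise ValueError(
            f"differential genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(de)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(members & de)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_name": name, "set_size": K, "overlap": k, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def paired_subtype_concordance(pairs: Iterable[PairedCompartment]) -> dict:
    """Concordance of tumor vs stroma subtype calls across patients.

    A pair is discordant when the two compartments receive different
    calls; ``n_discordant_stroma_msl`` counts discordant pairs whose
    stromal compartment was called MSL (the signature of stromal
    mesenchymal gene expression dominating the profile).
    """
    rows = []
    for p in pairs:
        if p.tumor_call is None or p.stroma_call is None:
            raise ValueError(f"patient {p.patient_id}: subtype calls missing")
        rows.append({
            "patient_id": p.patient_id,
            "tumor_call": p.tumor_call,
            "stroma_call": p.stroma_call,
            "concordant": p.tumor_call == p.stroma_call,
        })
    table = pd.DataFrame(rows)
    n_conc = int(table["concordant"].sum()) if len(table) else 0
    disc = table[~table["concordant"]] if len(table) else table
    return {
        "n_pairs": len(table),
        "n_concordant": n_conc,
        "n_discordant": len(table) - n_conc,
        "n_discordant_stroma_msl": int((disc["stroma_call"] == "MSL").sum())
        if len(table) else 0,
        "table": table,
    }


def wilcoxon_signed_rank_exact(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Wilcoxon signed-rank test with an exact small-n null.

    Zero differences are dropped (Wilcoxon's original treatment); ties
    among the remaining |differences| receive mid-ranks.  For n <= 25
    the p-value is exact over the 2^n equiprobable sign assignments of
    the realized rank multiset: the one-tailed probability of a rank sum
    at least as extreme as observed, doubled and capped at 1.  Larger n
    uses the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero")
        return {"statistic": 0.0, "p_value": 1.0, "n_used": 0,
                "exact": True, "all_zero": True}
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        # DP over doubled ranks (mid-ranks are half-integers) counts the
        # number of sign vectors achieving each possible positive-rank sum.
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:total + 1 - r]
            counts = counts + shifted
        w2 = int(np.rint(2 * w_pos))
        denom = 2.0 ** n
        p_ge = counts[w2:].sum() / denom
        p_le = counts[:w2 + 1].sum() / denom
        p = min(1.0, 2.0 * min(p_ge, p_le))
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        # null variance of the positive-rank sum on the realized
        # (possibly tied, mid-ranked) rank multiset
        var = (ranks ** 2).sum() / 4.0
        z = (w_pos - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        exact = False
    return {"statistic": w_pos, "p_value": float(p), "n_used": int(n),
            "exact": exact, "all_zero": False}


def compartment_separation(m: ExpressionMatrix, group_a: Sequence[str],
                           group_b: Sequence[str], n_components: int = 2
                           ) -> dict:
    """Principal-component view of two sample groups with a silhouette.

    Positive silhouette on the compartment labels in PC space indicates
    the compartments separate in overall expression (as paired
    tumor/stroma profiles do when the compartment effect exceeds noise).
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    cols = list(group_a) + list(group_b)
    X = m.df[cols].values.T
    pcs = PCA(n_components=n_components).fit_transform(X - X.mean(axis=0))
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    return {
        "components": pd.DataFrame(
            pcs, index=cols,
            columns=[f"PC{i + 1}" for i in range(pcs.shape[1])]),
        "silhouette": float(silhouette_score(pcs, labels)),
    }


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets
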