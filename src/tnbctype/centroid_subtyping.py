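"""Nearest-centroid molecular subtyping and the four-subtype refinement.

A sample is assigned to the subtype whose centroid (a vector of gene
weights) it correlates with most strongly, Spearman by default.  The
six-way call over {BL1, BL2, IM, M, MSL, LAR} is refined to the four
tumor-intrinsic subtypes {BL1, BL2, M, LAR} by reassigning samples
called IM or MSL to their best-correlated tumor-intrinsic centroid; the
IM and MSL correlations are kept on every sample as descriptors of
immune infiltrate and stromal content.  Any other centroid collection
(e.g. a 50-gene intrinsic-subtype set) can be pushed through the same
engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from tnbctype.io_formats import (ExpressionMatrix, read_centroid_table,
                                 write_centroid_table, _norm_id)

__all__ = [
    "SUBTYPES6",
    "INTRINSIC4",
    "UNS",
    "CentroidSet",
    "SubtypeResult",
    "correlate_to_centroids",
    "call_tnbctype",
    "refine_tnbctype4",
    "derive_centroids",
    "subtype_samples",
    "results_to_frame",
]

SUBTYPES6 = ("BL1", "BL2", "IM", "M", "MSL", "LAR")
INTRINSIC4 = ("BL1", "BL2", "M", "LAR")
NON_INTRINSIC = ("IM", "MSL")
UNS = "UNS"

#: fixed tie-break precedence for equal correlations
TIE_ORDER = SUBTYPES6


@dataclass
class CentroidSet:
    """Subtype centroids: a genes x subtypes weight table.

    ``intrinsic_subset`` names the tumor-intrinsic subtypes used by the
    four-way refinement; it defaults to the intersection of the column
    names with {BL1, BL2, M, LAR} so that arbitrary centroid collections
    pass through unharmed.
    """

    weights: pd.DataFrame
    intrinsic_subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = self.weights.copy()
        w.index = [_norm_id(g) for g in w.index]
        if w.index.duplicated().any():
            raise ValueError("duplicate gene ids in centroid set")
        if w.columns.duplicated().any():
            raise ValueError("duplicate subtype names in centroid set")
        if w.shape[0] < 2:
            raise ValueError("each centroid needs at least 2 genes")
        self.weights = w.astype(float)
        if not self.intrinsic_subset:
            self.intrinsic_subset = tuple(s for s in INTRINSIC4 if s in w.columns)
        else:
            self.intrinsic_subset = tuple(self.intrinsic_subset)
            missing = set(self.intrinsic_subset) - set(w.columns)
            if missing:
                raise ValueError(f"intrinsic subtypes absent from centroids: {missing}")

    @property
    def names(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.index)

    @classmethod
    def from_tsv(cls, path: str | Path, standardize: bool = False,
                 intrinsic_subset: Sequence[str] = ()) -> "CentroidSet":
        w = read_centroid_table(path)
        if standardize:
            w = _row_standardize(w)
        return cls(w, tuple(intrinsic_subset))

    def to_tsv(self, path: str | Path) -> None:
        write_centroid_table(self.weights, path)


def _row_standardize(df: pd.DataFrame, floor: float = 1e-12) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).clip(lower=floor)
    return df.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class SubtypeResult:
    """Per-sample correlations and subtype calls.

    ``im_score`` / ``msl_score`` are the IM and MSL centroid correlations
    and remain populated (and untouched by refinement) whatever the
    final call; ``n_genes_used`` records the gene-overlap count per
    centroid.
    """

    sample_id: str
    corr: dict[str, float]
    call6: str | None = None
    call4: str | None = None
    im_score: float = np.nan
    msl_score: float = np.nan
    n_genes_used: dict[str, int] = field(default_factory=dict)


def correlate_to_centroids(m: ExpressionMatrix, c: CentroidSet,
                           method: str = "spearman",
                           min_overlap: float = 0.5
                           ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Correlate every sample with every centroid on the gene overlap.

    Returns a samples x subtypes correlation frame and the per-centroid
    count of genes used.  Errors when the overlap with any centroid
    falls below ``min_overlap`` as a fraction of that centroid's genes.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = pd.DataFrame(index=m.sample_ids, columns=c.names, dtype=float)
    n_used: dict[str, int] = {}
    gene_index = pd.Index(m.gene_ids)
    for name in c.names:
        cg = c.weights[name].dropna()
        genes = gene_index.intersection(cg.index)
        frac = len(genes) / len(cg)
        if frac < min_overlap:
            raise ValueError(
                f"centroid {name!r}: only {len(genes)} of {len(cg)} genes "
                f"found in matrix (fraction {frac:.2f} < {min_overlap})")
        n_used[name] = len(genes)
        x = m.df.loc[genes].values          # genes x samples
        w = cg.loc[genes].values
        if method == "spearman":
            x = rankdata(x, axis=0)
            w = rankdata(w)
        xc = x - x.mean(axis=0)
        wc = w - w.mean()
        denom = np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((wc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[name] = np.where(denom > 0, xc.T @ wc / denom, np.nan)
    return corr, n_used


def _argmax_call(corr: Mapping[str, float], names: Sequence[str],
                 threshold: float) -> str:
    """Highest-correlation name in tie-break order, or UNS below threshold."""
    ordered = [n for n in TIE_ORDER if n in names]
    ordered += [n for n in names if n not in ordered]
    best_name, best_val = None, -np.inf
    for n in ordered:
        v = corr[n]
        if np.isfinite(v) and v > best_val:
            best_name, best_val = n, v
    if best_name is None or best_val < threshold:
        return UNS
    return best_name


def call_tnbctype(corr: pd.DataFrame,
                  n_genes_used: Mapping[str, int] | None = None,
                  uns_threshold: float = 0.1,
                  expected_subtypes: Sequence[str] = SUBTYPES6
                  ) -> list[SubtypeResult]:
    """Six-way call: argmax correlation, UNS below ``uns_threshold``.

    Ties break by the fixed precedence BL1 > BL2 > IM > M > MSL > LAR.
    ``expected_subtypes`` declares the centroid names that must be
    present (pass the centroid set's own names for non-TNBC collections).
    """
    missing = [s for s in expected_subtypes if s not in corr.columns]
    if missing:
        raise KeyError(f"correlation map lacks subtype entries: {missing}")
    n_genes_used = dict(n_genes_used or {})
    results = []
    for sample, row in corr.iterrows():
        cmap = {k: float(v) for k, v in row.items()}
        call6 = _argmax_call(cmap, list(corr.columns), uns_threshold)
        results.append(SubtypeResult(
            sample_id=str(sample), corr=cmap, call6=call6,
            im_score=cmap.get("IM", np.nan),
            msl_score=cmap.get("MSL", np.nan),
            n_genes_used=n_genes_used))
    return results


def refine_tnbctype4(results: Iterable[SubtypeResult],
                     uns_threshold: float = 0.1,
                     intrinsic: Sequence[str] = INTRINSIC4
                     ) -> list[SubtypeResult]:
    """Reassign IM/MSL calls to the best tumor-intrinsic centroid.

    Samples called IM or MSL take the highest-correlated centroid among
    the intrinsic subset (not the literal second-highest overall, which
    could itself be the other non-intrinsic subtype).  Intrinsic calls
    pass through; UNS is re-examined against the intrinsic subset and
    stays UNS only if every intrinsic correlation is below threshold.
    IM/MSL scores are untouched.
    """
    refined = []
    for r in results:
        if r.call6 is None:
            raise ValueError(f"sample {r.sample_id}: call6 not populated")
        icorr = {k: r.corr[k] for k in intrinsic if k in r.corr}
        if not icorr:
            raise ValueError("no intrinsic subtype correlations available")
        if r.call6 in NON_INTRINSIC:
            call4 = _argmax_call(icorr, list(icorr), threshold=-np.inf)
        elif r.call6 == UNS:
            call4 = _argmax_call(icorr, list(icorr), threshold=uns_threshold)
        else:
            call4 = r.call6
        refined.append(replace(r, call4=call4))
    return refined


def derive_centroids(m: ExpressionMatrix, labels: Mapping[str, str]
                     ) -> CentroidSet:
    """Build centroids as per-label means of row-standardized expression.

    ``labels`` maps sample id -> subtype name; every label needs at
    least two samples.  Standardization (per gene, across the labeled
    samples) puts weights on the standardized-log2 scale centroid files
    use.
    """
    labels = {str(k): str(v) for k, v in labels.items()}
    missing = set(labels) - set(m.sample_ids)
    if missing:
        raise KeyError(f"labeled samples absent from matrix: {sorted(missing)[:5]}")
    sub = m.df[list(labels)]
    z = _row_standardize(sub)
    by_label: dict[str, list[str]] = {}
    for s, lab in labels.items():
        by_label.setdefault(lab, []).append(s)
    small = {lab: len(ss) for lab, ss in by_label.items() if len(ss) < 2}
    if small:
        raise ValueError(f"labels with fewer than 2 samples: {small}")
    weights = pd.DataFrame({lab: z[ss].mean(axis=1)
                            for lab, ss in sorted(by_label.items())})
    return CentroidSet(weights)


def subtype_samples(m: ExpressionMatrix, c: CentroidSet,
                    method: str = "spearman", uns_threshold: float = 0.1,
                    min_overlap: float = 0.5) -> list[SubtypeResult]:
    """Correlate, call and refine in one step."""
    corr, n_used = correlate_to_centroids(m, c, method=method,
                                          min_overlap=min_overlap)
    results = call_tnbctype(corr, n_used, uns_threshold=uns_threshold,
                            expected_subtypes=c.names)
    intrinsic = c.intrinsic_subset or tuple(c.names)
    return refine_tnbctype4(results, uns_threshold=uns_threshold,
                            intrinsic=intrinsic)


def results_to_frame(results: Iterable[SubtypeResult]) -> pd.DataFrame:
    """Flatten results to the documented CSV layout."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        row.update({f"corr_{k}": v for k, v in r.corr.items()})
        row.update({
            "call6": r.call6, "call4": r.call4,
            "im_score": r.im_score, "msl_score": r.msl_score,
            "n_genes_used": min(r.n_genes_used.values()) if r.n_genes_used else np.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows)
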