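"""Tumor-infiltrating lymphocyte (TIL) scoring vs the IM descriptor.

Pathologist TIL percentages (mononuclear cells as a fraction of all
nuclei on an H&E section) are binned as mild / moderate / intense and
related to each tumor's immunomodulatory (IM) centroid correlation.
The published bin definitions (mild 0-10%, moderate 20-40%, intense
>50%) leave 10-20% and 40-50% unassigned; half-open edges at 20 and 50
are used here so every percentage maps to exactly one bin.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TIL_BINS", "bin_til_levels", "im_til_association"]

TIL_BINS = ("mild", "moderate", "intense")


def bin_til_levels(til_percent: float) -> str:
    """Bin a TIL percentage: mild < 20 <= moderate < 50 <= intense."""
    p = float(til_percent)
    if not np.isfinite(p) or p < 0 or p > 100:
        raise ValueError(f"TIL percentage out of [0, 100]: {til_percent!r}")
    if p < 20:
        return "mild"
    if p < 50:
        return "moderate"
    return "intense"


def im_til_association(im_scores: Mapping[str, float] | pd.Series,
                       til: pd.DataFrame | Iterable) -> dict:
    """Association between IM descriptor scores and lymphocytic infiltrate.

    ``im_scores`` maps sample id -> IM centroid correlation; ``til`` is
    a frame with ``sample_id`` and ``til_percent`` columns (or records
    with those attributes).  Returns the Spearman rho across matched
    samples, per-bin median IM scores, a monotonicity flag
    (median_mild <= median_moderate <= median_intense over the bins
    present) and a Kruskal-Wallis p across bins.  A constant IM score
    makes rho undefined; it is returned as NaN with ``degenerate`` set
    while the per-bin medians are still reported.
    """
    im = pd.Series(dict(im_scores) if not isinstance(im_scores, pd.Series)
                   else im_scores, dtype=float)
    if not isinstance(til, pd.DataFrame):
        til = pd.DataFrame([{"sample_id": t.sample_id,
                             "til_percent": t.til_percent} for t in til])
    til = til.set_index(til["sample_id"].astype(str))
    common = im.index.astype(str).intersection(til.index)
    if len(common) == 0:
        raise ValueError("no samples shared between IM scores and TIL table")
    if len(common) < 3:
        raise ValueError(f"need at least 3 matched samples, got {len(common)}")
    im = im.loc[common].astype(float)
    pct = til.loc[common, "til_percent"].astype(float)
    bins = pct.map(bin_til_levels)

    degenerate = im.nunique() <= 1 or pct.nunique() <= 1
    if degenerate:
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(im.values, pct.values)

    medians = {b: (float(im[bins == b].median()) if (bins == b).any() else np.nan)
               for b in TIL_BINS}
    present = [medians[b] for b in TIL_BINS if np.isfinite(medians[b])]
    monotone = bool(all(a <= b for a, b in zip(present, present[1:])))

    groups = [im[bins == b].values for b in TIL_BINS if (bins == b).sum() > 0]
    if len(groups) >= 2 and not degenerate:
        kw_p = float(stats.kruskal(*groups).pvalue)
    else:
        kw_p = np.nan

    return {
        "n": int(len(common)),
        "spearman_rho": float(rho) if np.isfinite(rho) else np.nan,
        "spearman_p": float(rho_p) if np.isfinite(rho_p) else np.nan,
        "bin_medians": medians,
        "monotone": monotone,
        "kruskal_p": kw_p,
        "degenerate": bool(degenerate),
    }
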