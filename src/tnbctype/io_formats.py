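"""Tabular I/O: expression matrices, centroid files, clinical tables.

All expression values are assumed to be on the log2 scale (post
normalization); matrices are genes x samples with a header row of sample
identifiers and the first column holding gene or probe identifiers.
Gene identifiers are matched exactly after uppercasing and whitespace
stripping; no alias resolution is attempted.  Missing values are rejected
rather than imputed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MatrixFormatError",
    "ExpressionMatrix",
    "ProbeMap",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "read_centroid_table",
    "write_centroid_table",
    "read_clinical",
    "read_til_table",
]

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


class MatrixFormatError(ValueError):
    """Raised when an input table violates the documented format."""


def _norm_id(x) -> str:
    return str(x).strip().upper()


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes (rows) x samples (columns).

    Row identifiers are uppercased and stripped on construction and must
    be unique (probe-level matrices keep one row per probe; collapsing
    multiple probes of one gene is a separate, explicit step).  All
    values must be finite.
    """

    df: pd.DataFrame
    platform_note: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.df, pd.DataFrame):
            self.df = pd.DataFrame(self.df)
        if self.df.shape[0] == 0 or self.df.shape[1] == 0:
            raise MatrixFormatError("empty expression matrix")
        df = self.df.copy()
        df.index = [_norm_id(g) for g in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        if len(set(df.index)) != len(df.index):
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene/probe identifiers: {dupes[:5]}")
        if len(set(df.columns)) != len(df.columns):
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample identifiers: {dupes[:5]}")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise MatrixFormatError(f"non-numeric expression values: {exc}") from exc
        if not np.all(np.isfinite(df.values)):
            bad = np.argwhere(~np.isfinite(df.values))[0]
            raise MatrixFormatError(
                f"non-finite value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.df = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def gene(self, gene_id: str) -> pd.Series:
        """Expression of one gene across samples (KeyError if absent)."""
        key = _norm_id(gene_id)
        if key not in self.df.index:
            raise KeyError(f"gene {gene_id!r} not present in matrix")
        return self.df.loc[key]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.df[list(sample_ids)], self.platform_note)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.df.equals(other.df)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping; identifiers normalized on load."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {_norm_id(p): _norm_id(g) for p, g in dict(self.mapping).items()}
        if not self.mapping:
            raise MatrixFormatError("empty probe map")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProbeMap":
        tab = pd.read_csv(path)
        if tab.shape[1] < 2:
            raise MatrixFormatError("probe map needs probe_id and gene_id columns")
        return cls(dict(zip(tab.iloc[:, 0], tab.iloc[:, 1])))

    def genes(self) -> set[str]:
        return set(self.mapping.values())


def _parse_series_matrix(text: str) -> str:
    """Extract the !series_matrix_table block from a GEO series-matrix file."""
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
    except StopIteration:
        raise MatrixFormatError("no !series_matrix_table_begin marker found")
    end = next((i for i, l in enumerate(lines)
                if l.startswith("!series_matrix_table_end")), len(lines))
    block = "\n".join(lines[start + 1:end])
    return block.replace('"', "")


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or a GEO series-matrix file.

    The first column holds gene/probe identifiers, the header row sample
    identifiers.  ``series_matrix`` parses only the table block of a GEO
    series-matrix file (tab-separated, quoted identifiers stripped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "series_matrix":
        raw = _parse_series_matrix(path.read_text())
        df = pd.read_csv(io.StringIO(raw), sep="\t", index_col=0)
    elif dialect in _DIALECT_SEP:
        df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty expression table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.values.any():
        r, c = np.argwhere(bad.values)[0]
        raise MatrixFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise MatrixFormatError(
            f"{path}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     dialect: str = "tsv") -> None:
    """Write a matrix as UTF-8 TSV/CSV with a ``gene_id`` index header."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = m.df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_DIALECT_SEP[dialect], encoding="utf-8")


def collapse_probes(m: ExpressionMatrix, pm: ProbeMap,
                    method: str = "max_variance") -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``max_variance`` keeps, per gene, the probe with the largest variance
    across samples; ``mean`` averages all of a gene's probes;
    ``named_probe`` keeps exactly the probes listed in the map (one per
    gene) and errors if any listed probe is absent from the matrix.
    """
    if method not in {"max_variance", "mean", "named_probe"}:
        raise ValueError(f"unknown collapse method {method!r}")
    if method == "named_probe":
        missing = sorted(set(pm.mapping) - set(m.gene_ids))
        if missing:
            raise MatrixFormatError(f"named probes absent from matrix: {missing}")
        per_gene: dict[str, list[str]] = {}
        for probe, gene in pm.mapping.items():
            per_gene.setdefault(gene, []).append(probe)
        multi = {g: ps for g, ps in per_gene.items() if len(ps) > 1}
        if multi:
            raise MatrixFormatError(
                f"named_probe requires one probe per gene; multiple for: {multi}")
        sub = m.df.loc[list(pm.mapping)]
        sub.index = [pm.mapping[p] for p in sub.index]
        return ExpressionMatrix(sub.sort_index(), m.platform_note)

    matched = [p for p in m.gene_ids if p in pm.mapping]
    if not matched:
        raise MatrixFormatError("no probe in the map matches a matrix row")
    sub = m.df.loc[matched]
    genes = pd.Series([pm.mapping[p] for p in matched], index=sub.index)
    if method == "mean":
        out = sub.groupby(genes).mean()
    else:  # max_variance
        var = sub.var(axis=1, ddof=1).fillna(0.0)
        keep = var.groupby(genes).idxmax()
        out = sub.loc[keep.values]
        out.index = keep.index
    return ExpressionMatrix(out.sort_index(), m.platform_note)


def read_centroid_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a gene x subtype centroid weight table (numeric)."""
    df = pd.read_csv(path, sep=_DIALECT_SEP.get(dialect, "\t"), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty centroid table")
    df.index = [_norm_id(g) for g in df.index]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"{path}: non-numeric centroid weight: {exc}") from exc
    return df


def write_centroid_table(weights: pd.DataFrame, path: str | Path) -> None:
    out = weights.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", encoding="utf-8")


CLINICAL_COLUMNS = [
    "sample_id", "subtype", "pcr", "age", "grade", "stage", "node_positive",
    "tumor_size_mm", "met_brain", "met_bone", "met_lung",
    "os_time", "os_event", "rfs_time", "rfs_event",
    "drfs_time", "drfs_event", "im_score",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical annotation CSV (see CLINICAL_COLUMNS for the schema).

    Only ``sample_id`` is strictly required; downstream statistics check
    for the columns they need.  ``pcr`` is 0/1 with NA for missing
    response information.
    """
    tab = pd.read_csv(path)
    if "sample_id" not in tab.columns:
        raise MatrixFormatError(f"{path}: clinical table lacks a sample_id column")
    if tab["sample_id"].duplicated().any():
        raise MatrixFormatError(f"{path}: duplicated sample_id values")
    unknown = set(tab.columns) - set(CLINICAL_COLUMNS)
    if unknown:
        warnings.warn(f"clinical table has unrecognized columns: {sorted(unknown)}")
    return tab


def read_til_table(path: str | Path) -> pd.DataFrame:
    """Read a sample_id / til_percent CSV."""
    tab = pd.read_csv(path)
    for col in ("sample_id", "til_percent"):
        if col not in tab.columns:
            raise MatrixFormatError(f"{path}: TIL table lacks column {col!r}")
    return tab
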