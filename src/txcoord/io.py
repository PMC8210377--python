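"""Expression matrices, sample metadata and gene-set collections.

This module is the package's entry point for data: it reads count matrices
(TSV/CSV, genes in rows or columns), two-column sample metadata, and GMT
gene-set files, and provides the pre-correlation transforms (expression
filtering, log2-CPM, reference-gene normalization).

Count matrices are expected to be complete: missing values are rejected
rather than imputed, because silently imputed cells would bias every
downstream correlation.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized units tags for an expression matrix.
VALID_UNITS = ("raw_counts", "cpm", "log2cpm", "ratio")


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric expression matrix.

    Parameters
    ----------
    data:
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as the columns.  All values must be finite;
        ``raw_counts`` must additionally be non-negative.
    units:
        One of ``raw_counts``, ``cpm``, ``log2cpm``, ``ratio``.
    """

    data: pd.DataFrame
    units: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:10]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.units == "raw_counts" and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative raw count at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.units)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.units)


@dataclass
class SampleMetadata:
    """Sample-to-condition assignment.

    ``groups`` maps each sample identifier (index) to a condition label.
    """

    groups: pd.Series

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            dups = self.groups.index[self.groups.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dups[:10]}")
        self.groups = self.groups.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples(self, group: str) -> list[str]:
        """Sample identifiers belonging to ``group`` (input order preserved)."""
        if group not in set(self.groups):
            raise KeyError(f"unknown group label {group!r}; known: {self.group_labels}")
        return list(self.groups.index[self.groups == group])


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")


class GeneSetCollection(Mapping[str, GeneSet]):
    """An ordered collection of named gene sets keyed by term id."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.term_id in self._sets:
                raise ValueError(f"duplicate term id {s.term_id!r}")
            self._sets[s.term_id] = s

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _separator(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, orientation: str = "genes_in_rows", units: str = "raw_counts"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV (or CSV, by extension).

    The file must have one header row and identifiers in the first column.
    ``orientation='genes_in_columns'`` transposes on read, so the returned
    matrix is always genes x samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_separator(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value in {path.name} at row {row!r}, column {col!r}")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing value in {path.name} at row {row!r}, column {col!r}")
        df[col] = coerced
    if orientation == "genes_in_columns":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(df, units=units)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix (genes in rows) at full float precision."""
    path = Path(path)
    expr.data.to_csv(path, sep=_separator(path), index_label="gene_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column (sample_id, group) table with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep=_separator(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected two columns (sample_id, group)")
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample_id"))
    return SampleMetadata(series)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame({"sample_id": meta.groups.index, "group": meta.groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (term, description, tab-separated genes)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                raise ValueError(f"{path.name}:{lineno}: GMT line has no genes")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(term_id=fields[0], term_name=fields[1], genes=genes))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Pre-correlation transforms
# ---------------------------------------------------------------------------


def filter_expressed(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    groups: Sequence[str],
    min_mean_count: float = 1.0,
) -> ExpressionMatrix:
    """Keep genes whose mean raw count is >= ``min_mean_count`` in every group.

    This is the "expressed gene" criterion applied before any correlation:
    a gene must clear the threshold in *each* listed condition, so that its
    correlation profile is measured on comparable support in both groups of
    a comparison.  Gene order is preserved.
    """
    if expr.units != "raw_counts":
        raise ValueError(f"filter_expressed expects raw_counts, got units={expr.units!r}")
    keep = np.ones(expr.n_genes, dtype=bool)
    for group in groups:
        cols = meta.samples(group)
        keep &= expr.data[cols].mean(axis=1).to_numpy() >= min_mean_count
    return ExpressionMatrix(expr.data.loc[keep], expr.units)


def log_cpm(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(counts-per-million + pseudocount) transform.

    value = log2(count / library_size * 1e6 + pseudocount), per sample.
    """
    if expr.units != "raw_counts":
        raise ValueError(f"log_cpm expects raw_counts, got units={expr.units!r}")
    totals = expr.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = expr.data / totals * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount), units="log2cpm")


def reference_normalize(expr: ExpressionMatrix, reference_gene: str) -> ExpressionMatrix:
    """Express every gene as a per-sample ratio to a reference gene.

    Mirrors housekeeping-gene normalization (e.g. ratios to TBP): each value
    is divided by the reference gene's value in the same sample, so the
    reference row becomes all ones and the result has units ``ratio``.
    """
    if reference_gene not in expr.data.index:
        raise KeyError(f"reference gene {reference_gene!r} not present")
    ref = expr.data.loc[reference_gene]
    zero = ref[ref == 0]
    if len(zero):
        raise ValueError(
            f"reference gene {reference_gene!r} has zero expression in sample(s): "
            f"{list(zero.index)}"
        )
    return ExpressionMatrix(expr.data / ref, units="ratio")
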