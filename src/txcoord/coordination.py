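"""Condition-specific co-expression and the composite correlation (Pc) index.

The central quantity of the package.  Within one condition group, the
co-expression matrix holds the Pearson correlation of every gene with every
other gene across that group's samples.  For a pair of conditions A and B,
each gene's Pc is the Pearson correlation between its row of correlation
coefficients in A and the corresponding row in B (the gene's self-entry,
a constant 1, is excluded from both rows by default).  Pc near 1 means the
gene's co-expression profile is preserved between conditions; Pc near 0
means the profile is lost; negative Pc means it is inverted.

The gene x gene matrices are never required to be fully resident: rows of
correlations are produced in blocks from the standardized expression
matrices, so memory stays O(block x genes) for arbitrarily large gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, SampleMetadata, filter_expressed, log_cpm

logger = logging.getLogger(__name__)

_BOUND_TOL = 1e-12


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene Pearson correlation matrix for one group."""

    gene_ids: list[str]
    R: np.ndarray
    group: str
    n_samples: int

    def __post_init__(self) -> None:
        G = len(self.gene_ids)
        if self.R.shape != (G, G):
            raise ValueError(f"R has shape {self.R.shape}, expected ({G}, {G})")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("co-expression matrix contains non-finite entries")
        if np.max(np.abs(self.R - self.R.T)) > _BOUND_TOL:
            raise ValueError("co-expression matrix is not symmetric")
        if np.max(np.abs(self.R)) > 1 + _BOUND_TOL:
            raise ValueError("correlation coefficients outside [-1, 1]")


@dataclass
class PcTable:
    """Per-gene composite correlation for one pairwise group comparison.

    Undefined values (a gene whose correlation profile had zero variance in
    either group) are stored as NaN and excluded from summaries/selections.
    """

    gene_ids: list[str]
    pc: np.ndarray
    comparison: tuple[str, str]
    n_profile: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.pc):
            raise ValueError("one pc value per gene required")
        finite = self.pc[np.isfinite(self.pc)]
        if finite.size and np.max(np.abs(finite)) > 1 + _BOUND_TOL:
            raise ValueError("pc values outside [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of genes with a defined (non-sentinel) Pc."""
        return np.isfinite(self.pc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "pc": self.pc,
                "comparison": f"{self.comparison[0]}_vs_{self.comparison[1]}",
            }
        )

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PcTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        a, _, b = str(df["comparison"].iloc[0]).partition("_vs_")
        return cls(
            gene_ids=list(df["gene_id"]),
            pc=df["pc"].to_numpy(dtype=float),
            comparison=(a, b),
            n_profile=len(df) - 1,
        )


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def drop_degenerate(
    expr: ExpressionMatrix, meta: SampleMetadata, groups: Sequence[str]
) -> ExpressionMatrix:
    """Remove genes with zero variance within any of the listed groups.

    A constant gene has no defined correlation with anything, so it cannot
    enter a co-expression matrix.  Removed gene ids are logged.
    """
    keep = np.ones(expr.n_genes, dtype=bool)
    for group in groups:
        sub = expr.data[meta.samples(group)].to_numpy(dtype=float)
        keep &= sub.std(axis=1) > 0
    removed = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if removed:
        logger.info(
            "drop_degenerate: removed %d constant gene(s) in groups %s: %s%s",
            len(removed),
            list(groups),
            removed[:10],
            "..." if len(removed) > 10 else "",
        )
    return ExpressionMatrix(expr.data.loc[keep], expr.units)


def _profile_units(values: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Center and L2-normalize each gene row so that U @ U.T is the
    correlation matrix.  ``method='spearman'`` ranks within each gene first."""
    X = np.asarray(values, dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance gene encountered; run drop_degenerate first")
    return Xc / norms


def compute_coexpression(
    expr: ExpressionMatrix, group: str = "", method: str = "pearson"
) -> CoexpressionMatrix:
    """Pearson correlation of every gene with every other gene in one group.

    ``expr`` must already be restricted to the group's samples; at least 3
    samples are required and every gene must vary across them.
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.n_samples}")
    values = expr.values
    constant = [g for g, s in zip(expr.gene_ids, values.std(axis=1)) if s == 0]
    if constant:
        raise ValueError(f"zero-variance gene(s): {constant[:10]}; run drop_degenerate first")
    U = _profile_units(values, method=method)
    R = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CoexpressionMatrix(
        gene_ids=expr.gene_ids, R=R, group=group, n_samples=expr.n_samples
    )


def _rowwise_pc(
    RA: np.ndarray,
    RB: np.ndarray,
    diag_offset: int | None,
) -> np.ndarray:
    """Pearson correlation of corresponding rows of RA and RB.

    ``diag_offset`` gives the column index of row 0's self-entry; the
    self-entries are excluded from the profile sums.  ``None`` keeps them
    (include-self mode).  Rows whose profile has zero variance yield NaN.
    """
    n_rows, G = RA.shape
    sa = RA.sum(axis=1)
    sb = RB.sum(axis=1)
    saa = np.einsum("ij,ij->i", RA, RA)
    sbb = np.einsum("ij,ij->i", RB, RB)
    sab = np.einsum("ij,ij->i", RA, RB)
    if diag_offset is not None:
        idx = np.arange(n_rows)
        da = RA[idx, diag_offset + idx]
        db = RB[idx, diag_offset + idx]
        sa = sa - da
        sb = sb - db
        saa = saa - da * da
        sbb = sbb - db * db
        sab = sab - da * db
        m = G - 1
    else:
        m = G
    cov = sab - sa * sb / m
    va = saa - sa * sa / m
    vb = sbb - sb * sb / m
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = cov / np.sqrt(va * vb)
    degenerate = (va <= _BOUND_TOL * m) | (vb <= _BOUND_TOL * m)
    pc = np.where(degenerate, np.nan, np.clip(pc, -1.0, 1.0))
    return pc


def pc_index(
    coexA: CoexpressionMatrix,
    coexB: CoexpressionMatrix,
    exclude_self: bool = True,
) -> PcTable:
    """Composite correlation of each gene's co-expression profile in A vs B.

    The two matrices are aligned on their common genes (order of A).  For a
    gene g, Pc(g) is the Pearson correlation between row g of A and row g of
    B over the common genes, excluding g's self-entry by default.
    """
    in_b = set(coexB.gene_ids)
    common = [g for g in coexA.gene_ids if g in in_b]
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} genes common to both matrices; need >= 4 "
            "(profile vectors need >= 3 entries after self-exclusion)"
        )
    pos_a = {g: i for i, g in enumerate(coexA.gene_ids)}
    pos_b = {g: i for i, g in enumerate(coexB.gene_ids)}
    ia = np.fromiter((pos_a[g] for g in common), dtype=int)
    ib = np.fromiter((pos_b[g] for g in common), dtype=int)
    RA = coexA.R[np.ix_(ia, ia)]
    RB = coexB.R[np.ix_(ib, ib)]
    pc = _rowwise_pc(RA, RB, diag_offset=0 if exclude_self else None)
    n_undef = int(np.sum(~np.isfinite(pc)))
    if n_undef:
        logger.info("pc_index: %d gene(s) with undefined Pc (zero-variance profile)", n_undef)
    return PcTable(
        gene_ids=common,
        pc=pc,
        comparison=(coexA.group, coexB.group),
        n_profile=len(common) - (1 if exclude_self else 0),
    )


def _pc_from_units(
    UA: np.ndarray,
    UB: np.ndarray,
    exclude_self: bool = True,
    block_size: int = 2048,
) -> np.ndarray:
    """Blockwise Pc: correlation rows are produced block by block from the
    standardized matrices, never materializing either full G x G matrix."""
    G = UA.shape[0]
    out = np.empty(G)
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        RA = np.clip(UA[start:stop] @ UA.T, -1.0, 1.0)
        RB = np.clip(UB[start:stop] @ UB.T, -1.0, 1.0)
        rows = np.arange(stop - start)
        RA[rows, start + rows] = 1.0
        RB[rows, start + rows] = 1.0
        out[start:stop] = _rowwise_pc(RA, RB, diag_offset=start if exclude_self else None)
    return out


def pairwise_pc(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    *,
    transform: str = "log2cpm",
    pseudocount: float = 1.0,
    min_mean_count: float = 1.0,
    exclude_self: bool = True,
    method: str = "pearson",
    block_size: int = 2048,
) -> PcTable:
    """Full pairwise coordination analysis between two condition groups.

    Composition of the stages: expression filtering (raw-count mean >=
    ``min_mean_count`` in both groups) -> transform (``log2cpm`` default,
    ``none`` to correlate the input values as given) -> removal of
    within-group constant genes -> per-group co-expression -> Pc.
    Deterministic given inputs and settings; computed in row blocks.
    """
    groups = [group_a, group_b]
    if expr.units == "raw_counts":
        work = filter_expressed(expr, meta, groups, min_mean_count=min_mean_count)
        if transform == "log2cpm":
            work = log_cpm(work, pseudocount=pseudocount)
        elif transform not in ("none", "raw"):
            raise ValueError(f"unknown transform {transform!r}")
    else:
        # already-transformed matrix supplied by the caller: use as-is
        work = expr
    work = drop_degenerate(work, meta, groups)
    if work.n_genes < 4:
        raise ValueError(f"only {work.n_genes} genes survive filtering; need >= 4")
    sub_a = work.subset_samples(meta.samples(group_a))
    sub_b = work.subset_samples(meta.samples(group_b))
    for label, sub in ((group_a, sub_a), (group_b, sub_b)):
        if sub.n_samples < 3:
            raise ValueError(f"group {label!r} has {sub.n_samples} samples; need >= 3")
    UA = _profile_units(sub_a.values, method=method)
    UB = _profile_units(sub_b.values, method=method)
    pc = _pc_from_units(UA, UB, exclude_self=exclude_self, block_size=block_size)
    n_undef = int(np.sum(~np.isfinite(pc)))
    if n_undef:
        logger.info("pairwise_pc %s vs %s: %d undefined Pc value(s)", group_a, group_b, n_undef)
    return PcTable(
        gene_ids=work.gene_ids,
        pc=pc,
        comparison=(group_a, group_b),
        n_profile=work.n_genes - (1 if exclude_self else 0),
    )


def summarize_pc(table: PcTable) -> dict[str, float]:
    """Mean, median, sd, quartiles and counts of the defined Pc values."""
    vals = table.pc[table.defined]
    if vals.size == 0:
        raise ValueError("no defined Pc values to summarize")
    return {
        "comparison": f"{table.comparison[0]}_vs_{table.comparison[1]}",
        "n": int(vals.size),
        "n_undefined": int(table.pc.size - vals.size),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
    }


# ---------------------------------------------------------------------------
# Estimator interface
# ---------------------------------------------------------------------------


class CoordinationAnalysis(BaseEstimator):
    """Scikit-learn style front end to the pairwise coordination analysis.

    ``fit(X, y)`` takes samples-in-rows expression (ndarray or DataFrame,
    samples x genes, raw counts by default) and a condition label per sample,
    and computes a :class:`PcTable` for every pair of conditions, in the
    order the labels first appear.

    Parameters
    ----------
    transform : {"log2cpm", "none"}, default "log2cpm"
        Pre-correlation transform applied to raw counts.
    pseudocount : float, default 1.0
        Added inside the log2 for the CPM transform.
    min_mean_count : float, default 1.0
        "Expressed" threshold: per-group mean raw count required of a gene.
    exclude_self : bool, default True
        Drop each gene's self-correlation entry from its profile vectors.
    method : {"pearson", "spearman"}, default "pearson"
    units : str, default "raw_counts"
        Units tag of X; non-raw inputs skip filtering and transform.
    block_size : int, default 2048
        Row-block size for the streaming correlation computation.

    Attributes
    ----------
    groups_ : list of condition labels in order of first appearance.
    comparisons_ : list of (group_a, group_b) pairs analyzed.
    pc_tables_ : dict mapping each pair to its PcTable.
    summaries_ : dict mapping each pair to its Pc summary statistics.
    n_features_in_, feature_names_in_ : standard fitted metadata.
    """

    def __init__(
        self,
        transform: str = "log2cpm",
        pseudocount: float = 1.0,
        min_mean_count: float = 1.0,
        exclude_self: bool = True,
        method: str = "pearson",
        units: str = "raw_counts",
        block_size: int = 2048,
    ):
        self.transform = transform
        self.pseudocount = pseudocount
        self.min_mean_count = min_mean_count
        self.exclude_self = exclude_self
        self.method = method
        self.units = units
        self.block_size = block_size

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            data = X.T.copy()
            data.index = data.index.astype(str)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples x genes)")
            width = len(str(X.shape[1]))
            data = pd.DataFrame(
                X.T, index=[f"g{i:0{width}d}" for i in range(X.shape[1])]
            )
        data.columns = [str(c) for c in data.columns]
        y = np.asarray(y)
        if len(y) != data.shape[1]:
            raise ValueError(f"y has {len(y)} labels for {data.shape[1]} samples")
        expr = ExpressionMatrix(data, units=self.units)
        meta = SampleMetadata(pd.Series([str(v) for v in y], index=data.columns))
        self.groups_ = meta.group_labels
        if len(self.groups_) < 2:
            raise ValueError("need at least two condition groups")
        self.comparisons_ = [
            (a, b)
            for i, a in enumerate(self.groups_)
            for b in self.groups_[i + 1 :]
        ]
        self.pc_tables_ = {}
        self.summaries_ = {}
        for a, b in self.comparisons_:
            table = pairwise_pc(
                expr,
                meta,
                a,
                b,
                transform=self.transform,
                pseudocount=self.pseudocount,
                min_mean_count=self.min_mean_count,
                exclude_self=self.exclude_self,
                method=self.method,
                block_size=self.block_size,
            )
            self.pc_tables_[(a, b)] = table
            self.summaries_[(a, b)] = summarize_pc(table)
        self.n_features_in_ = data.shape[0]
        self.feature_names_in_ = np.asarray(data.index)
        return self

    def pc_frame(self) -> pd.DataFrame:
        """All fitted Pc tables concatenated into one long DataFrame."""
        if not hasattr(self, "pc_tables_"):
            raise AttributeError("CoordinationAnalysis is not fitted yet")
        return pd.concat([t.to_frame() for t in self.pc_tables_.values()], ignore_index=True)
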