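"""Gene-set over-representation and Pc distribution statistics.

Over-representation uses the one-sided Fisher exact test (hypergeometric
upper tail) against a caller-supplied background — by convention the genes
actually analyzed in the corresponding coordination comparison, not the
whole annotation universe — with Benjamini-Hochberg FDR across the reported
terms.  Pc distributions across comparisons are compared by ordinary
one-way ANOVA followed by Tukey-Kramer honestly-significant-difference
tests (unequal group sizes supported).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coordination import PcTable
from .io import GeneSetCollection


@dataclass
class EnrichmentResult:
    """One gene-set term's over-representation statistics.

    k of n study genes and K of N background genes carry the annotation;
    fold_enrichment = (k/n)/(K/N).
    """

    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_raw: float
    fdr: float


@dataclass
class AnovaTukeyResult:
    F: float
    df_between: int
    df_within: int
    p: float
    #: (group_a, group_b, mean_a - mean_b, Tukey-adjusted p) for every pair
    pairwise: list[tuple[str, str, float, float]]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """One-sided over-representation of each gene set in the study list.

    Term gene lists are intersected with the background before counting, so
    annotations outside the surveyed transcriptome do not dilute the test.
    p_raw is the hypergeometric upper tail P(X >= k); FDR is BH across all
    reported terms.  Terms with fewer than ``min_term_size`` background
    genes are skipped.  Results are sorted by raw p, ties by term id.
    """
    study_set = set(study)
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    stray = study_set - bg
    if stray:
        raise ValueError(
            f"{len(stray)} study gene(s) not in background: {sorted(stray)[:10]}"
        )
    N = len(bg)
    n = len(study_set)
    rows: list[EnrichmentResult] = []
    for term in sets.values():
        annotated = term.genes & bg
        K = len(annotated)
        if K < max(min_term_size, 1):
            continue
        k = len(annotated & study_set)
        fold = (k * N) / (n * K) if n and K else 0.0
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                k=k,
                n=n,
                K=K,
                N=N,
                fold_enrichment=fold,
                p_raw=min(p_raw, 1.0),
                fdr=np.nan,
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    if rows:
        fdrs = bh_fdr([r.p_raw for r in rows])
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
    return rows


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "raw_p": [r.p_raw for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


def write_enrichment(
    results: list[EnrichmentResult], path: str | Path, float_format: str = "%.6g"
) -> None:
    enrichment_to_frame(results).to_csv(path, sep="\t", index=False, float_format=float_format)


def compare_pc_groups(
    tables: Sequence[PcTable | np.ndarray], labels: Sequence[str] | None = None
) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey-Kramer HSD over Pc value distributions.

    Each table's defined Pc values form one group.  Raw arrays are accepted
    for convenience; labels default to the tables' comparison names.
    """
    groups: list[np.ndarray] = []
    names: list[str] = []
    for i, t in enumerate(tables):
        if isinstance(t, PcTable):
            vals = t.pc[t.defined]
            name = f"{t.comparison[0]}_vs_{t.comparison[1]}"
        else:
            vals = np.asarray(t, dtype=float)
            vals = vals[np.isfinite(vals)]
            name = f"group{i}"
        if vals.size < 2:
            raise ValueError(f"group {name!r} has {vals.size} value(s); need >= 2")
        groups.append(vals)
        names.append(name)
    if labels is not None:
        if len(labels) != len(groups):
            raise ValueError("one label per group required")
        names = list(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):  # identical constant groups: no variance anywhere
        F, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*groups)
    pairwise = [
        (
            names[i],
            names[j],
            float(np.mean(groups[i]) - np.mean(groups[j])),
            float(hsd.pvalue[i, j]),
        )
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    total = sum(g.size for g in groups)
    return AnovaTukeyResult(
        F=float(max(F, 0.0)),
        df_between=len(groups) - 1,
        df_within=total - len(groups),
        p=float(p),
        pairwise=pairwise,
    )
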