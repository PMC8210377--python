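"""Cumulative Pc and the two gene-selection rules feeding enrichment.

Two selections are supported: genes whose coordination profile is inverted
in a single comparison (Pc strictly below a threshold, default -0.2), and
the top fraction (default 5%) of genes by cumulative Pc summed over the
three pairwise comparisons on their common gene set.  All orderings are
deterministic: ties are broken lexicographically by gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coordination import PcTable


@dataclass
class CumulativePcTable:
    """Per-gene sum of Pc over three pairwise comparisons (common genes)."""

    gene_ids: list[str]
    cum_pc: np.ndarray
    constituent_comparisons: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.cum_pc):
            raise ValueError("one cumulative value per gene required")
        k = len(self.constituent_comparisons)
        if np.max(np.abs(self.cum_pc), initial=0.0) > k + 1e-12:
            raise ValueError(f"cumulative Pc outside [-{k}, {k}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "cum_pc": self.cum_pc})

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)


def cumulative_pc(pc1: PcTable, pc2: PcTable, pc3: PcTable) -> CumulativePcTable:
    """Elementwise sum of three Pc tables on their common, defined genes.

    Genes absent from any table — or with an undefined (sentinel) Pc in any
    table — are excluded.  Gene order follows the first table.  The result
    is invariant to argument order up to gene ordering.
    """
    tables = [pc1, pc2, pc3]
    comparisons = [t.comparison for t in tables]
    if len(set(comparisons)) != 3:
        raise ValueError(f"expected three distinct comparisons, got {comparisons}")
    maps = [
        {g: v for g, v, ok in zip(t.gene_ids, t.pc, t.defined) if ok} for t in tables
    ]
    common = [g for g in pc1.gene_ids if all(g in m for m in maps)]
    if not common:
        raise ValueError("no genes common to all three comparisons")
    total = np.array([maps[0][g] + maps[1][g] + maps[2][g] for g in common])
    return CumulativePcTable(
        gene_ids=common, cum_pc=total, constituent_comparisons=comparisons
    )


def select_decoordinated(pc: PcTable, threshold: float = -0.2) -> list[str]:
    """Genes with Pc strictly below ``threshold``, most de-coordinated first.

    The boundary value is excluded (strict ``<``).  Output is sorted by
    ascending Pc, ties by gene id; may be empty.
    """
    picked = [
        (v, g) for g, v, ok in zip(pc.gene_ids, pc.pc, pc.defined) if ok and v < threshold
    ]
    picked.sort(key=lambda t: (t[0], t[1]))
    return [g for _, g in picked]


def select_top_fraction(cum: CumulativePcTable, fraction: float = 0.05) -> list[str]:
    """The floor(fraction * n) genes with the highest cumulative Pc.

    Returned in descending cumulative-Pc order; ties (including at the
    cutoff) are broken lexicographically by gene id so the selection is
    reproducible across platforms.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(cum.gene_ids)
    k = math.floor(fraction * n)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {n} genes selects nothing; "
            "increase the fraction or supply more genes"
        )
    ranked = sorted(zip(cum.cum_pc, cum.gene_ids), key=lambda t: (-t[0], t[1]))
    return [g for _, g in ranked[:k]]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    """One gene id per line."""
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def write_gene_list_tsv(
    genes: list[str],
    values: dict[str, float],
    path: str | Path,
    value_column: str = "pc",
    float_format: str = "%.6g",
) -> None:
    """Gene list with its selection statistic as a two-column TSV."""
    pd.DataFrame({"gene_id": genes, value_column: [values[g] for g in genes]}).to_csv(
        path, sep="\t", index=False, float_format=float_format
    )
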