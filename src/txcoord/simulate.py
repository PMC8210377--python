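"""Synthetic expression datasets with known coordination ground truth.

Genes are organized into co-expression modules via a latent-factor model:
each sample draws one standard-normal factor per module, and a module gene's
log-scale signal is ``loading * factor + noise``.  Background genes are pure
noise.  "Rewiring" a module in one condition group replaces the shared
module factor with an independent per-gene factor in that group only, which
destroys the genes' mutual correlation there — the ground truth for
de-coordination — while leaving their marginal distribution unchanged.
Signals scale a per-gene base mean multiplicatively and are mapped to
counts either deterministically (rounded log-normal means, the fast
default) or through a negative-binomial draw for overdispersed realism.

The defaults emulate the study design this package targets: three condition
groups (control plus two treatment outcomes) with 6/5/5 animals, a few
thousand genes, and more extensive rewiring in the group with overt
pathology than in the treated-but-unaffected group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coordination import PcTable
from .io import ExpressionMatrix, SampleMetadata

BACKGROUND = -1  # module index of genes outside every module


def _default_groups() -> dict[str, int]:
    return {"C": 6, "S": 5, "NS": 5}


def _default_rewired() -> dict[str, frozenset[int]]:
    return {"S": frozenset({0, 1, 2, 3}), "NS": frozenset({0, 1})}


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults model a three-arm study (6/5/5 samples) of ~2000 genes with 10
    modules of 50 genes; treatment group "S" rewires four modules and "NS"
    two, a graded loss of coordination relative to control "C".
    """

    n_genes: int = 2000
    n_modules: int = 10
    module_sizes: Sequence[int] | None = None  # default: 50 genes each
    groups: Mapping[str, int] = field(default_factory=_default_groups)
    rewired_modules: Mapping[str, frozenset[int]] = field(default_factory=_default_rewired)
    loading_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.4
    count_model: str = "lognormal_counts"
    nb_dispersion: float = 10.0
    base_mean_range: tuple[float, float] = (20.0, 200.0)
    seed: int | None = None

    def resolved_module_sizes(self) -> list[int]:
        if self.module_sizes is None:
            return [50] * self.n_modules
        return list(self.module_sizes)

    def validate(self) -> None:
        sizes = self.resolved_module_sizes()
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory for reproducibility")
        if self.n_genes < 1 or self.n_modules < 0:
            raise ValueError("n_genes must be >= 1 and n_modules >= 0")
        if len(sizes) != self.n_modules:
            raise ValueError(f"{len(sizes)} module sizes for {self.n_modules} modules")
        if any(s < 2 for s in sizes):
            raise ValueError("every module needs >= 2 genes")
        if sum(sizes) > self.n_genes:
            raise ValueError(f"module sizes sum to {sum(sizes)} > n_genes={self.n_genes}")
        if not self.groups:
            raise ValueError("at least one group required")
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("every group needs >= 1 sample")
        for grp, mods in self.rewired_modules.items():
            if grp not in self.groups:
                raise ValueError(f"rewired_modules references unknown group {grp!r}")
            bad = [m for m in mods if not 0 <= m < self.n_modules]
            if bad:
                raise ValueError(f"invalid module indices for group {grp!r}: {bad}")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must satisfy 0 < lo <= hi <= 1")
        if self.noise_sd <= 0 or self.nb_dispersion <= 0:
            raise ValueError("noise_sd and nb_dispersion must be positive")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")
        if self.count_model not in ("lognormal_counts", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``module`` maps gene id -> module index (-1 for background genes);
    ``rewired`` maps group label -> the set of module indices rewired there.
    """

    module: pd.Series
    rewired: dict[str, frozenset[int]]

    def rewired_mask(self, group_a: str, group_b: str) -> np.ndarray:
        """True for module genes whose module is rewired in either group."""
        affected = self.rewired.get(group_a, frozenset()) | self.rewired.get(
            group_b, frozenset()
        )
        return self.module.isin(list(affected)).to_numpy()

    def module_mask(self) -> np.ndarray:
        return (self.module.to_numpy() != BACKGROUND)

    def to_frame(self) -> pd.DataFrame:
        flags = [
            ",".join(sorted(g for g, mods in self.rewired.items() if m in mods))
            for m in self.module
        ]
        return pd.DataFrame(
            {
                "gene_id": self.module.index,
                "module": self.module.to_numpy(),
                "rewired_in_groups": flags,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Draw one complete dataset (counts, metadata, truth) from ``cfg``.

    Fully reproducible: a single generator stream seeded from ``cfg.seed``
    governs every draw, and repeated calls with the same config yield
    bitwise-identical matrices.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.resolved_module_sizes()
    G = cfg.n_genes

    module_of = np.full(G, BACKGROUND, dtype=int)
    pos = 0
    for m, size in enumerate(sizes):
        module_of[pos : pos + size] = m
        pos += size

    width = max(4, len(str(G)))
    gene_ids = [f"g{i:0{width}d}" for i in range(G)]
    loadings = rng.uniform(*cfg.loading_range, size=G)
    log_lo, log_hi = np.log(cfg.base_mean_range[0]), np.log(cfg.base_mean_range[1])
    base_mean = np.exp(rng.uniform(log_lo, log_hi, size=G))

    columns: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    for group, n_samples in cfg.groups.items():
        rewired = cfg.rewired_modules.get(group, frozenset())
        for s in range(n_samples):
            factors = rng.standard_normal(cfg.n_modules)
            own_factor = rng.standard_normal(G)  # used only where rewired
            noise = rng.normal(0.0, cfg.noise_sd, size=G)
            signal = noise.copy()
            in_module = module_of != BACKGROUND
            shared = factors[np.where(in_module, module_of, 0)]
            use_own = in_module & np.isin(module_of, list(rewired))
            factor_value = np.where(use_own, own_factor, shared)
            signal[in_module] += loadings[in_module] * factor_value[in_module]
            mean = base_mean * np.exp(signal)
            if cfg.count_model == "lognormal_counts":
                counts = np.rint(mean)
            else:
                r = cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
            sid = f"{group}_{s + 1:02d}"
            columns[sid] = counts
            sample_groups[sid] = group

    data = pd.DataFrame(columns, index=gene_ids)
    expr = ExpressionMatrix(data, units="raw_counts")
    meta = SampleMetadata(pd.Series(sample_groups, index=list(columns)))
    truth = SyntheticTruth(
        module=pd.Series(module_of, index=gene_ids),
        rewired={g: frozenset(m) for g, m in cfg.rewired_modules.items()},
    )
    return expr, meta, truth


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Probability that a positive-class score exceeds a negative-class score,
    counting ties as half.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def truth_recovery_report(
    pc: PcTable, truth: SyntheticTruth
) -> dict[str, float]:
    """How well low Pc recovers the rewired modules of ``pc``'s comparison.

    Positives are module genes whose module is rewired in either compared
    group; negatives are the remaining (preserved) module genes.  Returns
    the AUROC of ranking genes by -Pc plus mean Pc per class.
    """
    group_a, group_b = pc.comparison
    aligned = truth.module.reindex(pc.gene_ids)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()])[:5]
        raise ValueError(f"genes absent from truth: {missing}")
    rewired = truth.rewired_mask(group_a, group_b)[
        truth.module.index.get_indexer(pc.gene_ids)
    ]
    in_module = aligned.to_numpy() != BACKGROUND
    ok = pc.defined
    pos = pc.pc[ok & in_module & rewired]
    neg = pc.pc[ok & in_module & ~rewired]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both rewired and preserved module genes to score recovery")
    report = {
        "auroc": auroc(-pos, -neg),
        "n_rewired": int(pos.size),
        "n_preserved": int(neg.size),
        "mean_pc_rewired": float(np.mean(pos)),
        "mean_pc_preserved": float(np.mean(neg)),
    }
    bg = pc.pc[ok & ~in_module]
    if bg.size:
        report["mean_pc_background"] = float(np.mean(bg))
        report["n_background"] = int(bg.size)
    return report
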