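"""End-to-end coordination workflow driven by a YAML config.

Runs: expression filtering -> transform -> per-group co-expression -> the
three pairwise Pc tables -> distribution summaries and ANOVA/Tukey ->
cumulative Pc -> both gene selections -> over-representation per selection,
and writes every table plus a JSON run report.  The run is deterministic:
the same config and inputs produce byte-identical outputs (timestamps go
only to the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import coordination, enrichment, io, selection

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression: str
    metadata: str
    gmt: str
    outdir: str
    groups: list[str] = field(default_factory=lambda: ["C", "S", "NS"])
    comparisons: list[tuple[str, str]] | None = None
    transform: str = "log2cpm"
    pseudocount: float = 1.0
    min_mean_count: float = 1.0
    decoordination_threshold: float = -0.2
    top_fraction: float = 0.05
    min_term_size: int = 2
    exclude_self: bool = True
    method: str = "pearson"
    block_size: int = 2048
    orientation: str = "genes_in_rows"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.comparisons is None:
            self.comparisons = [
                (a, b)
                for i, a in enumerate(self.groups)
                for b in self.groups[i + 1 :]
            ]
        self.comparisons = [tuple(c) for c in self.comparisons]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"expression", "metadata", "gmt", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("expression", "metadata", "gmt"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"config {key}: no such file {p}")
        declared = set(self.groups)
        for a, b in self.comparisons:
            if a not in declared or b not in declared:
                raise ValueError(
                    f"comparison ({a!r}, {b!r}) references undeclared group; "
                    f"declared: {sorted(declared)}"
                )
            if a == b:
                raise ValueError(f"comparison pairs two identical groups: {a!r}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")


def common_genes_report(tables: Sequence[coordination.PcTable]) -> dict:
    """Per-comparison gene counts and the size of their intersection."""
    per_table = {
        f"{t.comparison[0]}_vs_{t.comparison[1]}": len(t.gene_ids) for t in tables
    }
    sets = [set(t.gene_ids) for t in tables]
    common = set.intersection(*sets) if sets else set()
    return {"per_comparison": per_table, "n_common": len(common)}


def _pair_tag(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written as JSON)."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        expr = io.read_expression(cfg.expression, orientation=cfg.orientation)
        meta = io.read_metadata(cfg.metadata)
        gene_sets = io.read_gmt(cfg.gmt)
        logger.info(
            "inputs: %d genes x %d samples; %d gene sets",
            expr.n_genes, expr.n_samples, len(gene_sets),
        )
        known = set(meta.group_labels)
        undeclared = [g for g in cfg.groups if g not in known]
        if undeclared:
            raise ValueError(f"groups {undeclared} not present in metadata")

        report: dict = {"config": dataclasses.asdict(cfg), "outputs": {}, "summaries": {}}
        tables: list[coordination.PcTable] = []
        for pair in cfg.comparisons:
            stage = f"pairwise Pc {_pair_tag(pair)}"
            table = coordination.pairwise_pc(
                expr,
                meta,
                *pair,
                transform=cfg.transform,
                pseudocount=cfg.pseudocount,
                min_mean_count=cfg.min_mean_count,
                exclude_self=cfg.exclude_self,
                method=cfg.method,
                block_size=cfg.block_size,
            )
            tables.append(table)
            path = outdir / f"pc_{_pair_tag(pair)}.tsv"
            table.to_tsv(path, float_format=FLOAT_FORMAT)
            report["outputs"][f"pc_{_pair_tag(pair)}"] = str(path)
            report["summaries"][_pair_tag(pair)] = coordination.summarize_pc(table)
            logger.info("%s: %d genes, mean Pc %.4f", _pair_tag(pair),
                        len(table.gene_ids), report["summaries"][_pair_tag(pair)]["mean"])

        stage = "common genes"
        report["common_genes"] = common_genes_report(tables)

        stage = "ANOVA / Tukey"
        if len(tables) >= 2:
            aov = enrichment.compare_pc_groups(tables)
            report["anova"] = {
                "F": aov.F,
                "p": aov.p,
                "df_between": aov.df_between,
                "df_within": aov.df_within,
                "tukey": [
                    {"pair": [a, b], "mean_diff": d, "p_adj": p}
                    for a, b, d, p in aov.pairwise
                ],
            }

        selections: dict[str, tuple[list[str], set[str]]] = {}
        for table in tables:
            tag = _pair_tag(table.comparison)
            stage = f"de-coordinated selection {tag}"
            genes = selection.select_decoordinated(table, cfg.decoordination_threshold)
            path = outdir / f"decoordinated_{tag}.txt"
            selection.write_gene_list(genes, path)
            values = dict(zip(table.gene_ids, table.pc))
            selection.write_gene_list_tsv(
                genes, values, outdir / f"decoordinated_{tag}.tsv", value_column="pc"
            )
            report["outputs"][f"decoordinated_{tag}"] = str(path)
            report.setdefault("n_decoordinated", {})[tag] = len(genes)
            background = {g for g, ok in zip(table.gene_ids, table.defined) if ok}
            selections[f"decoordinated_{tag}"] = (genes, background)

        stage = "cumulative Pc"
        if len(tables) == 3:
            cum = selection.cumulative_pc(*tables)
            cum.to_tsv(outdir / "cumulative_pc.tsv", float_format=FLOAT_FORMAT)
            report["outputs"]["cumulative_pc"] = str(outdir / "cumulative_pc.tsv")
            report["n_cumulative_genes"] = len(cum.gene_ids)
            top = selection.select_top_fraction(cum, cfg.top_fraction)
            selection.write_gene_list(top, outdir / "top_fraction.txt")
            selection.write_gene_list_tsv(
                top,
                dict(zip(cum.gene_ids, cum.cum_pc)),
                outdir / "top_fraction.tsv",
                value_column="cum_pc",
            )
            report["outputs"]["top_fraction"] = str(outdir / "top_fraction.txt")
            report["n_top_fraction"] = len(top)
            selections["top_fraction"] = (top, set(cum.gene_ids))

        for name, (genes, background) in selections.items():
            stage = f"enrichment {name}"
            if not genes:
                logger.info("enrichment %s skipped: empty selection", name)
                continue
            results = enrichment.fisher_enrichment(
                genes, background, gene_sets, min_term_size=cfg.min_term_size
            )
            path = outdir / f"enrichment_{name}.tsv"
            enrichment.write_enrichment(results, path, float_format=FLOAT_FORMAT)
            report["outputs"][f"enrichment_{name}"] = str(path)
            report.setdefault("n_enriched_fdr05", {})[name] = int(
                sum(r.fdr < 0.05 for r in results)
            )

        stage = "write report"
        report_path = outdir / "report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        report["outputs"]["report"] = str(report_path)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
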