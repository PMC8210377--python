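# txcoord — whole-transcriptome expression-coordination analysis

Differential expression finds genes whose *level* changes between
conditions. `txcoord` instead asks whether a gene's *relationships* change:
for each gene it compares the vector of Pearson correlations with every
other gene in the transcriptome, computed separately in each condition
group, and summarizes the change in one number per gene. The approach is
aimed at bulk (or pseudo-bulk) RNA-seq studies of genetically diverse
cohorts — for example outbred rodent models of fatty-liver disease with a
control group and two diet-response groups — where inter-individual
variability masks level changes but leaves co-expression structure
measurable.

## The statistic

Within a condition group *g* with expression matrix restricted to that
group's samples, the co-expression matrix is

&nbsp;&nbsp;&nbsp;&nbsp;R⁽ᵍ⁾ᵢⱼ = corr(xᵢ, xⱼ)  (Pearson, across the group's samples).

For a pair of groups (A, B), each gene *i*'s **composite correlation
index** is the correlation of its correlation profiles,

&nbsp;&nbsp;&nbsp;&nbsp;Pc(i) = corr( R⁽ᴬ⁾ᵢ,₋ᵢ , R⁽ᴮ⁾ᵢ,₋ᵢ ),

where *−i* excludes the gene's self-entry (a constant 1 in both profiles).
Pc ≈ 1 means the gene keeps its co-expression partners across conditions;
Pc ≈ 0 means the profile is lost; Pc < 0 means it is inverted. Downstream,
genes with Pc < −0.2 in a comparison form the "de-coordinated" selection,
the per-gene sum of Pc over the three pairwise comparisons (on their common
genes) is the cumulative Pc, whose top 5% forms the "retained coordination"
selection, and both selections feed a one-sided Fisher over-representation
test with Benjamini–Hochberg FDR against the background of genes actually
analyzed. Pc distributions across comparisons are compared by one-way ANOVA
with Tukey–Kramer HSD.

A latent-factor count simulator with known module structure and per-group
"rewiring" (ground-truth de-coordination) makes the whole pipeline testable
without any external data.

## Worked example

```python
import json
from txcoord import (SimConfig, generate_dataset, pairwise_pc,
                     summarize_pc, truth_recovery_report)

cfg = SimConfig(n_genes=200, n_modules=10, module_sizes=[20] * 10,
                groups={"C": 30, "S": 30},
                rewired_modules={"S": frozenset({0, 1})}, seed=42)
expr, meta, truth = generate_dataset(cfg)          # counts, labels, truth
table = pairwise_pc(expr, meta, "C", "S")          # per-gene Pc
print(json.dumps(summarize_pc(table), indent=2))
print(json.dumps(truth_recovery_report(table, truth), indent=2))
```

Output:

```
{
  "comparison": "C_vs_S",
  "n": 200,
  "n_undefined": 0,
  "mean": 0.6025553672899305,
  "median": 0.7308408219857419,
  "sd": 0.3000561133495748,
  "q1": 0.5995548722102899,
  "q3": 0.804399346761709
}
{
  "auroc": 0.99984375,
  "n_rewired": 40,
  "n_preserved": 160,
  "mean_pc_rewired": 0.03358422666205247,
  "mean_pc_preserved": 0.7447981524469001
}
```

Most genes keep high Pc (mean 0.60, median 0.73): their co-expression
profiles are preserved between the groups. The 40 genes of the two modules
rewired in group "S" collapse to Pc ≈ 0.03 — their correlation structure in
"S" is gone — and ranking genes by −Pc recovers them almost perfectly
(AUROC 0.9998).

A scikit-learn style front end is available for samples×genes input:

```python
from txcoord import CoordinationAnalysis
est = CoordinationAnalysis(min_mean_count=1.0).fit(expr.data.T, meta.groups)
est.summaries_[("C", "S")]["mean"]   # same statistic, estimator interface
```

## Command line

```sh
txcoord simulate --seed 7 --out-dir data/            # synthetic study
txcoord coordinate --expression data/expression.tsv \
    --metadata data/metadata.tsv --group-a C --group-b S --out pc.tsv
txcoord run --config run.yaml                        # full pipeline
txcoord enrich --study genes.txt --background bg.txt --gmt sets.gmt --out enr.tsv
txcoord report pc_*.tsv                              # summaries + ANOVA
```

The `run` verb executes the full study workflow from a YAML config
(expression/metadata/GMT paths, groups, the three comparisons, thresholds)
and writes the three Pc tables, the cumulative-Pc table, both gene
selections, per-selection enrichment tables, and a JSON run report.
Reruns with the same config are byte-identical.

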