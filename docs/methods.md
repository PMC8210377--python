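# Methods

## The coordination model

The package treats a transcriptome as a correlation network per condition.
For a condition group with *n* samples and *G* genes, the co-expression
matrix R holds the Pearson correlation of every gene pair across the
group's samples. A gene's *coordination profile* in that condition is its
row of R. The composite correlation index Pc compares a gene's profiles
between two conditions: Pc(i) = Pearson correlation of row i of R in
condition A with row i in condition B, restricted to the genes common to
both analyses and excluding the self-entry.

The self-entry is excluded by default because it is the constant 1 in both
profiles: including a shared constant adds a common point to both vectors
and biases Pc upward; the statistic is meant to describe a gene's
relationships with *other* genes. Include-self mode is available
(`exclude_self=False`) for sensitivity analysis.

Genes whose profile has zero variance in either condition have no defined
Pc; they are recorded as NaN sentinels, counted in the logs, and excluded
from summaries and from both selections (the top-fraction selection is
therefore computed after removing undefined genes). Silent dropping would
hide data problems; silent inclusion would poison downstream sorts.

Pc lies in [−1, 1]; per-gene interpretation: ≈1 coordination retained,
≈0 coordination lost, <0 coordination inverted. Because each Pc is itself
a correlation of (noisy) correlation estimates, at small sample sizes the
per-gene values are noisy (see "What the simulator shows" below), and the
package's distribution-level summaries (mean, median, ANOVA across
comparisons) are the primary readouts at such scales.

## Analysis pipeline

1. **Expression filter.** A gene is "expressed" for a comparison if its
   mean raw count is at least `min_mean_count` (default 1) in *every*
   group of the comparison. The gene universe therefore differs between
   comparisons; cumulative Pc uses the intersection.
2. **Transform.** Default `log2(CPM + 1)`: counts per million per sample,
   log2 with pseudocount 1. Variance stabilization is standard before
   Pearson correlation of RNA-seq counts; `transform="none"` correlates
   the supplied values as-is, and a caller may pass an already-transformed
   matrix (any non-`raw_counts` units tag skips filtering and transform).
3. **Degeneracy removal.** Genes constant within any analyzed group are
   removed (logged) — a constant vector has no correlation.
4. **Per-group co-expression and Pc**, computed blockwise (below).
5. **Summaries and tests.** Mean *and* median Pc are reported per
   comparison; distributions across comparisons are compared by ordinary
   one-way ANOVA plus Tukey–Kramer HSD (unequal group sizes supported,
   via `scipy.stats.tukey_hsd`).
6. **Selections.** (a) Per comparison: genes with Pc strictly below the
   de-coordination threshold (default −0.2; the boundary itself is
   excluded), ascending by Pc. (b) Across the three comparisons: genes are
   summed into cumulative Pc on the common gene set and the top
   `floor(fraction × n)` (default 5%) by cumulative Pc are selected —
   floor, not ceil, so a 12,000-gene universe yields exactly 600 genes.
   Ties anywhere are broken lexicographically by gene id so outputs are
   identical across platforms.
7. **Over-representation.** One-sided Fisher exact test (hypergeometric
   upper tail, via `scipy.stats.hypergeom`) per GMT term, with term gene
   lists intersected with the background first. The default background is
   the set of genes actually analyzed in the corresponding comparison —
   the transcriptome actually surveyed — not the whole annotation
   universe; it is caller-configurable. Multiple testing uses
   Benjamini–Hochberg step-up FDR (`statsmodels`), the default of the
   common GO web platforms; the test suite checks it against an
   independent sort-based reimplementation. Terms with fewer than
   `min_term_size` (default 2) background genes are skipped. Fold
   enrichment is (k/n)/(K/N).

## Numerical choices

- Correlations are computed as U Uᵀ from row-centered, L2-normalized
  expression (exact Pearson), clipped to [−1, 1]; diagonals set to 1.
- Pc is computed from row sums with the self-entry subtracted analytically,
  so the full profile never needs to be copied per gene. Identities hold
  exactly in floating point: Pc(A, A) = 1 and a sign-flipped expression
  vector gives Pc = −1, both asserted as equalities in the tests.
- **Memory contract.** The two G×G matrices are never materialized in
  `pairwise_pc`: correlation rows are produced in blocks of `block_size`
  genes (default 2048) directly from the standardized n-column matrices,
  so memory is O(block_size × G). Results are independent of block size;
  because BLAS may reorder sums across different matrix shapes, the test
  contract is agreement to 1e-12 (and 1e-10 against the scalar
  double-loop oracle), which is far below any scientific resolution of
  the statistic.
- A profile variance below 1e-12 × profile length is treated as zero and
  yields the NaN sentinel rather than an amplified rounding artifact.
- Spearman mode ranks each gene within each group and then applies the
  identical machinery; it is off by default because the statistic is
  defined on Pearson correlations.
- TSV outputs use 6 significant digits; the Pc identities above are
  properties of the in-memory tables.

## The synthetic-data generator

`SimConfig`/`generate_dataset` emulate a three-arm cohort study:
co-expression arises from per-sample latent module factors. Gene *g* in
module *m* has log-scale signal `loading_g · factor_m + ε`,
ε ~ N(0, noise_sd²); background genes are pure noise. Signals scale a
per-gene base mean (log-uniform on `base_mean_range`) multiplicatively,
and counts are either the rounded log-normal mean (default, fast and
deterministic given the signals) or a negative-binomial draw with
dispersion `nb_dispersion` (variance μ + μ²/r) for overdispersion realism.
"Rewiring" a module in one group replaces the shared factor by an
independent per-gene factor in that group only: the genes' marginal
distributions are untouched but their mutual correlation there is
destroyed — exact ground truth for de-coordination. The latent-factor
construction was chosen over Cholesky sampling of a target correlation
matrix because it is O(G) in memory, positive semi-definite by
construction, and rewiring is a one-line reassignment.

Defaults are the emulated study conditions: groups C/S/NS with 6/5/5
samples, 2000 genes, 10 modules of 50 (25% of genes in modules), loadings
uniform on (0.6, 0.95) with noise_sd 0.4 — giving within-module
correlations of roughly 0.7–0.85, typical of tightly co-regulated
metabolic modules — and graded rewiring S:{0,1,2,3}, NS:{0,1}, i.e. the
group with overt pathology reorganizes more of its transcriptome than the
treated-but-unaffected group. A single `numpy` Generator stream seeded
from the mandatory `seed` drives every draw; no global RNG state is used.

**What the simulator shows — and does not.** At the validation scale
(200 genes, 30 samples/group) ranking genes by −Pc recovers rewired
modules almost perfectly (AUROC ≥ 0.99 across seeds) and preserved-module
genes keep mean Pc ≈ 0.6. At the emulated study scale (5–6 samples per
group) individual correlation estimates carry sd ≈ 1/√(n−3), so per-gene
Pc is noisy and group-mean Pc shrinks toward zero; this is why the
package's claims at that scale are distribution-level (means, medians,
ANOVA ordering across comparisons), not per-gene calls. The generator does
not attempt species-specific expression distributions, sex effects,
library-size variation, or correlated noise between modules; passing tests
demonstrate correctness of the machinery and recoverability of planted
structure, not effect sizes in any particular real cohort.

## Design decisions that were genuinely open

- **Gene universe per comparison**: intersection of genes surviving
  filtering and degeneracy checks in both groups, so transcript counts
  naturally differ between comparisons.
- **Strict inequality** at the de-coordination threshold; boundary genes
  are not selected.
- **floor** for the top-fraction count, documented above.
- **Both mean and median** Pc are always reported; summaries and the
  acceptance script use the mean as the primary location measure.
- **Mandatory config validation before compute**: the pipeline fails on
  unknown YAML keys, missing files, or comparisons naming undeclared
  groups before reading any data, and any stage failure is re-raised with
  the stage name.

## Known limitations

- No permutation null or FDR on Pc values themselves; the threshold −0.2
  is a conventional cut, not a calibrated significance level.
- No network analytics (hubs, soft thresholding, module detection) and no
  GO DAG structure — annotation arrives flat as GMT.
- Fold-enrichment values depend on the annotation release and identifier
  mapping of the supplied GMT; the package makes no attempt to reproduce
  any particular database snapshot.
- Pc compares linear (or rank, in Spearman mode) co-expression only;
  profile changes that preserve the correlation pattern while changing
  magnitudes are invisible to it.
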