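# Methods

This note documents the models and procedures implemented in `nettracks`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the package's known limitations.

## Network decomposition and the 1D layout

The decomposition treats an undirected, unweighted gene network as having a
nested community structure.  At each module (starting from the whole
network, or from each connected component of at least `min_module_size`
genes; smaller components are pooled into a single "remainder" top-level
module, placed last in the layout), Louvain modularity maximisation runs on
the module-induced subgraph.  A split is accepted only if it yields at
least two communities with positive modularity; communities smaller than
`min_module_size` are merged into the sibling they share the most edges
with (ties broken by smallest member symbol).  Recursion stops at
`max_depth` (default 4) or when a module has fewer than
`2 * min_module_size` genes.  The Louvain pass is seeded, so the whole
decomposition is a pure function of (network, config).

Two caveats a user should understand:

- **Louvain is greedy.**  On small graphs its top-level partition is
  compared in the test suite against the exhaustive best *bipartition*;
  because Louvain may return a multi-way partition, agreement is asserted
  up to a documented tolerance of 0.05 in modularity (the multi-way
  optimum can also legitimately exceed the best bipartition).
- **`min_module_size` is the resolution control, not just a guard.**
  Essentially any subgraph — including a pure Erdős–Rényi block — admits a
  positive-modularity split, so the "modularity > 0" stopping rule alone
  never stops early.  The size floor is what determines the granularity of
  the leaves.  In the planted-block recovery checks the floor is set to
  about half the planted block size (13 for 25-gene blocks), which makes
  the leaves coincide with the planted modules; with a much smaller floor
  the tree subdivides blocks further, which is not wrong as a hierarchy
  but no longer matches the planted flat partition.

The layout orders children of every parent by decreasing size, ties by
smallest member symbol, and genes within a leaf by decreasing degree in the
leaf's induced subgraph, ties lexicographic.  These rules are arbitrary but
fully deterministic; any rule that keeps modules contiguous would serve.
Positions are 0-based and module intervals half-open.  Contiguity (every
module's genes occupy exactly its interval) and tiling (sibling intervals
partition the parent's) are enforced invariants, checked on every nsm read.

## Track data model and formats

All six formats are plain TSV (optionally gzip), `NA` for missing, UTF-8,
LF newlines.  Numeric values are serialized with Python `repr`, which
round-trips doubles exactly; all writers emit canonical orderings, so
write→read→write is byte-identical.  Gene symbols are case-sensitive and
never normalised — cross-track joins are exact-string, because silent
symbol munging is a classic source of wrong joins.  Binary composite
matrices accept only {0, 1, NA} and are validated on read.

Boolean combination evaluates an AND/OR/NOT/XOR expression over 2–5 gene
sets; `NOT` is taken relative to the union of the supplied sets (the
interactive-Venn convention), not to any genome-wide universe.  All
`2^k − 1` disjoint region counts are reported and always sum to the union
size.  Threshold filtering parses a restricted comparison/boolean grammar
(names, numeric literals, `< > <= >=`, `and/or/not`); a gene is evaluated
only if present in every referenced track.

Snapshot tracks encode multi-omics status per gene as ±2 (strong /
significant), ±1 (weak, e.g. recurrently but not significantly mutated), 0
(none) or missing, assembled from three rule types: significance + optional
recurrence (fraction of samples altered ≥ threshold, default 5%), signed
differential (significant and fold-change magnitude ≥ `fc_strong`, default
2, → ±2, significant below it → ±1), and plain membership.

## Cohort statistics

Expression matrices are assumed already log2-scale, so the differential
effect is a log2 fold change and "fold change > 2" means `|effect| > 1`;
significance calling uses `2**|effect| > fold_min`.

- **t-test**: Welch (unequal variances) — the safer default when group
  variances are unknown.  Genes with zero variance in both groups and
  equal means get a missing p and are excluded from the FDR family.
- **Wilcoxon rank-sum**: exact p for combined n ≤ 12 without ties, normal
  approximation with continuity and tie correction otherwise.
- **Cox regression**: univariate Newton–Raphson maximisation of the
  Breslow partial likelihood (simplest tie convention, documented), with
  step-halving; Wald two-sided p by default, score test at β = 0 available
  (for a binary covariate it equals the log-rank χ², which the test suite
  exploits as an independent oracle via lifelines).  Guards: ≥ 10
  non-missing samples and ≥ 3 events per gene, non-constant covariate;
  failing genes get missing p rather than unstable fits.
- **Spearman correlation**: average ranks for ties; exact permutation p
  (full enumeration, cached per rank pattern) for n < 10, t-approximation
  otherwise; at least 5 shared samples per gene.
- **FDR**: Benjamini–Hochberg step-up, computed per screen over the genes
  actually tested; missing p-values are excluded from the family and
  returned missing.

Sign conventions: differential statistics and effects are positive when
the second (lexicographically larger) group level is higher; Cox β is
positive when higher expression means worse survival.

## Order-statistics meta-analysis

Per study, genes are ranked (1 = most significant; ties get average ranks,
which keeps ranks within [1, m]) and converted to ratios r = rank/m.  For
a gene measured in N studies, Q is the joint cumulative probability that N
i.i.d. uniform order statistics lie below the observed sorted ratios,
computed by the alternating V_k recursion (numerically fine for N ≤ 20,
the enforced cap).  Q is validated against a vectorised Monte-Carlo
estimate of the same probability rather than trusted.

Calibration is empirical: the null distribution of Q is simulated per
distinct N (N i.i.d. uniforms per replicate, default 10^5 replicates) and
p_emp = (1 + #{null ≤ observed}) / (reps + 1) with add-one smoothing —
assumption-free and conditional on how many studies measured the gene.
Genes in fewer than two studies are excluded.  BH FDR over integrated
genes.  Ranks are assumed pre-directionalized by the caller; sign-conflict
handling across studies is out of scope.

## Enrichment

All over-representation tests are one-sided Fisher exact tests (upper
hypergeometric tail); depletion is out of scope because every use case
here is over-representation.  The enrichment ratio is (k/n)/(K/N) and
satisfies ratio · (K/N) · n = k exactly.  Continuous module enrichment
uses the two-sided two-sample Kolmogorov–Smirnov test (exact method for
small samples); a one-sided variant would require a directionality
convention the use cases do not supply.

Module enrichment tests every module at every level (root excluded) and
corrects jointly across all of them — conservative, but avoids an
arbitrary per-level family choice.  Neighborhood enrichment evaluates, per
gene, the 2×2 table of (neighbor vs non-neighbor) × (seed vs non-seed)
over a universe that excludes the evaluated gene itself, so a seed gene
never counts as its own evidence; degree-0 genes are skipped.  Gene-set
enrichment intersects sets with a caller-supplied universe and skips sets
smaller than 3 genes after intersection.

## Synthetic data

The generators are pure functions of (config, seed) and produce inputs
that pass the consuming modules' validation:

- `planted_network`: stochastic block model; `levels=2` pairs blocks into
  super-blocks with intermediate density (geometric mean of p_in, p_out by
  default).
- `simulate_cohort`: baseline Normal(8, 1), mimicking log2 microarray
  intensity scale (documented, arbitrary); planted genes shifted by
  `effect_sd` in group 2.  Defaults (30 + 30 samples, 100 of 2000 genes,
  2-SD shift) are the sizes used in the calibration and recovery checks.
- `simulate_survival`: exponential baseline hazard scaled by
  exp(β · Σ prognostic expressions); independent exponential censoring
  with its rate tuned so the expected censored fraction is roughly
  `censor_rate`.  With one prognostic gene the univariate Cox fit is
  unbiased for β; with several, univariate fits are attenuated by omitted
  covariates (a real phenomenon, not a bug).
- `simulate_mutations`: Bernoulli matrix with a hypermutated sample
  fraction at an elevated rate and driver genes elevated everywhere.

What these do *not* emulate: real mutation spectra, copy-number segment
structure, expression correlation between genes, batch effects, or
informative censoring.  Passing recovery tests therefore demonstrates that
the statistical machinery is correct under its stated assumptions, not
that those assumptions hold in tumor cohorts.

## Rendering and CLI

Figures are vector SVG with a fixed hash salt and no timestamps, so
identical inputs give byte-identical output.  Node-link views are limited
to 500 genes by default (configurable); for a binary-track overlay the
limit may instead be satisfied by the count of *present* genes, in which
case only those are drawn.  The palette approximates the red/light-red /
blue/light-blue / grey semantics of strong/weak up/down/missing codes.
The CLI is a thin wrapper: each subcommand reads standard formats, calls
one library function and writes standard formats; `--seed` feeds every
stochastic stage.

## Problem sizes used in checks

The bundled checks run at desk scale by choice: 100-gene planted networks
(4 × 25), 2000-gene cohorts with 20–30 samples per arm, survival fits at
n = 500 over 20 seeds, 5 simulated studies of 1000 genes for
meta-analysis, 10^5 Monte-Carlo draws for Q validation.  These sizes give
stable statistics (binomial/MC standard errors well inside the asserted
tolerances) while keeping the whole suite fast.

## Known limitations

- Directed or weighted networks, edge confidence scores and network
  merging are not supported; the decomposition is greedy and approximate.
- The layout's child ordering optimises nothing beyond determinism;
  related modules are not placed adjacently.
- No multivariable or stratified Cox, paired tests, batch correction, or
  GSEA-style weighted statistics.
- The track-format dialects are self-consistent but not claimed compatible
  with any external tool's exports; the missing-value token is `NA`.
- Empirical meta-analysis p-values are floored at 1/(reps + 1); genes
  cannot be distinguished below the Monte-Carlo floor.
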