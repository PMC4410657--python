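# nettracks

Hierarchical decomposition of biological interaction networks into a
one-dimensional, module-contiguous gene layout, with omics evidence carried
as "tracks" along that layout — plus the statistics needed to turn raw
gene-by-sample matrices into evidence: per-gene cohort screens, rank-based
cross-study integration, Boolean track algebra and enrichment analysis.

## Who this is for

Systems-biology and cancer-genomics analysts who want to interpret
multi-omics data (expression, copy number, methylation, mutation, survival)
in the context of a protein–protein interaction network, at a scale where
node-link diagrams stop working.  Instead of a 2D hairball, the network's
nested community structure is flattened into a single gene ordering in
which every module occupies a contiguous interval; evidence layers then
stack vertically like tracks in a genome browser, and enrichment statistics
quantify what the eye picks out.

## The core machinery

- **Decomposition and layout** (`nettracks.network`).  Seeded Louvain
  modularity maximisation applied recursively to each module's induced
  subgraph yields a module tree; a deterministic ordering rule (children by
  decreasing size, genes by decreasing within-module degree, lexicographic
  ties) flattens it into a bijection gene → position where every module at
  every level is an interval.  Serialized in a line-oriented `nsm` format.
- **Tracks** (`nettracks.tracks`).  Six TSV formats: gene sets (`sbt`),
  per-gene values (`sct`), gene×sample continuous (`cct`) and binary
  (`cbt`) matrices, sample annotations (`tsi`) and categorical snapshot
  tracks coding strong/weak up/down alterations.  Threshold filtering
  (`"fdr < 0.01 and fc > 2"`), Boolean/Venn combination of 2–5 gene sets,
  stable sample sorting and snapshot assembly.
- **Cohort statistics** (`nettracks.cohort`).  Welch t / Wilcoxon rank-sum
  differential screens (exact small-sample p), univariate Cox
  proportional-hazards survival screening (Breslow ties, Wald and score
  tests — the score test at β=0 reproduces the log-rank statistic),
  Spearman correlation (exact permutation p for n < 10), Benjamini–Hochberg
  FDR and threshold-based significance calling.
- **Meta-analysis** (`nettracks.meta`).  Order-statistics rank aggregation:
  a gene ranked at ratios r₍₁₎ ≤ … ≤ r₍N₎ across N studies gets
  Q = N!·V_N with V₀ = 1, V_k = Σᵢ (−1)^(i−1) V_(k−i) r₍N−k+1₎^i / i!,
  the joint probability that N uniform order statistics fall below the
  observed ratios; calibrated by per-N Monte-Carlo null simulation.
- **Enrichment** (`nettracks.enrich`).  One-sided Fisher exact tests of
  seed genes against network modules at all levels, GMT gene sets and each
  gene's direct interaction neighborhood; two-sample Kolmogorov–Smirnov for
  continuous tracks; the enrichment ratio is (k/n)/(K/N).
- **Synthetic data** (`nettracks.synth`).  Seeded generators with planted
  ground truth: stochastic block-model networks, differential cohorts,
  survival cohorts, mutation matrices.
- **Rendering and CLI** (`nettracks.render`, `nettracks.cli`).  Deterministic
  SVG track stacks (heat map / bar chart / barcode / snapshot strip) and
  node-link detail views (≤ 500 genes by default); a `nettracks` command
  mirroring the library.

## Worked example

```python
import nettracks as nt
from nettracks.synth import planted_network, simulate_cohort

net, truth = planted_network([25, 25, 25, 25], p_in=0.3, p_out=0.01, seed=1)
tree = nt.decompose(net, nt.DecomposeConfig(min_module_size=13, seed=0))
layout = nt.linearize(tree, net)
print("genes:", net.n_genes, "edges:", net.n_edges)
print("leaf modules:", [(m.id, len(m.genes)) for m in tree.leaves()])
print("module intervals:", {m.id: layout.intervals[m.id] for m in tree.leaves()})

track, groups, planted = simulate_cohort(n_genes=2000, n_group1=30, n_group2=30,
                                         n_de=100, effect_sd=2.0, seed=2)
stats = nt.differential(track, groups, method="t")
sig = nt.call_significant(stats, fdr_max=0.01, fold_min=2.0)
print("significant genes:", len(sig.genes))

block0 = sorted(g for g, b in truth.blocks.items() if b == 0)
seeds = nt.SingleBinaryTrack("seeds", frozenset(block0[:10]))
row = nt.module_enrichment(seeds, tree).table.loc["M1"]
print(f"M1: k={int(row.k)}/{int(row.n)} ratio={row.ratio:.1f} fdr={row.fdr:.3e}")
```

prints

```
genes: 100 edges: 363
leaf modules: [('M1', 25), ('M2', 25), ('M3', 25), ('M4', 25)]
module intervals: {'M1': (0, 25), 'M2': (25, 50), 'M3': (50, 75), 'M4': (75, 100)}
significant genes: 100
M1: k=10/25 ratio=4.0 fdr=7.553e-07
```

The decomposition recovers the four planted 25-gene blocks exactly, each
occupying a contiguous 25-position interval of the layout.  The
differential screen at FDR < 0.01 and fold change > 2 calls exactly the 100
planted genes.  Ten seed genes drawn from the first block are 4-fold
over-represented in module M1 (10 of its 25 genes vs 10 of 100 genes
overall), Fisher FDR ≈ 7.6e-07.

The same pipeline from the shell:

```sh
nettracks --seed 1 synth network --blocks 25,25,25,25 -o net.tsv
nettracks network decompose net.tsv --min-module-size 13 -o net.nsm
nettracks synth cohort --out-cct expr.cct --out-tsi groups.tsi
nettracks stats diff expr.cct groups.tsi --attr group -o diff.tsv
nettracks stats call diff.tsv --fdr-max 0.01 --fold-min 2 -o sig.sbt
nettracks enrich modules sig.sbt net.nsm -o modules.tsv
nettracks render region net.nsm expr.cct --start 0 --end 25 -o fig.svg
```

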