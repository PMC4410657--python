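"""Enrichment analyses: network modules, gene sets and direct neighborhoods.

Three flavours of over-representation analysis share one result table:

- *module enrichment*: a binary track (seed genes) is tested against every
  module of the network hierarchy (all levels, root excluded) with the
  one-sided Fisher exact test; a continuous track is tested per module with
  the two-sample Kolmogorov–Smirnov test (module values vs the rest).
- *gene-set enrichment*: the same Fisher test against GMT gene-set
  collections (GO terms, pathways) restricted to a caller-supplied universe.
- *direct-neighborhood enrichment*: every gene's direct interaction
  partners are tested for enrichment of the seeds; focusing on seed genes
  prioritises them, focusing on non-seed genes expands the seed list.

Each table row carries the 2x2 counts (k of n in the unit vs K of N in the
universe), the enrichment ratio (k/n)/(K/N), the p-value and its BH FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import bh_adjust
from .network import Module, ModuleTree, Network, NetworkError, neighbors
from .tracks import SingleBinaryTrack, SingleContinuousTrack, _open_text

logger = logging.getLogger(__name__)


class EnrichError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT): name -> genes, with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise EnrichError(f"gene set {name!r} is empty")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        desc: dict[str, str] = {}
        with _open_text(Path(path), "rt") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise EnrichError(
                        f"{path}: line {lineno}: GMT rows need name, description "
                        "and at least one gene"
                    )
                name = parts[0]
                if name in sets:
                    raise EnrichError(f"{path}: duplicate set name {name!r}")
                sets[name] = frozenset(g for g in parts[2:] if g)
                desc[name] = parts[1]
        return cls(sets, desc)

    def write_gmt(self, path: str | Path) -> None:
        with _open_text(Path(path), "wt") as fh:
            for name in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{self.descriptions.get(name, '')}\t{genes}\n")


ENRICH_COLUMNS = ["k", "n", "K", "N", "ratio", "stat", "p", "fdr"]


@dataclass
class EnrichmentTable:
    """Per-unit enrichment results (unit = module / set / gene)."""

    table: pd.DataFrame

    def write_tsv(self, path: str | Path) -> None:
        with _open_text(Path(path), "wt") as fh:
            fh.write("unit\t" + "\t".join(ENRICH_COLUMNS) + "\n")
            for unit, row in self.table.iterrows():
                cells = []
                for c in ENRICH_COLUMNS:
                    v = row[c]
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        cells.append("NA")
                    elif c in ("k", "n", "K", "N"):
                        cells.append(str(int(v)))
                    else:
                        cells.append(repr(float(v)))
                fh.write(str(unit) + "\t" + "\t".join(cells) + "\n")

    def significant(self, fdr_max: float = 0.05, name: str = "enriched") -> SingleBinaryTrack:
        sel = self.table.index[self.table["fdr"] < fdr_max]
        return SingleBinaryTrack(name, frozenset(sel))


def fisher_over(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation p: P(X >= k) for
    X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise EnrichError(f"inconsistent 2x2 counts k={k} n={n} K={K} N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def _ratio(k: int, n: int, K: int, N: int) -> float:
    if n == 0 or K == 0:
        return math.nan
    return (k / n) / (K / N)


def module_enrichment(
    track: "SingleBinaryTrack | SingleContinuousTrack",
    tree: ModuleTree,
    ks_mode: str = "auto",
) -> EnrichmentTable:
    """Enrichment of a track in every module of the hierarchy (root excluded).

    Binary track: one-sided Fisher exact test of module membership vs seed
    membership; universe = all genes in the tree.  Continuous track:
    two-sided two-sample KS test of module values vs all other values.
    FDR is corrected jointly across all tested modules at all levels.
    """
    universe = frozenset(g for leaf in tree.leaves() for g in leaf.genes)
    nn = len(universe)
    modules = [m for m in tree.modules() if m.level > 0]

    rows: dict[str, tuple] = {}
    if isinstance(track, SingleBinaryTrack):
        seeds = track.genes & universe
        dropped = len(track.genes) - len(seeds)
        if dropped:
            logger.info("module_enrichment: %d track gene(s) outside universe dropped", dropped)
        if not seeds:
            raise EnrichError("track has no genes in the module universe")
        kk = len(seeds)
        for m in modules:
            n = len(m.genes)
            k = len(m.genes & seeds)
            p = fisher_over(k, n, kk, nn)
            rows[m.id] = (k, n, kk, nn, _ratio(k, n, kk, nn), float(k), p)
    else:
        vals = {g: v for g, v in track.values.items() if g in universe}
        dropped = len(track.values) - len(vals)
        if dropped:
            logger.info("module_enrichment: %d track gene(s) outside universe dropped", dropped)
        if not vals:
            raise EnrichError("track has no genes in the module universe")
        for m in modules:
            inside = np.array([v for g, v in vals.items() if g in m.genes])
            outside = np.array([v for g, v in vals.items() if g not in m.genes])
            if inside.size == 0 or outside.size == 0:
                rows[m.id] = (inside.size, len(m.genes), len(vals), nn,
                              math.nan, math.nan, math.nan)
                continue
            method = ks_mode if ks_mode != "auto" else (
                "exact" if inside.size + outside.size <= 25 else "auto"
            )
            res = sps.ks_2samp(inside, outside, method=method)
            rows[m.id] = (inside.size, len(m.genes), len(vals), nn,
                          math.nan, float(res.statistic), float(res.pvalue))

    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["k", "n", "K", "N", "ratio", "stat", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return EnrichmentTable(df[ENRICH_COLUMNS])


def geneset_enrichment(
    track: SingleBinaryTrack,
    sets: GeneSetCollection,
    universe: frozenset[str],
    min_size: int = 3,
) -> EnrichmentTable:
    """One-sided Fisher enrichment of seed genes in each gene set.

    Sets are intersected with the universe first; sets smaller than
    ``min_size`` after intersection are skipped (count logged).
    """
    seeds = track.genes & universe
    if not seeds:
        raise EnrichError("track has no genes in the universe")
    nn, kk = len(universe), len(seeds)
    rows = {}
    n_skipped = 0
    for name, genes in sets.sets.items():
        inset = genes & universe
        n = len(inset)
        if n < min_size:
            n_skipped += 1
            continue
        k = len(inset & seeds)
        p = fisher_over(k, n, kk, nn)
        rows[name] = (k, n, kk, nn, _ratio(k, n, kk, nn), float(k), p)
    if n_skipped:
        logger.info("geneset_enrichment: %d set(s) below min_size skipped", n_skipped)
    if not rows:
        raise EnrichError("no testable gene sets")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["k", "n", "K", "N", "ratio", "stat", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return EnrichmentTable(df[ENRICH_COLUMNS])


def neighborhood_enrichment(
    seeds: SingleBinaryTrack,
    net: Network,
    mode: str = "all",
) -> EnrichmentTable:
    """Seed enrichment among each gene's direct interaction partners.

    For an evaluated gene g the universe is every other network gene; its
    neighbors are crossed against seed membership in a 2x2 table and tested
    one-sided (Fisher).  ``mode`` evaluates all genes, only seeds
    (prioritisation) or only non-seeds (seed expansion).  Genes of degree 0
    are skipped; FDR over evaluated genes.
    """
    if mode not in ("all", "seed_only", "nonseed_only"):
        raise EnrichError(f"unknown mode {mode!r}")
    seed_set = seeds.genes & net.genes
    if not seed_set:
        raise EnrichError("no seed genes present in the network")
    all_genes = sorted(net.genes)
    if mode == "seed_only":
        evaluated = [g for g in all_genes if g in seed_set]
    elif mode == "nonseed_only":
        evaluated = [g for g in all_genes if g not in seed_set]
    else:
        evaluated = all_genes

    nn_total = len(all_genes)
    rows = {}
    n_skipped = 0
    for g in evaluated:
        nbrs = set(net.graph[g])
        if not nbrs:
            n_skipped += 1
            continue
        n = len(nbrs)
        k = len(nbrs & seed_set)
        kk = len(seed_set - {g})
        nn = nn_total - 1
        p = fisher_over(k, n, kk, nn)
        rows[g] = (k, n, kk, nn, _ratio(k, n, kk, nn), float(k), p)
    if n_skipped:
        logger.info("neighborhood_enrichment: %d degree-0 gene(s) skipped", n_skipped)
    if not rows:
        raise EnrichError("no evaluable genes")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["k", "n", "K", "N", "ratio", "stat", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return EnrichmentTable(df[ENRICH_COLUMNS])


def seed_neighbors(
    seeds: SingleBinaryTrack, net: Network, max_seeds: int = 10
) -> Network:
    """Induced subgraph on a small seed set plus all its direct neighbors.

    Only offered for small seed tracks (default <= 10 genes in the network,
    matching the portal's retrieval limit)."""
    present = seeds.genes & net.genes
    if not present:
        raise EnrichError("no seed genes present in the network")
    if len(present) > max_seeds:
        raise EnrichError(
            f"{len(present)} seeds exceed the max_seeds={max_seeds} limit"
        )
    region = set(present)
    for g in present:
        region |= set(net.graph[g])
    return Network(net.graph.subgraph(region).copy())
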