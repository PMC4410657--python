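"""Network representation, hierarchical modular decomposition and 1D layout.

A gene interaction network is an undirected simple graph over gene symbols.
Its community structure is extracted recursively (seeded Louvain modularity
maximisation on each module's induced subgraph) into a :class:`ModuleTree`,
and the tree is flattened into a :class:`Layout`: a bijection from genes to
consecutive integer positions in which every module, at every level of the
hierarchy, occupies a contiguous interval.  The layout is what lets per-gene
evidence tracks be drawn side by side along one axis, genome-browser style,
while preserving the network's modular organisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from networkx.algorithms.community import louvain_communities, modularity

logger = logging.getLogger(__name__)

NSM_HEADER = "#nsm v1"


class NetworkError(ValueError):
    """Malformed network input or an invalid query against a network."""


@dataclass(frozen=True)
class Network:
    """Undirected simple graph over gene symbols.

    Genes are defined by edge membership: an isolated symbol never occurs.
    Symbols are case-preserved and never normalised.
    """

    graph: nx.Graph

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Network":
        g = nx.Graph()
        n_self = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
        if n_self:
            logger.info("dropped %d self-loop(s)", n_self)
        return cls(g)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def load_network(path: str | Path) -> Network:
    """Read a tab-delimited two-column edge list.

    Lines starting with ``#`` are comments.  Duplicate edges (in either
    orientation) are collapsed and self-loops dropped with a logged count.
    """
    from .tracks import _open_text  # gzip-aware

    path = Path(path)
    edges: list[tuple[str, str]] = []
    with _open_text(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NetworkError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            edges.append((parts[0], parts[1]))
    if not edges:
        raise NetworkError(f"{path}: no edges found")
    return Network.from_edges(edges)


@dataclass
class Module:
    """A node of the module hierarchy.

    ``genes`` is the full gene set of the module; children partition it.
    ``level`` is the depth (root = 0).  ``is_remainder`` marks the synthetic
    top-level module that absorbs small disconnected components.
    """

    id: str
    genes: frozenset[str]
    level: int
    children: list["Module"] = field(default_factory=list)
    is_remainder: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["Module"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class ModuleTree:
    root: Module

    def modules(self) -> list[Module]:
        return list(self.root.walk())

    def leaves(self) -> list[Module]:
        return [m for m in self.root.walk() if m.is_leaf]

    def validate(self) -> None:
        seen_ids: set[str] = set()
        for m in self.root.walk():
            if m.id in seen_ids:
                raise NetworkError(f"duplicate module id {m.id!r}")
            seen_ids.add(m.id)
            if m.children:
                union: set[str] = set()
                total = 0
                for c in m.children:
                    union |= c.genes
                    total += len(c.genes)
                if union != set(m.genes) or total != len(m.genes):
                    raise NetworkError(
                        f"children of {m.id!r} do not partition its gene set"
                    )


@dataclass(frozen=True)
class DecomposeConfig:
    """Knobs of the recursive decomposition.

    min_module_size : smallest admissible module; a module with fewer than
        ``2 * min_module_size`` genes is never split further.
    max_depth : maximum hierarchy depth below the root.
    resolution : Louvain modularity resolution (1.0 = classic modularity).
    seed : seed for Louvain's randomised local moving; fixes the output.
    """

    min_module_size: int = 5
    max_depth: int = 4
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def _sorted_children_key(genes: frozenset[str]) -> tuple[int, str]:
    return (-len(genes), min(genes))


def _split_once(
    sub: nx.Graph, cfg: DecomposeConfig
) -> list[frozenset[str]] | None:
    """One level of community detection on an induced subgraph.

    Returns the accepted partition (>= 2 parts, positive modularity, all
    parts >= min_module_size after merging undersized communities), or None
    if the module should stay a leaf.
    """
    comms = louvain_communities(sub, resolution=cfg.resolution, seed=cfg.seed)
    comms = [frozenset(c) for c in comms]
    if len(comms) < 2:
        return None
    # Merge communities below min_module_size into the sibling they are most
    # connected to (tie: smallest member symbol of the target).
    comms.sort(key=_sorted_children_key)
    merged = True
    while merged and len(comms) > 1:
        merged = False
        for i, c in enumerate(comms):
            if len(c) >= cfg.min_module_size:
                continue
            best_j, best_score = None, (-1, "")
            for j, other in enumerate(comms):
                if j == i:
                    continue
                cut = sum(1 for u in c for v in sub[u] if v in other)
                score = (cut, min(other))
                if best_j is None or cut > best_score[0] or (
                    cut == best_score[0] and min(other) < best_score[1]
                ):
                    best_j, best_score = j, score
            assert best_j is not None
            comms[best_j] = comms[best_j] | c
            del comms[i]
            comms.sort(key=_sorted_children_key)
            merged = True
            break
    if len(comms) < 2:
        return None
    q = modularity(sub, comms, resolution=cfg.resolution)
    if q <= 0:
        return None
    return comms


def decompose(net: Network, cfg: DecomposeConfig | None = None) -> ModuleTree:
    """Recursive modular decomposition of a network.

    Each connected component of at least ``min_module_size`` genes becomes a
    top-level module; smaller components are pooled into one remainder
    module, ordered last.  Within a module, Louvain community detection on
    the induced subgraph is accepted as a split only if it yields at least
    two communities with positive modularity; recursion stops at
    ``max_depth`` or when a module has fewer than ``2 * min_module_size``
    genes.  Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or DecomposeConfig()
    if net.n_genes == 0:
        raise NetworkError("cannot decompose an empty network")

    g = net.graph
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=_sorted_children_key,
    )
    big = [c for c in components if len(c) >= cfg.min_module_size]
    small = [c for c in components if len(c) < cfg.min_module_size]

    root = Module(id="M0", genes=frozenset(g.nodes), level=0)
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def build(genes: frozenset[str], level: int, is_remainder: bool = False) -> Module:
        mod = Module(id=next_id(), genes=genes, level=level, is_remainder=is_remainder)
        if is_remainder or level >= cfg.max_depth:
            return mod
        if len(genes) < 2 * cfg.min_module_size:
            return mod
        parts = _split_once(g.subgraph(genes), cfg)
        if parts is None:
            return mod
        for part in sorted(parts, key=_sorted_children_key):
            mod.children.append(build(part, level + 1))
        return mod

    if len(big) == 1 and not small:
        # Connected network: split the root itself.
        parts = (
            _split_once(g, cfg)
            if net.n_genes >= 2 * cfg.min_module_size
            else None
        )
        if parts is not None:
            for part in sorted(parts, key=_sorted_children_key):
                root.children.append(build(part, 1))
    else:
        for comp in big:
            root.children.append(build(comp, 1))
        if small:
            pooled = frozenset().union(*small)
            root.children.append(
                Module(id=next_id(), genes=pooled, level=1, is_remainder=True)
            )

    tree = ModuleTree(root)
    tree.validate()
    return tree


@dataclass(frozen=True)
class Layout:
    """Bijection gene -> 0-based position, plus per-module intervals.

    ``intervals`` maps module id to a half-open ``[start, end)`` interval;
    every module's genes occupy exactly its interval (contiguity), sibling
    intervals tile the parent's, and the root interval is ``[0, N)``.
    """

    positions: dict[str, int]
    intervals: dict[str, tuple[int, int]]

    @property
    def n_genes(self) -> int:
        return len(self.positions)

    def genes_in(self, start: int, end: int) -> list[str]:
        """Genes with position in [start, end), in position order."""
        inv = self.order()
        return inv[max(start, 0): min(end, len(inv))]

    def order(self) -> list[str]:
        out = [""] * len(self.positions)
        for gene, pos in self.positions.items():
            out[pos] = gene
        return out


def linearize(tree: ModuleTree, net: Network | None = None) -> Layout:
    """Derive the deterministic 1D layout from a module tree.

    Children of each parent are ordered by decreasing size then by smallest
    member symbol (the remainder module, if any, goes last); genes within a
    leaf are ordered by decreasing degree inside the leaf's induced subgraph
    (requires ``net``; without it, lexicographic), ties lexicographic.
    """
    tree.validate()
    positions: dict[str, int] = {}
    intervals: dict[str, tuple[int, int]] = {}
    cursor = [0]

    def place(mod: Module) -> None:
        start = cursor[0]
        if mod.is_leaf:
            if net is not None:
                sub = net.graph.subgraph(mod.genes)
                key = lambda gene: (-sub.degree(gene), gene)
            else:
                key = lambda gene: (0, gene)
            for gene in sorted(mod.genes, key=key):
                positions[gene] = cursor[0]
                cursor[0] += 1
        else:
            ordered = sorted(
                mod.children,
                key=lambda c: (c.is_remainder, *_sorted_children_key(c.genes)),
            )
            for child in ordered:
                place(child)
        intervals[mod.id] = (start, cursor[0])

    place(tree.root)
    return Layout(positions=positions, intervals=intervals)


def neighbors(net: Network, gene: str) -> frozenset[str]:
    """Direct interaction partners of ``gene`` (never includes the gene)."""
    if gene not in net.graph:
        raise NetworkError(f"gene {gene!r} is not in the network")
    return frozenset(net.graph[gene])


def induced_components(net: Network, genes: Iterable[str]) -> list[frozenset[str]]:
    """Connected components of the subgraph induced by ``genes``.

    Unknown genes are dropped with a logged count.  Components are sorted by
    decreasing size, ties by smallest member symbol.
    """
    genes = set(genes)
    known = genes & set(net.graph.nodes)
    dropped = len(genes) - len(known)
    if dropped:
        logger.info("induced_components: dropped %d unknown gene(s)", dropped)
    sub = net.graph.subgraph(known)
    comps = [frozenset(c) for c in nx.connected_components(sub)]
    return sorted(comps, key=_sorted_children_key)


# ---------------------------------------------------------------------------
# nsm serialization: modularized-network files
# ---------------------------------------------------------------------------

def write_nsm(
    net: Network, tree: ModuleTree, layout: Layout, path: str | Path
) -> None:
    """Serialize a (network, module tree, layout) triple.

    Line-oriented TSV with a version header, a module table
    (module_id, parent_id, level, remainder flag), a gene table
    (gene, leaf module, position) and an edge table.  Writing is canonical
    (modules in depth-first layout order, genes by position, edges sorted) so
    write -> read -> write is byte-identical.
    """
    from .tracks import _open_text

    parent_of: dict[str, str] = {}
    for m in tree.root.walk():
        for c in m.children:
            parent_of[c.id] = m.id

    def dfs_order(mod: Module) -> Iterable[Module]:
        yield mod
        for child in sorted(
            mod.children,
            key=lambda c: (c.is_remainder, *_sorted_children_key(c.genes)),
        ):
            yield from dfs_order(child)

    leaf_of: dict[str, str] = {}
    for leaf in tree.leaves():
        for gene in leaf.genes:
            leaf_of[gene] = leaf.id

    with _open_text(Path(path), "wt") as fh:
        fh.write(NSM_HEADER + "\n")
        fh.write("#modules\n")
        for m in dfs_order(tree.root):
            pid = parent_of.get(m.id, "-")
            flag = "1" if m.is_remainder else "0"
            fh.write(f"{m.id}\t{pid}\t{m.level}\t{flag}\n")
        fh.write("#genes\n")
        for gene in layout.order():
            fh.write(f"{gene}\t{leaf_of[gene]}\t{layout.positions[gene]}\n")
        fh.write("#edges\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_nsm(path: str | Path) -> tuple[Network, ModuleTree, Layout]:
    """Read an nsm file back into a consistent (Network, ModuleTree, Layout)."""
    from .tracks import _open_text

    path = Path(path)
    with _open_text(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != NSM_HEADER:
        raise NetworkError(f"{path}: missing or unsupported nsm header")

    section = None
    mod_rows: list[tuple[str, str, int, bool]] = []
    gene_rows: list[tuple[str, str, int]] = []
    edge_rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line in ("#modules", "#genes", "#edges"):
            section = line
            continue
        if not line:
            continue
        parts = line.split("\t")
        if section == "#modules":
            if len(parts) != 4:
                raise NetworkError(f"{path}: line {lineno}: bad module row")
            mod_rows.append((parts[0], parts[1], int(parts[2]), parts[3] == "1"))
        elif section == "#genes":
            if len(parts) != 3:
                raise NetworkError(f"{path}: line {lineno}: bad gene row")
            gene_rows.append((parts[0], parts[1], int(parts[2])))
        elif section == "#edges":
            if len(parts) != 2:
                raise NetworkError(f"{path}: line {lineno}: bad edge row")
            edge_rows.append((parts[0], parts[1]))
        else:
            raise NetworkError(f"{path}: line {lineno}: data before a section header")

    modules: dict[str, Module] = {}
    root_id = None
    gene_sets: dict[str, set[str]] = {mid: set() for mid, _, _, _ in mod_rows}
    for gene, mid, _pos in gene_rows:
        if mid not in gene_sets:
            raise NetworkError(f"{path}: gene {gene!r} references unknown module {mid!r}")
        gene_sets[mid].add(gene)
    # Propagate leaf gene sets up the parent chain.
    parents = {mid: pid for mid, pid, _, _ in mod_rows}
    for mid, _, _, _ in mod_rows:
        genes_here = set(gene_sets[mid])
        cur = parents[mid]
        while cur != "-":
            gene_sets[cur] |= genes_here
            cur = parents[cur]

    for mid, pid, level, remainder in mod_rows:
        modules[mid] = Module(
            id=mid, genes=frozenset(gene_sets[mid]), level=level,
            is_remainder=remainder,
        )
        if pid == "-":
            root_id = mid
    if root_id is None:
        raise NetworkError(f"{path}: no root module")
    for mid, pid, _, _ in mod_rows:
        if pid != "-":
            modules[pid].children.append(modules[mid])

    tree = ModuleTree(modules[root_id])
    tree.validate()

    net = Network.from_edges(edge_rows)
    leaf_genes = {g for leaf in tree.leaves() for g in leaf.genes}
    for a, b in edge_rows:
        for gene in (a, b):
            if gene not in leaf_genes:
                raise NetworkError(
                    f"{path}: gene {gene!r} occurs in edges but not in any leaf module"
                )

    positions = {gene: pos for gene, _mid, pos in gene_rows}
    intervals: dict[str, tuple[int, int]] = {}
    for m in tree.modules():
        pos = [positions[g] for g in m.genes]
        intervals[m.id] = (min(pos), max(pos) + 1)
    layout = Layout(positions=positions, intervals=intervals)
    _check_layout(tree, layout)
    return net, tree, layout


def _check_layout(tree: ModuleTree, layout: Layout) -> None:
    n = len(layout.positions)
    if sorted(layout.positions.values()) != list(range(n)):
        raise NetworkError("positions are not a bijection onto 0..N-1")
    for m in tree.modules():
        start, end = layout.intervals[m.id]
        if end - start != len(m.genes):
            raise NetworkError(f"module {m.id!r} is not contiguous in the layout")
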