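"""Static rendering of track stacks along the 1D layout and node-link views.

Composite tracks are drawn as heat maps, single continuous tracks as bar
charts, single binary tracks as barcode plots and snapshot tracks as
color-coded strips, all sharing the gene axis given by the layout.  For
small regions a node-link diagram of the induced subgraph is available,
optionally colored by a track overlay.  Output is deterministic vector SVG
(fixed hash salt, no timestamps), so identical inputs give byte-identical
figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .network import Layout, Network
from .tracks import (
    CategoricalTrack,
    CompositeTrack,
    SingleBinaryTrack,
    SingleContinuousTrack,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_GENES = 500

_SNAPSHOT_COLORS = {
    2.0: "#c62828",   # strong up / significant: red
    1.0: "#ef9a9a",   # weak up: light red
    0.0: "#ffffff",   # none
    -1.0: "#90caf9",  # weak down: light blue
    -2.0: "#1565c0",  # strong down: blue
}
_MISSING_COLOR = "#bdbdbd"


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class RegionQuery:
    """A slice of the 1D layout: either a gene with a flank of neighbors on
    each side, or an explicit half-open position interval."""

    gene: str | None = None
    flank: int = 10
    start: int | None = None
    end: int | None = None
    max_genes: int = DEFAULT_MAX_GENES

    def resolve(self, layout: Layout) -> tuple[int, int]:
        n = layout.n_genes
        if self.gene is not None:
            if self.flank < 0:
                raise RenderError("flank must be >= 0")
            if self.gene not in layout.positions:
                raise RenderError(f"gene {self.gene!r} is not in the layout")
            pos = layout.positions[self.gene]
            return max(0, pos - self.flank), min(n, pos + self.flank + 1)
        if self.start is None or self.end is None:
            return 0, n
        if not (0 <= self.start < self.end <= n):
            raise RenderError(f"interval [{self.start}, {self.end}) outside [0, {n})")
        return self.start, self.end


def _deterministic_svg() -> None:
    plt.rcParams["svg.hashsalt"] = "nettracks"
    plt.rcParams["svg.fonttype"] = "none"


def _save(fig, out: Path) -> None:
    _deterministic_svg()
    fig.savefig(out, format=out.suffix.lstrip(".") or "svg",
                metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)


def render_region(
    layout: Layout,
    tracks: Sequence[object],
    region: RegionQuery,
    out: str | Path,
) -> Path:
    """Render a stacked panel of tracks over a layout region.

    Track genes that are not in the layout are skipped with a logged count.
    One panel per track, in the given order, sharing the gene axis.
    """
    out = Path(out)
    start, end = region.resolve(layout)
    genes = layout.genes_in(start, end)
    if not genes:
        raise RenderError("empty region")
    if not tracks:
        raise RenderError("no tracks to render")

    heights = []
    for t in tracks:
        if isinstance(t, CompositeTrack):
            heights.append(max(1.2, min(3.0, 0.08 * len(t.samples))))
        elif isinstance(t, CategoricalTrack):
            heights.append(max(0.8, 0.3 * len(t.subtracks)))
        else:
            heights.append(0.9)
    fig, axes = plt.subplots(
        len(tracks), 1, figsize=(max(4.0, 0.18 * len(genes) + 1.5), sum(heights) + 0.8),
        gridspec_kw={"height_ratios": heights}, squeeze=False,
    )
    xs = np.arange(len(genes))
    for ax, t in zip(axes[:, 0], tracks):
        if isinstance(t, CompositeTrack):
            sub = t.data.reindex(genes)[t.samples]
            missing = int(sub.isna().all(axis=1).sum())
            if missing:
                logger.info("render_region: %d gene(s) absent from %s", missing, t.name)
            ax.imshow(sub.to_numpy(dtype=float).T, aspect="auto",
                      interpolation="nearest", cmap="RdBu_r")
            ax.set_ylabel(t.name, fontsize=7)
        elif isinstance(t, SingleContinuousTrack):
            vals = np.array([t.values.get(g, np.nan) for g in genes])
            ax.bar(xs, np.nan_to_num(vals), width=0.8, color="#455a64")
            ax.set_ylabel(t.name, fontsize=7)
        elif isinstance(t, SingleBinaryTrack):
            present = [i for i, g in enumerate(genes) if g in t.genes]
            ax.vlines(present, 0, 1, color="#c62828", linewidth=2)
            ax.set_ylim(0, 1)
            ax.set_yticks([])
            ax.set_ylabel(t.name, fontsize=7)
        elif isinstance(t, CategoricalTrack):
            sub = t.data.reindex(genes)[t.subtracks]
            arr = sub.to_numpy(dtype=float).T
            rgb = np.empty(arr.shape + (3,))
            for code, color in _SNAPSHOT_COLORS.items():
                rgb[arr == code] = matplotlib.colors.to_rgb(color)
            rgb[np.isnan(arr)] = matplotlib.colors.to_rgb(_MISSING_COLOR)
            ax.imshow(rgb, aspect="auto", interpolation="nearest")
            ax.set_yticks(range(len(t.subtracks)))
            ax.set_yticklabels(t.subtracks, fontsize=6)
            ax.set_ylabel(t.name, fontsize=7)
        else:
            raise RenderError(f"cannot render object of type {type(t).__name__}")
        ax.set_xlim(-0.5, len(genes) - 0.5)
        ax.set_xticks([])
    axes[-1, 0].set_xticks(xs)
    axes[-1, 0].set_xticklabels(genes, rotation=90, fontsize=6)
    fig.suptitle(f"positions [{start}, {end})", fontsize=8)
    _save(fig, out)
    return out


def render_node_link(
    net: Network,
    genes: Sequence[str],
    out: str | Path,
    overlay: object = None,
    max_genes: int = DEFAULT_MAX_GENES,
    seed: int = 0,
) -> Path:
    """Node-link diagram of the subgraph induced by ``genes``.

    Refuses regions larger than ``max_genes`` — except that a binary-track
    overlay may satisfy the limit with its *present* gene count alone, in
    which case only present genes are drawn.  Node colors come from the
    overlay (binary membership or continuous value).
    """
    out = Path(out)
    present = [g for g in genes if g in net.genes]
    if len(present) > max_genes:
        if isinstance(overlay, SingleBinaryTrack):
            shown = [g for g in present if g in overlay.genes]
            if len(shown) > max_genes:
                raise RenderError(
                    f"{len(shown)} present genes exceed the {max_genes}-gene limit"
                )
            present = shown
        else:
            raise RenderError(
                f"{len(present)} genes exceed the {max_genes}-gene limit"
            )
    if not present:
        raise RenderError("no region genes found in the network")

    sub = net.graph.subgraph(present)
    pos = nx.spring_layout(sub, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    if isinstance(overlay, SingleBinaryTrack):
        colors = ["#c62828" if g in overlay.genes else "#b0bec5" for g in sub.nodes]
    elif isinstance(overlay, SingleContinuousTrack):
        vals = np.array([overlay.values.get(g, np.nan) for g in sub.nodes])
        vmax = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
        cmap = plt.get_cmap("RdBu_r")
        colors = [
            _MISSING_COLOR if np.isnan(v) else cmap(0.5 + 0.5 * v / (vmax or 1.0))
            for v in vals
        ]
    else:
        colors = "#90a4ae"
    nx.draw_networkx(
        sub, pos=pos, ax=ax, node_color=colors, node_size=180,
        font_size=6, edge_color="#78909c",
    )
    ax.set_axis_off()
    _save(fig, out)
    return out
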