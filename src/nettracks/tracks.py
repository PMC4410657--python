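"""Track data model and the six track file formats.

All per-gene evidence that is not the network itself is a *track*:

- :class:`SingleBinaryTrack`  — a gene set (``sbt`` files);
- :class:`SingleContinuousTrack` — one real value per gene (``sct``);
- :class:`CompositeTrack` — a gene x sample matrix, continuous (``cct``) or
  binary 0/1 (``cbt``);
- :class:`SampleInfo` — sample annotations (``tsi``);
- :class:`CategoricalTrack` — a multi-omics "snapshot": per gene and
  sub-track a code from {+2, +1, 0, -1, -2, missing} encoding strong/weak
  up- or down-alteration.

Formats are plain TSV, optionally gzip-compressed, with ``NA`` for missing
values; all readers and writers round-trip losslessly.  Gene symbols are
case-sensitive and never normalised: joins across tracks are exact-string.
"""

from __future__ import annotations

import ast
import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TrackError(ValueError):
    """Malformed track file or invalid track operation."""


def _open_text(path: Path, mode: str) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file (by .gz suffix)."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8", newline="\n")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8", newline="\n" if "w" in mode else None)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleBinaryTrack:
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class SingleContinuousTrack:
    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not math.isfinite(v):
                raise TrackError(f"track {self.name!r}: non-finite value for {g!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CompositeTrack:
    """Gene x sample matrix with ordered samples; NaN marks missing cells."""

    name: str
    data: pd.DataFrame  # index = genes, columns = samples
    kind: str = "continuous"  # or "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise TrackError(f"unknown composite kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TrackError(f"duplicate gene row {dup!r}")
        if self.data.columns.has_duplicates:
            raise TrackError("duplicate sample column")
        if self.kind == "binary":
            vals = self.data.to_numpy(dtype=float)
            bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise TrackError(
                    f"binary track {self.name!r}: value "
                    f"{vals[i, j]!r} at gene {self.data.index[i]!r} is not 0/1"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleInfo:
    """Sample x attribute table; each attribute is categorical or numeric."""

    data: pd.DataFrame  # index = samples
    types: dict[str, str] = field(default_factory=dict)  # attr -> cat|num

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise TrackError("duplicate sample identifier")
        for attr in self.data.columns:
            self.types.setdefault(attr, "cat")
            if self.types[attr] not in ("cat", "num"):
                raise TrackError(f"attribute {attr!r}: unknown type {self.types[attr]!r}")
            if self.types[attr] == "num":
                self.data[attr] = pd.to_numeric(self.data[attr], errors="raise")


SNAPSHOT_CODES = (-2, -1, 0, 1, 2)


@dataclass
class CategoricalTrack:
    """Snapshot track: gene x sub-track matrix of alteration codes.

    +2 strong up / significant, +1 weak up, 0 none, -1 weak down,
    -2 strong down, NaN missing.
    """

    name: str
    data: pd.DataFrame  # index = genes, columns = sub-track names

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals)
        for c in SNAPSHOT_CODES:
            ok |= vals == c
        if not ok.all():
            raise TrackError(f"snapshot {self.name!r}: code outside {SNAPSHOT_CODES}")

    @property
    def subtracks(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NA = "NA"


def _fmt(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return _NA
    return repr(v) if isinstance(v, float) else str(v)


def _track_name(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".cct", ".cbt", ".sct", ".sbt", ".tsi"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_track(path: str | Path, fmt: str | None = None):
    """Read a track file; format inferred from the extension if not given."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = stem.rsplit(".", 1)[-1]
    readers = {
        "cct": _read_composite_continuous,
        "cbt": _read_composite_binary,
        "sct": _read_sct,
        "sbt": _read_sbt,
        "tsi": _read_tsi,
    }
    if fmt not in readers:
        raise TrackError(f"unknown track format {fmt!r}")
    return readers[fmt](path)


def write_track(track, path: str | Path) -> None:
    path = Path(path)
    if isinstance(track, CompositeTrack):
        _write_composite(track, path)
    elif isinstance(track, SingleContinuousTrack):
        _write_sct(track, path)
    elif isinstance(track, SingleBinaryTrack):
        _write_sbt(track, path)
    elif isinstance(track, SampleInfo):
        _write_tsi(track, path)
    elif isinstance(track, CategoricalTrack):
        _write_composite(
            CompositeTrack(track.name, track.data, kind="continuous"), path
        )
    else:
        raise TrackError(f"cannot write object of type {type(track).__name__}")


def _read_matrix(path: Path) -> pd.DataFrame:
    with _open_text(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TrackError(f"{path}: empty file")
        cols = header.split("\t")
        samples = cols[1:]
        rows: list[list[float]] = []
        genes: list[str] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise TrackError(
                    f"{path}: line {lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            gene = parts[0]
            if gene in seen:
                raise TrackError(f"{path}: duplicate gene row {gene!r}")
            seen.add(gene)
            genes.append(gene)
            try:
                rows.append(
                    [math.nan if p == _NA else float(p) for p in parts[1:]]
                )
            except ValueError as exc:
                raise TrackError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, index=genes, columns=samples, dtype=float)


def _read_composite_continuous(path: Path) -> CompositeTrack:
    return CompositeTrack(_track_name(path), _read_matrix(path), kind="continuous")


def _read_composite_binary(path: Path) -> CompositeTrack:
    df = _read_matrix(path)
    vals = df.to_numpy()
    bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TrackError(
            f"{path}: value {vals[i, j]:g} for gene {df.index[i]!r} is not 0/1"
        )
    return CompositeTrack(_track_name(path), df, kind="binary")


def _write_composite(track: CompositeTrack, path: Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("gene\t" + "\t".join(map(str, track.data.columns)) + "\n")
        is_binary = track.kind == "binary"
        for gene, row in track.data.iterrows():
            cells = []
            for v in row.to_numpy(dtype=float):
                if math.isnan(v):
                    cells.append(_NA)
                elif is_binary:
                    cells.append(str(int(v)))
                else:
                    cells.append(repr(float(v)))
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def _read_sct(path: Path) -> SingleContinuousTrack:
    values: dict[str, float] = {}
    with _open_text(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TrackError(f"{path}: line {lineno}: expected 2 columns")
            gene, val = parts
            if gene in values:
                raise TrackError(f"{path}: duplicate gene row {gene!r}")
            try:
                values[gene] = float(val)
            except ValueError:
                raise TrackError(f"{path}: line {lineno}: bad value {val!r}") from None
    return SingleContinuousTrack(_track_name(path), values)


def _write_sct(track: SingleContinuousTrack, path: Path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(track.values):
            fh.write(f"{gene}\t{track.values[gene]!r}\n")


def _read_sbt(path: Path) -> SingleBinaryTrack:
    genes: set[str] = set()
    with _open_text(path, "rt") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line and not line.startswith("#"):
                genes.add(line)
    return SingleBinaryTrack(_track_name(path), frozenset(genes))


def _write_sbt(track: SingleBinaryTrack, path: Path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(track.genes):
            fh.write(gene + "\n")


def _read_tsi(path: Path) -> SampleInfo:
    with _open_text(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TrackError(f"{path}: empty file")
        cols = header.split("\t")
        attrs = cols[1:]
        types_line = fh.readline().rstrip("\n")
        if not types_line.startswith("#types"):
            raise TrackError(f"{path}: missing '#types' line")
        type_parts = types_line.split("\t")[1:]
        if len(type_parts) != len(attrs):
            raise TrackError(f"{path}: '#types' line does not match attribute count")
        rows, samples = [], []
        for lineno, raw in enumerate(fh, start=3):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise TrackError(
                    f"{path}: line {lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            samples.append(parts[0])
            rows.append([None if p == _NA else p for p in parts[1:]])
    df = pd.DataFrame(rows, index=samples, columns=attrs, dtype=object)
    types = dict(zip(attrs, type_parts))
    for attr, t in types.items():
        if t == "num":
            df[attr] = pd.to_numeric(df[attr])
    return SampleInfo(df, types)


def _write_tsi(info: SampleInfo, path: Path) -> None:
    attrs = list(info.data.columns)
    with _open_text(path, "wt") as fh:
        fh.write("sample\t" + "\t".join(attrs) + "\n")
        fh.write("#types\t" + "\t".join(info.types[a] for a in attrs) + "\n")
        for sample, row in info.data.iterrows():
            cells = []
            for a in attrs:
                v = row[a]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append(_NA)
                elif info.types[a] == "num":
                    cells.append(repr(float(v)))
                else:
                    cells.append(str(v))
            fh.write(str(sample) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Track construction and algebra
# ---------------------------------------------------------------------------

def gene_list_track(symbols: Sequence[str], name: str = "gene_list") -> SingleBinaryTrack:
    """Build a binary track from a user-entered symbol list (deduplicated)."""
    if not symbols:
        raise TrackError("empty gene list")
    genes = frozenset(symbols)
    dups = len(symbols) - len(genes)
    if dups:
        logger.info("gene_list_track: %d duplicate symbol(s) removed", dups)
    return SingleBinaryTrack(name, genes)


_CMP_OPS = (ast.Lt, ast.Gt, ast.LtE, ast.GtE, ast.Eq, ast.NotEq)


def _parse_predicate(expr: str, allowed: set[str]) -> ast.Expression:
    expr = expr.replace("≤", "<=").replace("≥", ">=")
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise TrackError(f"predicate syntax error at offset {exc.offset}: {exc.msg}") from None
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in allowed:
                raise TrackError(f"unknown track name {node.id!r} in predicate")
        elif isinstance(node, ast.Compare):
            if not all(isinstance(op, _CMP_OPS) for op in node.ops):
                raise TrackError("unsupported comparison operator")
        elif isinstance(node, (ast.Expression, ast.BoolOp, ast.And, ast.Or,
                               ast.UnaryOp, ast.Not, ast.USub, ast.Load,
                               *_CMP_OPS)):
            continue
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise TrackError(f"non-numeric constant {node.value!r} in predicate")
        else:
            raise TrackError(
                f"unsupported syntax in predicate: {type(node).__name__}"
            )
    return tree


def threshold_filter(
    inputs: Mapping[str, SingleContinuousTrack],
    predicate: str,
    name: str = "filtered",
) -> SingleBinaryTrack:
    """Derive a binary track from continuous tracks via a threshold predicate.

    ``predicate`` is a boolean expression over the track names using
    comparisons (``<``, ``>``, ``<=``, ``>=``) and ``and``/``or``/``not``,
    e.g. ``"fdr < 0.01 and fc > 2"``.  A gene is evaluated only if present in
    every referenced track; genes missing from any referenced track are
    excluded (the exclusion count is logged).
    """
    tree = _parse_predicate(predicate, set(inputs))
    referenced = sorted(
        {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}
    )
    if not referenced:
        raise TrackError("predicate references no tracks")
    code = compile(tree, "<predicate>", "eval")
    complete = set.intersection(
        *(set(inputs[r].values) for r in referenced)
    )
    union_all = set().union(*(set(inputs[r].values) for r in referenced))
    excluded = len(union_all) - len(complete)
    if excluded:
        logger.info("threshold_filter: %d gene(s) missing from some track, excluded", excluded)
    selected = {
        g
        for g in complete
        if eval(code, {"__builtins__": {}}, {r: inputs[r].values[g] for r in referenced})
    }
    return SingleBinaryTrack(name, frozenset(selected))


def boolean_combine(
    tracks: Mapping[str, SingleBinaryTrack],
    expr: str,
    name: str = "combined",
) -> tuple[SingleBinaryTrack, dict[frozenset[str], int]]:
    """Combine 2-5 binary tracks with AND/OR/NOT/XOR; report Venn regions.

    ``NOT`` is evaluated relative to the union of all supplied tracks.
    Returns the result track and the count of genes in each of the
    ``2**k - 1`` disjoint Venn regions, keyed by the frozenset of track
    names the region belongs to; counts sum to the union size.
    """
    if not 2 <= len(tracks) <= 5:
        raise TrackError("boolean_combine takes between 2 and 5 tracks")
    import re

    src = expr
    for word, repl in (("XOR", "^"), ("AND", "and"), ("OR", "or"), ("NOT", "not")):
        src = re.sub(rf"\b{word}\b", repl, src)
    try:
        parsed = ast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise TrackError(f"expression syntax error at offset {exc.offset}: {exc.msg}") from None
    for node in ast.walk(parsed):
        if isinstance(node, ast.Name) and node.id not in tracks:
            raise TrackError(f"unknown track name {node.id!r} in expression")
        if isinstance(node, (ast.Compare, ast.Call, ast.Constant)):
            raise TrackError("only track names and AND/OR/NOT/XOR are allowed")
        if isinstance(node, ast.BinOp) and not isinstance(node.op, ast.BitXor):
            raise TrackError("only track names and AND/OR/NOT/XOR are allowed")
    code = compile(parsed, "<boolexpr>", "eval")

    universe = sorted(set().union(*(t.genes for t in tracks.values())))
    names = list(tracks)
    selected: set[str] = set()
    regions: dict[frozenset[str], int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(sorted(names), r):
            regions[frozenset(combo)] = 0
    for gene in universe:
        member = {n: gene in tracks[n].genes for n in names}
        regions[frozenset(n for n in names if member[n])] += 1
        if eval(code, {"__builtins__": {}}, dict(member)):
            selected.add(gene)
    return SingleBinaryTrack(name, frozenset(selected)), regions


def sort_samples(
    track: CompositeTrack, info: SampleInfo, keys: Sequence[str]
) -> CompositeTrack:
    """Reorder a composite track's samples by annotation attributes.

    Stable sort; samples missing an attribute (or absent from ``info``) sort
    last.  Values are untouched — this is a pure column permutation.
    """
    for k in keys:
        if k not in info.data.columns:
            raise TrackError(f"unknown sample attribute {k!r}")
    if not keys:
        return CompositeTrack(track.name, track.data.copy(), kind=track.kind)
    ann = info.data.reindex(track.samples)
    order = ann.sort_values(list(keys), kind="stable", na_position="last").index
    return CompositeTrack(track.name, track.data.loc[:, list(order)], kind=track.kind)


# ---------------------------------------------------------------------------
# Snapshot assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceRule:
    """Sub-track: +2 for genes in a 'significant' list; optionally +1 for
    genes recurrently altered (fraction of samples with a 1 in a binary
    composite >= threshold), mirroring e.g. significantly mutated genes in
    red and genes mutated in >= 5% of samples in light red."""

    name: str
    significant: SingleBinaryTrack
    recurrence: CompositeTrack | None = None
    recurrence_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.recurrence_threshold <= 1:
            raise TrackError("recurrence threshold must be in (0, 1]")
        if self.recurrence is not None and self.recurrence.kind != "binary":
            raise TrackError("recurrence track must be binary")


@dataclass(frozen=True)
class SignedExpressionRule:
    """Sub-track from a differential table: significant genes coded +/-2 when
    the fold change magnitude reaches ``fc_strong``, +/-1 otherwise; the sign
    follows the direction of change.  ``stats`` is a GeneStatsTable frame
    with 'effect' (log2 scale) and 'fdr' columns."""

    name: str
    stats: pd.DataFrame
    fdr_max: float = 0.01
    fc_strong: float = 2.0


@dataclass(frozen=True)
class MembershipRule:
    """Sub-track: +2 for members of a binary track, 0 for every other gene
    in the supplied universe."""

    name: str
    track: SingleBinaryTrack
    universe: frozenset[str]


SnapshotRule = SignificanceRule | SignedExpressionRule | MembershipRule


def build_snapshot(rules: Sequence[SnapshotRule], name: str = "snapshot") -> CategoricalTrack:
    """Assemble an omics-snapshot categorical track from per-sub-track rules.

    Genes absent from a rule's inputs get a missing code in that sub-track.
    The gene universe of the snapshot is the union over rules.
    """
    if not rules:
        raise TrackError("no snapshot rules given")
    columns: dict[str, dict[str, float]] = {}
    for rule in rules:
        col: dict[str, float] = {}
        if isinstance(rule, SignificanceRule):
            for g in rule.significant.genes:
                col[g] = 2.0
            if rule.recurrence is not None:
                frac = rule.recurrence.data.mean(axis=1, skipna=True)
                for g, f in frac.items():
                    if g not in col:
                        col[g] = 1.0 if f >= rule.recurrence_threshold else 0.0
        elif isinstance(rule, SignedExpressionRule):
            for g, row in rule.stats.iterrows():
                fdr, eff = row.get("fdr"), row.get("effect")
                if fdr is None or eff is None or math.isnan(fdr) or math.isnan(eff):
                    continue
                if fdr >= rule.fdr_max:
                    col[g] = 0.0
                    continue
                strong = 2.0 ** abs(eff) >= rule.fc_strong
                col[g] = (2.0 if strong else 1.0) * (1 if eff >= 0 else -1)
        elif isinstance(rule, MembershipRule):
            for g in rule.universe:
                col[g] = 2.0 if g in rule.track.genes else 0.0
        else:
            raise TrackError(f"unknown snapshot rule type {type(rule).__name__}")
        columns[rule.name] = col
    df = pd.DataFrame(columns, dtype=float)
    df = df[[r.name for r in rules]]
    return CategoricalTrack(name, df)
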