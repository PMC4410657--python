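"""Per-gene cohort statistics on composite tracks.

Given a gene x sample matrix, these routines screen every gene for
association with a sample attribute: two-group differential tests (Welch t
or Wilcoxon rank-sum), univariate Cox proportional-hazards survival
screening, and Spearman correlation against another matrix or a per-sample
score (e.g. drug sensitivity).  Each screen returns a
:class:`GeneStatsTable` with the test statistic, an effect size, the nominal
two-sided p-value and its Benjamini–Hochberg FDR; significance calling then
thresholds FDR and fold change to produce a binary track.

Expression matrices are assumed to be on a log2 scale, so the differential
effect is a log2 fold change and ``fold change > 2`` means ``effect > 1``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tracks import CompositeTrack, SingleBinaryTrack, SingleContinuousTrack, _open_text

logger = logging.getLogger(__name__)

STATS_COLUMNS = ["stat", "effect", "p", "fdr", "n_used"]


class CohortError(ValueError):
    pass


@dataclass
class GeneStatsTable:
    """Per-gene screening results: stat, effect, p, fdr, n_used (by gene)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise CohortError(f"GeneStatsTable missing columns {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def write_tsv(self, path: str | Path) -> None:
        with _open_text(Path(path), "wt") as fh:
            fh.write("gene\t" + "\t".join(STATS_COLUMNS) + "\n")
            for gene, row in self.table.iterrows():
                cells = []
                for c in STATS_COLUMNS:
                    v = row[c]
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        cells.append("NA")
                    elif c == "n_used":
                        cells.append(str(int(v)))
                    else:
                        cells.append(repr(float(v)))
                fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneStatsTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index.name = None
        return cls(df)

    def to_sct(self, column: str, name: str | None = None) -> SingleContinuousTrack:
        """Export one numeric column as a single continuous track."""
        if column not in self.table.columns:
            raise CohortError(f"no column {column!r}")
        vals = {
            g: float(v)
            for g, v in self.table[column].items()
            if v is not None and not math.isnan(float(v))
        }
        return SingleContinuousTrack(name or column, vals)


@dataclass(frozen=True)
class GroupLabels:
    """Two-level categorical sample labels for differential testing."""

    labels: Mapping[str, str]

    def two_levels(self) -> tuple[str, str]:
        levels = sorted(set(self.labels.values()))
        if len(levels) != 2:
            raise CohortError(f"need exactly 2 group levels, got {len(levels)}")
        counts = {lv: sum(1 for v in self.labels.values() if v == lv) for lv in levels}
        for lv, c in counts.items():
            if c < 2:
                raise CohortError(f"group {lv!r} has fewer than 2 samples")
        return levels[0], levels[1]


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up time (>0) and event indicator (1 = event) per sample."""

    times: Mapping[str, float]
    events: Mapping[str, int]

    def __post_init__(self) -> None:
        for s, t in self.times.items():
            if not t > 0:
                raise CohortError(f"sample {s!r}: non-positive time {t}")
            if s not in self.events:
                raise CohortError(f"sample {s!r}: missing event indicator")
            if self.events[s] not in (0, 1):
                raise CohortError(f"sample {s!r}: event must be 0/1")
        if sum(self.events.values()) < 1:
            raise CohortError("survival data contains no events")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR: q(i) = min_{j>=i} p(j)*m/j on sorted p.

    NaN entries are excluded from the family and returned as NaN; input
    order is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise CohortError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[mask] = out
    return q


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------

def _wilcoxon_two_sided(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Rank-sum test; exact p when combined n <= 12 without ties, otherwise
    normal approximation with continuity and tie correction.  Returns
    (z-like statistic signed positive when group2 is higher, p)."""
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(g2, g1, alternative="two-sided", method=method)
    u = res.statistic
    mu = n1 * n2 / 2.0
    # Tie-corrected variance of U for the sign/statistic report.
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    var = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term)
    z = 0.0 if var == 0 else (u - mu) / math.sqrt(var)
    return z, float(res.pvalue)


def differential(
    track: CompositeTrack, groups: GroupLabels, method: str = "t"
) -> GeneStatsTable:
    """Two-group per-gene differential screen (Welch t or Wilcoxon).

    Sign convention: positive statistic and effect mean higher in the second
    group level (lexicographically larger label).  Effect is the group-mean
    difference of the (log2-scale) values.  Genes with fewer than 2
    non-missing values in either group get a missing p and are excluded from
    the FDR family.
    """
    if method not in ("t", "wilcoxon"):
        raise CohortError(f"unknown method {method!r}")
    lv1, lv2 = groups.two_levels()
    s1 = [s for s in track.samples if groups.labels.get(s) == lv1]
    s2 = [s for s in track.samples if groups.labels.get(s) == lv2]
    if len(s1) < 2 or len(s2) < 2:
        raise CohortError("each group needs >= 2 samples present in the track")

    rows = {}
    n_degenerate = 0
    m1 = track.data[s1].to_numpy(dtype=float)
    m2 = track.data[s2].to_numpy(dtype=float)
    for i, gene in enumerate(track.genes):
        g1 = m1[i][~np.isnan(m1[i])]
        g2 = m2[i][~np.isnan(m2[i])]
        n_used = g1.size + g2.size
        if g1.size < 2 or g2.size < 2:
            rows[gene] = (math.nan, math.nan, math.nan, n_used)
            continue
        effect = float(g2.mean() - g1.mean())
        if method == "t":
            if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
                if g1.mean() == g2.mean():
                    n_degenerate += 1
                    rows[gene] = (math.nan, effect, math.nan, n_used)
                    continue
                stat = math.inf if effect > 0 else -math.inf
                rows[gene] = (stat, effect, 0.0, n_used)
                continue
            res = sps.ttest_ind(g2, g1, equal_var=False)
            rows[gene] = (float(res.statistic), effect, float(res.pvalue), n_used)
        else:
            z, p = _wilcoxon_two_sided(g1, g2)
            rows[gene] = (z, effect, p, n_used)
    if n_degenerate:
        logger.info("differential: %d degenerate gene(s) with missing p", n_degenerate)

    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["stat", "effect", "p", "n_used"]
    )
    df = df.loc[track.genes]
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return GeneStatsTable(df[STATS_COLUMNS])


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

def _cox_prepare(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    return x[order], time[order], event[order]


def _cox_score_info(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                    beta: float) -> tuple[float, float, float]:
    """Score U, information I and log partial likelihood at ``beta``
    under the Breslow approximation for tied event times."""
    x, time, event = _cox_prepare(x, time, event)
    n = x.size
    w = np.exp(beta * x)
    # Suffix sums over the risk set {j : t_j >= t}.
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]
    # Risk set entry index for each event time (first sample with t_j >= t_i
    # is i itself after stable sort, but ties must share the full risk set).
    first_idx = np.searchsorted(time, time, side="left")
    ev = event == 1
    i0, i1, i2 = s0[first_idx[ev]], s1[first_idx[ev]], s2[first_idx[ev]]
    u = float(np.sum(x[ev] - i1 / i0))
    info = float(np.sum(i2 / i0 - (i1 / i0) ** 2))
    ll = float(np.sum(beta * x[ev] - np.log(i0)))
    return u, info, ll


def cox_univariate(
    x: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 50, tol: float = 1e-9,
) -> dict[str, float]:
    """Newton–Raphson fit of a one-covariate Cox model with Breslow ties.

    Returns beta, its standard error, the Wald two-sided p, and the score
    test chi-square at beta = 0 (equal to the log-rank statistic for a
    binary covariate).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    u0, i0, _ = _cox_score_info(x, time, event, 0.0)
    score_chi2 = u0 * u0 / i0 if i0 > 0 else math.nan
    score_p = float(sps.chi2.sf(score_chi2, df=1)) if i0 > 0 else math.nan

    beta, ll_prev = 0.0, -math.inf
    for _ in range(max_iter):
        u, info, ll = _cox_score_info(x, time, event, beta)
        if info <= 0:
            return dict(beta=math.nan, se=math.nan, p=math.nan,
                        score_chi2=score_chi2, score_p=score_p)
        step = u / info
        # Step-halving keeps the ascent monotone on awkward data.
        while abs(step) > 1e-8:
            _, _, ll_new = _cox_score_info(x, time, event, beta + step)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        if abs(step) < tol:
            break
        ll_prev = ll
    _, info, _ = _cox_score_info(x, time, event, beta)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return dict(beta=beta, se=se, p=p, score_chi2=score_chi2, score_p=score_p)


def survival_assoc(
    track: CompositeTrack,
    surv: SurvivalData,
    min_samples: int = 10,
    min_events: int = 3,
    use_score_test: bool = False,
) -> GeneStatsTable:
    """Per-gene univariate Cox screen of expression against survival.

    Effect is the Cox coefficient beta (positive = higher expression, worse
    survival); p is the Wald two-sided p (or the score test at beta = 0 when
    ``use_score_test``).  Genes with fewer than ``min_samples`` non-missing
    values or fewer than ``min_events`` events are given a missing p and
    excluded from the FDR family; constant covariates likewise.
    """
    shared = [s for s in track.samples if s in surv.times]
    if not shared:
        raise CohortError("no samples shared between track and survival data")
    t_all = np.array([surv.times[s] for s in shared], dtype=float)
    e_all = np.array([surv.events[s] for s in shared], dtype=int)
    if e_all.sum() == 0:
        raise CohortError("no events among shared samples")

    mat = track.data[shared].to_numpy(dtype=float)
    rows = {}
    n_skipped = 0
    for i, gene in enumerate(track.genes):
        keep = ~np.isnan(mat[i])
        x, t, e = mat[i][keep], t_all[keep], e_all[keep]
        n_used = int(keep.sum())
        if n_used < min_samples or e.sum() < min_events or np.ptp(x) == 0:
            n_skipped += 1
            rows[gene] = (math.nan, math.nan, math.nan, n_used)
            continue
        fit = cox_univariate(x, t, e)
        p = fit["score_p"] if use_score_test else fit["p"]
        stat = fit["score_chi2"] if use_score_test else (
            fit["beta"] / fit["se"] if fit["se"] > 0 else math.nan
        )
        rows[gene] = (stat, fit["beta"], p, n_used)
    if n_skipped:
        logger.info("survival_assoc: %d gene(s) skipped (guards/constant)", n_skipped)

    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["stat", "effect", "p", "n_used"]
    ).loc[track.genes]
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return GeneStatsTable(df[STATS_COLUMNS])


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

_PERM_CACHE: dict[tuple, np.ndarray] = {}


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = math.sqrt(float(np.dot(xr, xr)) * float(np.dot(yr, yr)))
    return float(np.dot(xr, yr)) / denom if denom > 0 else math.nan


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho (small n)."""
    xr, yr = sps.rankdata(x), sps.rankdata(y)
    rho = _spearman_rho(xr, yr)
    key = (tuple(np.sort(xr)), tuple(np.sort(yr)))
    if key not in _PERM_CACHE:
        base = np.sort(yr)
        _PERM_CACHE[key] = np.array(
            [_spearman_rho(np.sort(xr), np.array(p)) for p in
             itertools.permutations(base)]
        )
    null = _PERM_CACHE[key]
    # Invariance: rho distribution over permutations of y against fixed x
    # equals the distribution against sorted x.
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def correlate(
    a: CompositeTrack,
    b: "CompositeTrack | pd.Series",
    min_shared: int = 5,
) -> GeneStatsTable:
    """Per-gene Spearman correlation.

    When ``b`` is a composite track, each gene row of ``a`` is correlated
    with the matching row of ``b`` over shared samples; when ``b`` is a
    per-sample vector (``pd.Series`` indexed by sample, e.g. drug
    sensitivity), every gene row of ``a`` is correlated against it.  Exact
    permutation p for n < 10, t-approximation otherwise.
    """
    per_sample = isinstance(b, pd.Series)
    b_samples = list(b.index) if per_sample else b.samples
    shared = [s for s in a.samples if s in set(b_samples)]
    if not shared:
        raise CohortError("no shared samples")

    rows = {}
    genes = a.genes if per_sample else [g for g in a.genes if g in set(b.genes)]
    bvec = b.loc[shared].to_numpy(dtype=float) if per_sample else None
    for gene in genes:
        xa = a.data.loc[gene, shared].to_numpy(dtype=float)
        yb = bvec if per_sample else b.data.loc[gene, shared].to_numpy(dtype=float)
        keep = ~(np.isnan(xa) | np.isnan(yb))
        x, y = xa[keep], yb[keep]
        n = int(keep.sum())
        if n < min_shared:
            rows[gene] = (math.nan, math.nan, math.nan, n)
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[gene] = (math.nan, math.nan, math.nan, n)
            continue
        if n < 10:
            rho, p = _spearman_exact_p(x, y)
        else:
            res = sps.spearmanr(x, y)
            rho, p = float(res.statistic), float(res.pvalue)
        rows[gene] = (rho, rho, p, n)

    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["stat", "effect", "p", "n_used"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return GeneStatsTable(df[STATS_COLUMNS])


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def call_significant(
    stats: GeneStatsTable,
    fdr_max: float = 0.01,
    fold_min: float | None = None,
    direction: str = "both",
    name: str = "significant",
) -> SingleBinaryTrack:
    """Threshold a screen into a binary 'significant genes' track.

    A gene passes when ``fdr < fdr_max`` and, if ``fold_min`` is given, its
    fold change magnitude ``2**|effect|`` exceeds ``fold_min`` (effects are
    log2-scale).  ``direction`` restricts the sign of the effect.
    """
    if not 0 < fdr_max <= 1:
        raise CohortError("fdr_max must be in (0, 1]")
    if direction not in ("both", "up", "down"):
        raise CohortError(f"unknown direction {direction!r}")
    selected = set()
    for gene, row in stats.table.iterrows():
        fdr, eff = row["fdr"], row["effect"]
        if fdr is None or math.isnan(fdr) or fdr >= fdr_max:
            continue
        if direction == "up" and not eff > 0:
            continue
        if direction == "down" and not eff < 0:
            continue
        if fold_min is not None:
            if math.isnan(eff) or 2.0 ** abs(eff) <= fold_min:
                continue
        selected.add(gene)
    return SingleBinaryTrack(name, frozenset(selected))
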