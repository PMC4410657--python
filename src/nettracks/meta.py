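"""Cross-study integration by rank aggregation (order statistics).

Each study contributes a per-gene ranking (1 = most significant).  A gene
ranked r out of m genes has rank ratio r/m; across the N studies in which a
gene was measured, its sorted ratios r_(1) <= ... <= r_(N) are compared with
what N independent uniform order statistics would give.  The Q statistic is
the joint cumulative probability

    Q = P(U_(1) <= r_(1), ..., U_(N) <= r_(N)) = N! * V_N,

with the recursion V_0 = 1 and

    V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} * r_(N-k+1)^i / i!.

Small Q means the gene sits near the top of several studies at once —
e.g. consistently correlated with survival time in multiple cohorts.
Significance is calibrated empirically by Monte-Carlo simulation of the
uniform null, separately for each distinct study count N, followed by
Benjamini–Hochberg FDR over genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GeneStatsTable, bh_adjust
from .tracks import SingleBinaryTrack, SingleContinuousTrack

import logging

logger = logging.getLogger(__name__)

MAX_STUDIES = 20


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class StudyRanking:
    """One study's gene ranking: 1 = most significant; ties share average
    ranks.  ``m`` is the number of ranked genes in the study."""

    study: str
    ranks: Mapping[str, float]
    m: int

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.ranks) > self.m:
            raise MetaError(f"study {self.study!r}: inconsistent size m={self.m}")
        for g, r in self.ranks.items():
            if not 1 <= r <= self.m:
                raise MetaError(f"study {self.study!r}: rank {r} for {g!r} outside [1, m]")

    @classmethod
    def from_stats(
        cls, study: str, stats: GeneStatsTable, by: str = "p"
    ) -> "StudyRanking":
        """Rank a screening table by ascending p (default) or descending
        absolute statistic; untested genes (missing value) are dropped."""
        if by == "p":
            col = stats.table["p"]
            vals = col.to_numpy(dtype=float)
        elif by == "stat":
            vals = -np.abs(stats.table["stat"].to_numpy(dtype=float))
        else:
            raise MetaError(f"unknown ranking key {by!r}")
        genes = np.asarray(stats.table.index)
        keep = ~np.isnan(vals)
        ranks = sps.rankdata(vals[keep], method="average")
        return cls(study, dict(zip(genes[keep], ranks)), m=int(keep.sum()))


def rank_ratios(rankings: Sequence[StudyRanking]) -> pd.DataFrame:
    """Per-gene sorted rank ratios across studies.

    Returns a frame indexed by gene with one column per study (ratio
    rank/m, NaN where the gene is unranked) plus an ``N`` column counting
    contributing studies.
    """
    if len(rankings) < 2:
        raise MetaError("need at least 2 studies")
    names = [r.study for r in rankings]
    if len(set(names)) != len(names):
        raise MetaError("duplicate study names")
    cols = {
        r.study: pd.Series({g: rk / r.m for g, rk in r.ranks.items()})
        for r in rankings
    }
    df = pd.DataFrame(cols)
    df["N"] = df[names].notna().sum(axis=1)
    return df


def q_statistic(ratios: Sequence[float]) -> float:
    """Joint cumulative probability Q of sorted uniform order statistics.

    ``ratios`` must be ascending values in (0, 1]; Q = N! * V_N with the
    alternating recursion over V_k.  Q is in (0, 1] and is monotone
    non-decreasing in every ratio.
    """
    r = list(map(float, ratios))
    n = len(r)
    if not 1 <= n <= MAX_STUDIES:
        raise MetaError(f"need 1..{MAX_STUDIES} ratios, got {n}")
    for v in r:
        if not 0 < v <= 1:
            raise MetaError(f"ratio {v} outside (0, 1]")
    if any(r[i] > r[i + 1] for i in range(n - 1)):
        raise MetaError("ratios must be sorted ascending")
    v = [1.0]
    for k in range(1, n + 1):
        rk = r[n - k]  # r_(N-k+1), 1-based
        total = 0.0
        for i in range(1, k + 1):
            total += (-1.0) ** (i - 1) * v[k - i] * rk**i / math.factorial(i)
        v.append(total)
    return math.factorial(n) * v[n]


def q_statistic_null(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null: Q for ``reps`` draws of n sorted i.i.d. uniforms.

    Vectorised over replicates (the V_k recursion runs on arrays)."""
    r = np.sort(rng.random((reps, n)), axis=1)
    v = [np.ones(reps)]
    for k in range(1, n + 1):
        rk = r[:, n - k]
        total = np.zeros(reps)
        for i in range(1, k + 1):
            total += (-1.0) ** (i - 1) * v[k - i] * rk**i / math.factorial(i)
        v.append(total)
    return math.factorial(n) * v[n]


@dataclass
class IntegrationResult:
    """Per-gene integration: Q, study count N, empirical p and FDR."""

    table: pd.DataFrame  # columns Q, N, p_emp, fdr

    def to_sct(self, name: str = "meta_Q") -> SingleContinuousTrack:
        return SingleContinuousTrack(
            name, {g: float(v) for g, v in self.table["Q"].items()}
        )

    def significant(self, fdr_max: float = 0.01, name: str = "meta_significant") -> SingleBinaryTrack:
        sel = self.table.index[self.table["fdr"] < fdr_max]
        return SingleBinaryTrack(name, frozenset(sel))


def integrate_studies(
    rankings: Sequence[StudyRanking],
    mc_reps: int = 100_000,
    seed: int = 0,
) -> IntegrationResult:
    """Order-statistics integration of per-study rankings.

    Genes present in >= 2 studies get Q on their sorted rank ratios and an
    empirical p, p_emp = (1 + #{null Q <= Q_obs}) / (mc_reps + 1), against a
    null of N i.i.d. uniform ratios simulated separately per distinct N;
    FDR by Benjamini–Hochberg over all integrated genes.  Genes in fewer
    than 2 studies are excluded (count logged).
    """
    if mc_reps < 10_000:
        raise MetaError("mc_reps must be >= 10^4 for stable calibration")
    df = rank_ratios(rankings)
    names = [r.study for r in rankings]
    eligible = df[df["N"] >= 2]
    n_excluded = len(df) - len(eligible)
    if n_excluded:
        logger.info("integrate_studies: %d gene(s) in < 2 studies excluded", n_excluded)

    qs = {}
    for gene, row in eligible[names].iterrows():
        ratios = sorted(row.dropna().tolist())
        qs[gene] = q_statistic(ratios)

    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    for n in sorted(eligible["N"].unique()):
        nulls[int(n)] = np.sort(q_statistic_null(int(n), mc_reps, rng))

    out = {}
    for gene, q in qs.items():
        n = int(eligible.loc[gene, "N"])
        null = nulls[n]
        k = int(np.searchsorted(null, q, side="right"))
        out[gene] = (q, n, (1.0 + k) / (mc_reps + 1.0))
    table = pd.DataFrame.from_dict(out, orient="index", columns=["Q", "N", "p_emp"])
    table = table.sort_values(["Q", "p_emp"]).copy()
    table["fdr"] = bh_adjust(table["p_emp"].to_numpy())
    return IntegrationResult(table)


def consistent_overlap(
    tracks: Sequence[SingleBinaryTrack],
    min_studies: int,
    name: str = "consistent",
) -> SingleBinaryTrack:
    """Genes significant in at least ``min_studies`` of the given per-study
    binary tracks (min = #tracks is the plain intersection)."""
    if len(tracks) < 2:
        raise MetaError("need at least 2 tracks")
    if not 2 <= min_studies <= len(tracks):
        raise MetaError(f"min_studies must be in [2, {len(tracks)}]")
    counts: dict[str, int] = {}
    for t in tracks:
        for g in t.genes:
            counts[g] = counts.get(g, 0) + 1
    return SingleBinaryTrack(
        name, frozenset(g for g, c in counts.items() if c >= min_studies)
    )
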