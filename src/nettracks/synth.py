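"""Seeded synthetic-data generators with planted ground truth.

Everything the analysis modules consume can be generated here: stochastic
block-model networks with a planted (optionally two-level) module
structure, log2-scale expression cohorts with planted differential genes,
survival cohorts with planted prognostic genes (exponential hazards), and
binary mutation matrices with a hypermutated sample subgroup and planted
driver genes.  All generators are pure functions of (config, seed), so
fixtures never need to be stored: tests and pipelines re-create them.

Baselines mimic common data scales — expression ~ Normal(8, 1) like log2
microarray intensities; survival uses an exponential baseline hazard so
closed-form sanity checks exist — without attempting realistic tumor
biology (mutation spectra, copy-number segments), which the statistical
machinery does not require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GroupLabels, SurvivalData
from .network import Network
from .tracks import CompositeTrack, SampleInfo


class SynthError(ValueError):
    pass


@dataclass
class PlantedTruth:
    """Ground truth echoed by every generator for recovery tests."""

    seed: int
    config: dict
    blocks: dict[str, int] = field(default_factory=dict)  # gene -> block index
    effect_genes: frozenset[str] = frozenset()
    effect_size: float = 0.0


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def planted_network(
    blocks: Sequence[int],
    p_in: float,
    p_out: float,
    levels: int = 1,
    seed: int = 0,
    p_mid: float | None = None,
) -> tuple[Network, PlantedTruth]:
    """Stochastic block model with planted modules.

    With ``levels=2`` consecutive block pairs form super-blocks: edges
    within a block appear with ``p_in``, between blocks of the same
    super-block with ``p_mid`` (default geometric mean of p_in and p_out),
    and between super-blocks with ``p_out``.
    """
    if not 0 <= p_out < p_in <= 1:
        raise SynthError("need 0 <= p_out < p_in <= 1")
    if levels not in (1, 2):
        raise SynthError("levels must be 1 or 2")
    if p_mid is None:
        p_mid = float(np.sqrt(p_in * max(p_out, 1e-12))) if levels == 2 else p_out
    n = int(sum(blocks))
    genes = _gene_names(n)
    block_of: dict[str, int] = {}
    idx = 0
    for b, size in enumerate(blocks):
        for _ in range(size):
            block_of[genes[idx]] = b
            idx += 1
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = block_of[genes[i]], block_of[genes[j]]
            if bi == bj:
                p = p_in
            elif levels == 2 and bi // 2 == bj // 2:
                p = p_mid
            else:
                p = p_out
            if rng.random() < p:
                edges.append((genes[i], genes[j]))
    truth = PlantedTruth(
        seed=seed,
        config=dict(blocks=list(blocks), p_in=p_in, p_out=p_out,
                    levels=levels, p_mid=p_mid),
        blocks=block_of,
    )
    return Network.from_edges(edges), truth


def simulate_cohort(
    n_genes: int = 2000,
    n_group1: int = 30,
    n_group2: int = 30,
    n_de: int = 100,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> tuple[CompositeTrack, GroupLabels, PlantedTruth]:
    """Two-group expression cohort with planted differential genes.

    Baseline values are i.i.d. Normal(8, 1) on a log2-like scale; the first
    ``n_de`` genes are shifted upward by ``effect_sd`` standard deviations
    in group 2.
    """
    if n_de > n_genes:
        raise SynthError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"S{i:03d}" for i in range(n_group1 + n_group2)]
    mat = rng.normal(8.0, 1.0, size=(n_genes, n_group1 + n_group2))
    mat[:n_de, n_group1:] += effect_sd
    labels = {s: ("g1" if i < n_group1 else "g2") for i, s in enumerate(samples)}
    track = CompositeTrack(
        "sim_expression", pd.DataFrame(mat, index=genes, columns=samples)
    )
    truth = PlantedTruth(
        seed=seed,
        config=dict(n_genes=n_genes, n_group1=n_group1, n_group2=n_group2,
                    n_de=n_de, effect_sd=effect_sd),
        effect_genes=frozenset(genes[:n_de]),
        effect_size=effect_sd,
    )
    return track, GroupLabels(labels), truth


def simulate_survival(
    n_genes: int = 200,
    n_samples: int = 100,
    n_prognostic: int = 10,
    beta: float = 1.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> tuple[CompositeTrack, SurvivalData, PlantedTruth]:
    """Survival cohort with planted prognostic genes.

    Expression is standard normal per gene; each sample's hazard is an
    exponential baseline (rate 1) scaled by exp(beta * sum of its
    prognostic genes' expressions), so every prognostic gene carries the
    planted coefficient ``beta`` (with ``n_prognostic=1`` the univariate
    Cox fit recovers beta without omitted-covariate attenuation).
    Censoring is independent exponential with its rate tuned so that
    roughly ``censor_rate`` of samples are censored.
    """
    if n_prognostic > n_genes:
        raise SynthError("n_prognostic cannot exceed n_genes")
    if not 0 <= censor_rate < 1:
        raise SynthError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    risk = beta * expr[:n_prognostic].sum(axis=0)
    hazard = np.exp(risk)  # baseline rate 1
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # Tune the censoring rate so P(censor < event) ~ censor_rate:
        # with independent exponentials, P = c / (c + h) per sample.
        c_rate = censor_rate / (1 - censor_rate) * float(np.mean(hazard))
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        raise SynthError("simulation produced no events; lower censor_rate")
    track = CompositeTrack(
        "sim_survival_expr", pd.DataFrame(expr, index=genes, columns=samples)
    )
    surv = SurvivalData(
        times=dict(zip(samples, map(float, time))),
        events=dict(zip(samples, map(int, event))),
    )
    truth = PlantedTruth(
        seed=seed,
        config=dict(n_genes=n_genes, n_samples=n_samples,
                    n_prognostic=n_prognostic, beta=beta,
                    censor_rate=censor_rate),
        effect_genes=frozenset(genes[:n_prognostic]),
        effect_size=beta,
    )
    return track, surv, truth


def simulate_mutations(
    n_genes: int = 500,
    n_samples: int = 100,
    hyper_fraction: float = 0.15,
    rate_normal: float = 0.02,
    rate_hyper: float = 0.2,
    n_drivers: int = 5,
    driver_rate: float = 0.3,
    seed: int = 0,
) -> tuple[CompositeTrack, SampleInfo, PlantedTruth]:
    """Binary mutation matrix with a hypermutated subgroup and drivers.

    A ``hyper_fraction`` of samples mutate at ``rate_hyper`` instead of
    ``rate_normal`` across all genes; the first ``n_drivers`` genes are
    additionally mutated at ``driver_rate`` in every sample.  Sample info
    carries the hypermutated flag as a categorical attribute.
    """
    for r in (hyper_fraction, rate_normal, rate_hyper, driver_rate):
        if not 0 <= r <= 1:
            raise SynthError("rates and fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    n_hyper = int(round(hyper_fraction * n_samples))
    is_hyper = np.zeros(n_samples, dtype=bool)
    is_hyper[:n_hyper] = True
    rates = np.where(is_hyper, rate_hyper, rate_normal)
    mat = (rng.random((n_genes, n_samples)) < rates).astype(float)
    if n_drivers:
        extra = rng.random((n_drivers, n_samples)) < driver_rate
        mat[:n_drivers] = np.maximum(mat[:n_drivers], extra.astype(float))
    track = CompositeTrack(
        "sim_mutations", pd.DataFrame(mat, index=genes, columns=samples),
        kind="binary",
    )
    info = SampleInfo(
        pd.DataFrame(
            {"hypermutated": np.where(is_hyper, "yes", "no")}, index=samples
        ),
        types={"hypermutated": "cat"},
    )
    truth = PlantedTruth(
        seed=seed,
        config=dict(n_genes=n_genes, n_samples=n_samples,
                    hyper_fraction=hyper_fraction, rate_normal=rate_normal,
                    rate_hyper=rate_hyper, n_drivers=n_drivers,
                    driver_rate=driver_rate),
        effect_genes=frozenset(genes[:n_drivers]),
        effect_size=driver_rate,
    )
    return track, info, truth
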