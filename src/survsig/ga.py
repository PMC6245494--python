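"""Genetic-algorithm search over gene subsets for survival prediction.

Each chromosome is a 0/1 vector over the candidate features; fitness is
1 - C-index of the cluster-then-Cox risk model built from the selected
columns, so lower is better.  The population evolves by elitism,
rank-based roulette selection, single-point crossover and per-bit
mutation.  The clustering seed is held fixed inside the fitness function
so fitness is a deterministic function of the chromosome; fitness values
are cached across generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import SurvivalTable
from .risk import cluster_risk_groups, group_label_concordance, minmax_normalize

WORST_FITNESS = 1.0  # sentinel for degenerate (e.g. all-zero) chromosomes


@dataclass
class GAConfig:
    chromosome_length: int
    population_size: int = 200
    mutation_rate: float = 0.01
    generations: int = 100
    elitism_fraction: float = 0.2
    seed: int = 0
    cluster_seed: int = 0
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    fitness_trajectory: pd.DataFrame  # columns: generation, best, mean

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_chromosome)


def fitness(
    chromosome: np.ndarray,
    features: pd.DataFrame,
    survival: SurvivalTable,
    seed: int = 0,
    kmeans_restarts: int = 10,
) -> float:
    """1 - C-index of the risk model restricted to the selected features.

    An all-zero chromosome (no genes selected) returns the sentinel worst
    fitness 1.0; degenerate subsets that cannot be clustered do the same.
    """
    chrom = np.asarray(chromosome, dtype=int)
    if chrom.shape[0] != features.shape[1]:
        raise ValueError("chromosome length != number of candidate features")
    if chrom.sum() == 0:
        return WORST_FITNESS
    subset = features.iloc[:, np.flatnonzero(chrom)]
    try:
        normalized = minmax_normalize(subset)
        grouping = cluster_risk_groups(
            normalized, survival, seed=seed, n_init=kmeans_restarts
        )
    except ValueError:
        return WORST_FITNESS
    return 1.0 - group_label_concordance(grouping, survival)


def _rank_roulette_probs(fitnesses: np.ndarray) -> np.ndarray:
    """Selection probabilities proportional to rank (best gets the highest)."""
    order = np.argsort(fitnesses)  # ascending: best first
    ranks = np.empty_like(order)
    n = len(fitnesses)
    ranks[order] = np.arange(n, 0, -1)  # best -> n, worst -> 1
    return ranks / ranks.sum()


def run_ga(
    features: pd.DataFrame,
    survival: SurvivalTable,
    config: GAConfig,
    initial_chromosomes: Sequence[np.ndarray] | None = None,
) -> GAResult:
    """Evolve feature subsets minimizing 1 - C-index; deterministic per seed.

    Elitism copies the top fraction unchanged each generation, which makes
    the best fitness non-increasing across generations; the best-ever
    individual is returned.  ``initial_chromosomes`` lets callers inject
    known-good subsets (e.g. the full candidate set or a filtered subset)
    into the starting population, guaranteeing the search result is at
    least as fit as each of them.
    """
    if config.chromosome_length != features.shape[1]:
        raise ValueError(
            f"chromosome_length {config.chromosome_length} != "
            f"feature count {features.shape[1]}"
        )
    rng = np.random.default_rng(config.seed)
    pop = (rng.random((config.population_size, config.chromosome_length)) < 0.5).astype(
        np.int8
    )
    for i, chrom in enumerate(initial_chromosomes or []):
        chrom = np.asarray(chrom, dtype=np.int8)
        if chrom.shape[0] != config.chromosome_length:
            raise ValueError("initial chromosome length mismatch")
        if i < config.population_size:
            pop[i] = chrom
    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = fitness(
                chrom,
                features,
                survival,
                seed=config.cluster_seed,
                kmeans_restarts=config.kmeans_restarts,
            )
        return cache[key]

    n_elite = max(1, int(round(config.elitism_fraction * config.population_size)))
    best_chrom: np.ndarray | None = None
    best_fit = np.inf
    trajectory = []
    for gen in range(config.generations):
        fits = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit and pop[gen_best].sum() > 0:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        trajectory.append(
            {"generation": gen, "best": float(fits.min()), "mean": float(fits.mean())}
        )
        if gen == config.generations - 1:
            break
        elite_idx = np.argsort(fits)[:n_elite]
        children = [pop[i].copy() for i in elite_idx]
        probs = _rank_roulette_probs(fits)
        while len(children) < config.population_size:
            pa, pb = rng.choice(config.population_size, size=2, p=probs)
            point = rng.integers(1, config.chromosome_length) if config.chromosome_length > 1 else 0
            child = np.concatenate([pop[pa][:point], pop[pb][point:]]).astype(np.int8)
            flip = rng.random(config.chromosome_length) < config.mutation_rate
            child[flip] = 1 - child[flip]
            children.append(child)
        pop = np.array(children, dtype=np.int8)
    if best_chrom is None:
        # pathological: every evaluated individual degenerate; select a single gene
        best_chrom = np.zeros(config.chromosome_length, dtype=np.int8)
        best_chrom[0] = 1
        best_fit = evaluate(best_chrom)
    return GAResult(
        best_chromosome=best_chrom.astype(int),
        best_fitness=best_fit,
        fitness_trajectory=pd.DataFrame(trajectory),
    )
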