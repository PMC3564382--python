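"""Genetic algorithm for coexpressed gene sets.

A chromosome is a fixed-length binary inclusion vector over the candidate
gene universe (TF genes first, then nTF genes).  Fitness is the average
|PCC| over all pairs of included genes, where only significant, not-removed
pairs contribute (others count 0).  Selection is roulette-wheel, crossover
is one-point applied separately to the TF and nTF segments, mutation flips
bits independently, and random immigrants occasionally replace the worst
chromosome.  The best-ever chromosome is carried over each generation
(elitism), so the best-fitness trace is monotone and the stagnation-based
termination is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationStore
from .datamodel import DataError

_TOL = 1e-12


@dataclass
class GAConfig:
    pop_size: int = 100
    init_fraction: float = 0.02
    p_co: float = 0.7
    p_mu: float = 0.001
    p_new: float = 0.01
    max_generations: int = 5000
    stagnation_limit: int = 200
    crossover: str = "one_point"  # or "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("init_fraction", "p_co", "p_mu", "p_new"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.pop_size < 2:
            raise DataError("pop_size must be >= 2")
        if self.max_generations < 1 or self.stagnation_limit < 1:
            raise DataError("generation limits must be >= 1")


def _draw_chromosome(n: int, init_fraction: float, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        bits = rng.random(n) < init_fraction
        if bits.sum() >= 2:
            return bits
    raise DataError(
        f"could not draw a chromosome with >=2 genes at init_fraction="
        f"{init_fraction} over {n} genes after 100 attempts"
    )


def init_population(n_universe: int, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """pop_size x n boolean matrix; each gene included with p=init_fraction,
    chromosomes with fewer than 2 genes redrawn."""
    if n_universe < 2:
        raise DataError("universe must contain at least 2 genes")
    return np.stack(
        [_draw_chromosome(n_universe, config.init_fraction, rng)
         for _ in range(config.pop_size)]
    )


def coexpression_fitness(bits: np.ndarray, abs_cor: np.ndarray) -> float:
    """Mean |PCC| over all C(k,2) included-gene pairs (masked pairs count 0).

    Chromosomes with fewer than 2 genes have fitness 0 by convention.
    """
    k = int(bits.sum())
    if k < 2:
        return 0.0
    b = bits.astype(float)
    total = float(b @ abs_cor @ b) / 2.0
    return total / (k * (k - 1) / 2)


def _population_fitness(pop: np.ndarray, abs_cor: np.ndarray) -> np.ndarray:
    B = pop.astype(float)
    k = B.sum(axis=1)
    totals = np.einsum("ij,ij->i", B @ abs_cor, B) / 2.0
    npairs = k * (k - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = np.where(npairs > 0, totals / np.maximum(npairs, 1), 0.0)
    return fit


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Two parent indices drawn with probability proportional to fitness
    (with replacement; uniform fallback when all fitnesses are zero)."""
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise DataError("fitnesses must be non-negative")
    total = f.sum()
    p = None if total == 0 else f / total
    i, j = rng.choice(len(f), size=2, replace=True, p=p)
    return int(i), int(j)


def segment_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    p_co: float,
    tf_boundary: int,
    rng: np.random.Generator,
    kind: str = "one_point",
) -> tuple[np.ndarray, np.ndarray]:
    """Crossover applied separately to the TF segment [0, tf_boundary) and the
    nTF segment [tf_boundary, n); each segment crosses with probability p_co.

    ``one_point``: a random cut inside the segment, tails swapped.
    ``uniform``: each bit swapped independently with probability 1/2.
    Segments shorter than 2 bits are copied unchanged.
    """
    a, b = parent_a.copy(), parent_b.copy()
    for lo, hi in ((0, tf_boundary), (tf_boundary, len(a))):
        if hi - lo < 2 or rng.random() >= p_co:
            continue
        if kind == "one_point":
            cut = int(rng.integers(lo + 1, hi))
            a[cut:hi], b[cut:hi] = b[cut:hi].copy(), a[cut:hi].copy()
        elif kind == "uniform":
            swap = rng.random(hi - lo) < 0.5
            seg_a, seg_b = a[lo:hi].copy(), b[lo:hi].copy()
            a[lo:hi][swap], b[lo:hi][swap] = seg_b[swap], seg_a[swap]
        else:
            raise DataError(f"unknown crossover kind {kind!r}")
    return a, b


def mutate(bits: np.ndarray, p_mu: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability p_mu."""
    return bits ^ (rng.random(len(bits)) < p_mu)


def immigrate(
    pop: np.ndarray,
    fitnesses: np.ndarray,
    p_new: float,
    init_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """With probability p_new, replace the worst chromosome (ties: lowest
    index) by a freshly drawn init-style immigrant."""
    if rng.random() < p_new:
        worst = int(np.argmin(fitnesses))
        pop = pop.copy()
        pop[worst] = _draw_chromosome(pop.shape[1], init_fraction, rng)
    return pop


@dataclass
class GAResult:
    genes: list[str]
    fitness: float
    trace: pd.DataFrame  # generation, best_fitness, mean_fitness
    generations: int = 0


def run_ga(
    cor_store: CorrelationStore,
    tf_genes,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    universe: list[str] | None = None,
) -> GAResult:
    """Evolve a population and return the best-ever coexpressed gene set.

    ``tf_genes`` marks which universe members are TF-class (they form the
    first chromosome segment for segment-wise crossover).  The universe
    defaults to every gene in the correlation store.
    """
    config = config or GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if universe is None:
        universe = list(cor_store.genes)
    if not universe:
        raise DataError("empty gene universe")
    tf_set = set(tf_genes)
    ordered = sorted([g for g in universe if g in tf_set]) + sorted(
        [g for g in universe if g not in tf_set]
    )
    tf_boundary = sum(1 for g in ordered if g in tf_set)
    idx = [cor_store.gene_index[g] for g in ordered]
    A = cor_store.usable_gg_abs()[np.ix_(idx, idx)]
    n = len(ordered)

    pop = init_population(n, config, rng)
    fit = _population_fitness(pop, A)
    best_i = int(np.argmax(fit))
    best_bits, best_fit = pop[best_i].copy(), float(fit[best_i])
    trace = [(0, best_fit, float(fit.mean()))]
    stagnation = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        children = [best_bits.copy()]  # elitism
        while len(children) < config.pop_size:
            i, j = roulette_select(fit, rng)
            a, b = segment_crossover(
                pop[i], pop[j], config.p_co, tf_boundary, rng, config.crossover
            )
            children.append(mutate(a, config.p_mu, rng))
            if len(children) < config.pop_size:
                children.append(mutate(b, config.p_mu, rng))
        pop = np.stack(children)
        fit = _population_fitness(pop, A)
        pop = immigrate(pop, fit, config.p_new, config.init_fraction, rng)
        fit = _population_fitness(pop, A)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit + _TOL:
            best_fit = float(fit[gen_best])
            best_bits = pop[gen_best].copy()
            stagnation = 0
        else:
            stagnation += 1
        trace.append((gen, best_fit, float(fit.mean())))
        if stagnation >= config.stagnation_limit:
            break
    genes = [g for g, on in zip(ordered, best_bits) if on]
    return GAResult(
        genes=genes,
        fitness=best_fit,
        trace=pd.DataFrame(trace, columns=["generation", "best_fitness", "mean_fitness"]),
        generations=gen,
    )
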