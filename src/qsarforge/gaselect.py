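"""Genetic-algorithm search for a fixed-size descriptor subset.

Chromosomes are fixed-size sets of descriptor column indices. Each
generation applies tournament selection, uniform crossover (child repaired
to the fixed size), single-member swap mutation, and elitism. Fitness is a
cross-validated quality of an OLS model on the candidate subset — Q²_LOO by
default (computed through the closed-form PRESS identity), with PRESS and
training R² selectable. Repeated seeded runs yield a ranked list of
alternative models, from which the best is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, SingularFitError, TableError
from .table import DescriptorTable
from .validate import press_loo_ols

FITNESS_FUNCTIONS = ("q2_loo", "press", "r2")
_TOURNAMENT_SIZE = 3
_UNFIT = -np.inf  # fitness assigned to singular/degenerate subsets


@dataclass
class GaConfig:
    """GA hyperparameters; all exposed, defaults sized for small QSAR pools."""

    subset_size: int = 5
    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    fitness: str = "q2_loo"
    n_runs: int = 1
    seed: int = 0

    def validate(self, n_descriptors: int | None = None) -> None:
        if self.subset_size < 1:
            raise ConfigurationError("subset_size must be >= 1")
        if n_descriptors is not None and self.subset_size > n_descriptors:
            raise ConfigurationError(
                f"subset_size ({self.subset_size}) exceeds available "
                f"descriptors ({n_descriptors})")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism <= self.population_size:
            raise ConfigurationError("elitism must be in [0, population_size]")
        if self.fitness not in FITNESS_FUNCTIONS:
            raise ConfigurationError(f"fitness must be one of {FITNESS_FUNCTIONS}")
        if self.n_runs < 1 or self.n_generations < 0:
            raise ConfigurationError("n_runs >= 1 and n_generations >= 0 required")


@dataclass
class GaRun:
    """Winner of one GA run."""

    subset: list[str]
    fitness: float
    generation_found: int
    seed: int
    best_per_generation: list[float] = field(default_factory=list, repr=False)


@dataclass
class GaResult:
    runs: list[GaRun]
    best: int

    @property
    def best_run(self) -> GaRun:
        return self.runs[self.best]

    @property
    def best_subset(self) -> list[str]:
        return self.best_run.subset

    def ranked(self) -> list[GaRun]:
        return sorted(self.runs, key=lambda r: (-r.fitness, r.subset))

    def to_dict(self) -> dict:
        return {
            "runs": [
                {"subset": r.subset, "fitness": r.fitness,
                 "generation_found": r.generation_found, "seed": r.seed}
                for r in self.runs
            ],
            "best": self.best,
            "best_subset": self.best_subset,
        }


def make_fitness(X: np.ndarray, y: np.ndarray, kind: str = "q2_loo"):
    """Build a subset-fitness callable over column-index tuples.

    Larger is always better: PRESS is negated. Rank-deficient subsets score
    ``-inf`` so the search simply moves past them.
    """
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def fitness(idx: tuple[int, ...]) -> float:
        cols = X[:, list(idx)]
        try:
            press, q2 = press_loo_ols(cols, y)
        except SingularFitError:
            return _UNFIT
        if kind == "q2_loo":
            return q2
        if kind == "press":
            return -press
        # training R^2 via the same QR solve
        design = np.column_stack([np.ones(len(y)), cols])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return 1.0 - float(np.sum(resid ** 2)) / ss_tot

    return fitness


def _random_subset(rng: np.random.Generator, p: int, k: int) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(p, size=k, replace=False).tolist()))


def _crossover(rng, a: tuple[int, ...], b: tuple[int, ...], k: int) -> tuple[int, ...]:
    # uniform crossover repaired to fixed size: keep shared genes, fill the
    # remainder from the symmetric difference in random order
    shared = sorted(set(a) & set(b))
    pool = np.array(sorted(set(a) ^ set(b)))
    need = k - len(shared)
    if need > 0:
        fill = rng.choice(pool, size=need, replace=False).tolist()
        return tuple(sorted(shared + fill))
    return tuple(shared[:k])


def _mutate(rng, chrom: tuple[int, ...], p: int) -> tuple[int, ...]:
    outside = np.setdiff1d(np.arange(p), chrom)
    if len(outside) == 0:
        return chrom
    pos = int(rng.integers(len(chrom)))
    new = int(rng.choice(outside))
    genes = list(chrom)
    genes[pos] = new
    return tuple(sorted(genes))


def _tournament(rng, scored: list[tuple[float, tuple[int, ...]]]) -> tuple[int, ...]:
    picks = rng.integers(0, len(scored), size=_TOURNAMENT_SIZE)
    best = max(picks, key=lambda i: scored[i][0])
    return scored[best][1]


def _run_once(X: np.ndarray, y: np.ndarray, names: list[str],
              config: GaConfig, seed: int) -> GaRun:
    p = X.shape[1]
    k = config.subset_size
    rng = np.random.default_rng(seed)
    fitness = make_fitness(X, y, config.fitness)
    cache: dict[tuple[int, ...], float] = {}

    def score(chrom: tuple[int, ...]) -> float:
        if chrom not in cache:
            cache[chrom] = fitness(chrom)
        return cache[chrom]

    def sort_key(item):
        fit, chrom = item
        return (-fit, tuple(names[j] for j in chrom))  # lexicographic tie-break

    if p == k:
        only = tuple(range(p))
        return GaRun(subset=[names[j] for j in only], fitness=score(only),
                     generation_found=0, seed=seed, best_per_generation=[score(only)])

    population = {_random_subset(rng, p, k) for _ in range(config.population_size)}
    while len(population) < config.population_size:
        population.add(_random_subset(rng, p, k))
    scored = sorted(((score(c), c) for c in population), key=sort_key)

    best_fit, best_chrom = scored[0]
    best_gen = 0
    history = [best_fit]
    for gen in range(1, config.n_generations + 1):
        next_pop: list[tuple[int, ...]] = [c for _, c in scored[:config.elitism]]
        while len(next_pop) < config.population_size:
            parent_a = _tournament(rng, scored)
            parent_b = _tournament(rng, scored)
            if rng.random() < config.crossover_rate:
                child = _crossover(rng, parent_a, parent_b, k)
            else:
                child = parent_a
            if rng.random() < config.mutation_rate:
                child = _mutate(rng, child, p)
            next_pop.append(child)
        scored = sorted(((score(c), c) for c in next_pop), key=sort_key)
        gen_fit, gen_chrom = scored[0]
        if gen_fit > best_fit or (
                gen_fit == best_fit
                and tuple(names[j] for j in gen_chrom) < tuple(names[j] for j in best_chrom)):
            best_fit, best_chrom, best_gen = gen_fit, gen_chrom, gen
        history.append(best_fit)
    return GaRun(subset=[names[j] for j in best_chrom], fitness=float(best_fit),
                 generation_found=best_gen, seed=seed, best_per_generation=history)


def ga_select(table: DescriptorTable, config: GaConfig | None = None) -> GaResult:
    """Run the GA ``config.n_runs`` times and rank the winning subsets.

    Each run draws its RNG from a spawned seed sequence, so runs are
    independent yet the whole result is deterministic under ``config.seed``.
    """
    config = config or GaConfig()
    if table.activity is None:
        raise TableError("GA selection requires an activity vector")
    config.validate(table.n_descriptors)
    X, y = table.X, table.y
    names = table.descriptor_names
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(config.seed).spawn(config.n_runs)]
    runs = [_run_once(X, y, names, config, s) for s in seeds]
    best = min(range(len(runs)),
               key=lambda i: (-runs[i].fitness, runs[i].subset))
    return GaResult(runs=runs, best=best)


def exhaustive_select(table: DescriptorTable, subset_size: int,
                      fitness: str = "q2_loo") -> tuple[list[str], float]:
    """Enumerate every subset of the given size and return the best.

    Intended as an independent check of the GA on small pools; cost grows as
    C(p, k).
    """
    from itertools import combinations

    if table.activity is None:
        raise TableError("exhaustive selection requires an activity vector")
    X, y = table.X, table.y
    names = table.descriptor_names
    score = make_fitness(X, y, fitness)
    best_fit = -np.inf
    best_names: list[str] | None = None
    for chrom in combinations(range(table.n_descriptors), subset_size):
        fit = score(chrom)
        cand = [names[j] for j in chrom]
        if fit > best_fit or (fit == best_fit
                              and (best_names is None or cand < best_names)):
            best_fit, best_names = fit, cand
    assert best_names is not None
    return best_names, float(best_fit)
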