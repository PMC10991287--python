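"""Hybrid feature selection: a genetic algorithm over feature bitmasks
followed by recursive feature elimination on the GA winner's subset.

Each GA genome is a boolean mask over the p design-matrix columns; its
fitness is the cross-validated mean squared error of a ridge regression on
the binary label restricted to the masked columns (lower is better).  The GA
runs elitist generations (the printed configuration: 18 generations of 80
genomes — 40 elites carried plus 40 fresh random genomes — with a 5%
crossover rate and a 0.05 per-bit mutation rate).  RFE then iteratively drops
the lowest-|coefficient| features from the GA subset until the requested
count remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .records_io import DomainError, FeatureMatrix


class ConfigError(ValueError):
    """Inconsistent selection configuration."""


WORST_FITNESS = float("inf")


@dataclass(eq=False)
class Genome:
    """One candidate feature subset: a boolean mask plus its CV-MSE fitness."""

    mask: np.ndarray
    fitness: float = WORST_FITNESS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class GAConfig:
    generations: int = 18
    population: int = 80
    elites: int = 40
    randoms: int = 40
    crossover_rate: float = 0.05
    mutation_rate: float = 0.05
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ConfigError("population must be positive")
        if self.elites + self.randoms > self.population:
            raise ConfigError("elites + randoms must not exceed population")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")


@dataclass
class RFEConfig:
    n_keep: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.n_keep < 1:
            raise ConfigError("n_keep must be at least 1")
        if self.step < 1:
            raise ConfigError("step must be at least 1")


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def genome_fitness(g: Genome, X: FeatureMatrix | np.ndarray, y: np.ndarray,
                   seed: int = 0, cv_folds: int = 3) -> float:
    """Cross-validated MSE of the ridge base learner on the masked columns.

    An all-zero mask is not scorable and receives the +inf sentinel rather
    than raising, so the GA can discard it by ordinary selection.
    """
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    if g.mask.size != Xa.shape[1]:
        raise DomainError("mask length does not match column count")
    if g.n_selected == 0:
        return WORST_FITNESS
    Xm = Xa[:, g.mask]
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errs = []
    for train_idx, test_idx in kf.split(Xm):
        model = Ridge(alpha=1.0)
        model.fit(Xm[train_idx], y[train_idx])
        pred = model.predict(Xm[test_idx])
        errs.append(np.mean((pred - y[test_idx]) ** 2))
    return float(np.mean(errs))


def select_elites(pop: Sequence[Genome], n: int) -> list[Genome]:
    """The n lowest-MSE genomes; ties broken by earlier population index."""
    if n > len(pop):
        raise DomainError(f"cannot select {n} elites from population of {len(pop)}")
    order = sorted(range(len(pop)), key=lambda i: (pop[i].fitness, i))
    return [pop[i] for i in order[:n]]


def crossover_genomes(a: Genome, b: Genome, rate: float,
                      rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Single-point crossover with probability ``rate``, else parents unchanged."""
    if a.mask.size != b.mask.size:
        raise DomainError("genome length mismatch")
    p = a.mask.size
    if rng.uniform() >= rate or p < 2:
        return Genome(a.mask.copy()), Genome(b.mask.copy())
    cut = int(rng.integers(1, p))
    c1 = np.concatenate([a.mask[:cut], b.mask[cut:]])
    c2 = np.concatenate([b.mask[:cut], a.mask[cut:]])
    return Genome(c1), Genome(c2)


def mutate_genome(g: Genome, rate: float, rng: np.random.Generator) -> Genome:
    """Flip each bit independently with probability ``rate``."""
    if not (0 <= rate <= 1):
        raise DomainError("mutation rate must be in [0, 1]")
    flips = rng.uniform(size=g.mask.size) < rate
    return Genome(np.logical_xor(g.mask, flips))


def _random_genome(p: int, rng: np.random.Generator) -> Genome:
    mask = rng.uniform(size=p) < 0.5
    if not mask.any():
        mask[rng.integers(p)] = True
    return Genome(mask)


def ga_select(X: FeatureMatrix | np.ndarray, y: np.ndarray,
              cfg: GAConfig | None = None) -> tuple[Genome, list[float]]:
    """Elitist GA over feature masks; returns the best-ever genome and the
    per-generation best-fitness history (non-increasing by elitism)."""
    cfg = cfg or GAConfig()
    Xa = _as_array(X)
    p = Xa.shape[1]
    rng = np.random.default_rng(cfg.seed)

    def score(g: Genome) -> Genome:
        return replace(g, fitness=genome_fitness(g, Xa, y, seed=cfg.seed,
                                                 cv_folds=cfg.cv_folds))

    pop = [score(_random_genome(p, rng)) for _ in range(cfg.population)]
    best = min(pop, key=lambda g: g.fitness)
    history = [best.fitness]

    for _ in range(cfg.generations):
        elites = select_elites(pop, cfg.elites)
        children: list[Genome] = []
        # crossover + mutation on the elite mating pool
        pool = list(elites)
        rng.shuffle(pool)
        for i in range(0, len(pool) - 1, 2):
            c1, c2 = crossover_genomes(pool[i], pool[i + 1],
                                       cfg.crossover_rate, rng)
            children.extend([mutate_genome(c1, cfg.mutation_rate, rng),
                             mutate_genome(c2, cfg.mutation_rate, rng)])
        randoms = [_random_genome(p, rng) for _ in range(cfg.randoms)]
        nextgen = elites + randoms + children
        nextgen = nextgen[:cfg.population]
        while len(nextgen) < cfg.population:
            nextgen.append(_random_genome(p, rng))
        pop = [g if np.isfinite(g.fitness) else score(g) for g in nextgen]
        gen_best = min(pop, key=lambda g: g.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best
        history.append(best.fitness)

    return best, history


def rfe_select(X: FeatureMatrix | np.ndarray, y: np.ndarray,
               cfg: RFEConfig, columns: Sequence[int] | None = None) -> list[int]:
    """Recursive feature elimination by ridge |coefficient| on standardized
    columns; returns the surviving column indices (ascending)."""
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    alive = list(columns) if columns is not None else list(range(Xa.shape[1]))
    if cfg.n_keep > len(alive):
        raise DomainError(
            f"n_keep={cfg.n_keep} exceeds available feature count {len(alive)}")
    while len(alive) > cfg.n_keep:
        Xs = _standardize(Xa[:, alive])
        model = Ridge(alpha=1.0)
        model.fit(Xs, y)
        importance = np.abs(model.coef_)
        n_drop = min(cfg.step, len(alive) - cfg.n_keep)
        drop_order = np.argsort(importance, kind="stable")[:n_drop]
        for local in sorted(drop_order, reverse=True):
            del alive[local]
    return sorted(alive)


def hybrid_select(X: FeatureMatrix | np.ndarray, y: np.ndarray,
                  ga_cfg: GAConfig | None = None,
                  rfe_cfg: RFEConfig | None = None) -> list[int]:
    """GA global search, then RFE refinement of the GA-selected subset.

    The result is always a subset of the GA winner's features.  Raises
    :class:`ConfigError` if ``n_keep`` exceeds the GA subset size.
    """
    best, _ = ga_select(X, y, ga_cfg)
    ga_subset = [int(i) for i in np.flatnonzero(best.mask)]
    if rfe_cfg is None:
        return ga_subset
    if rfe_cfg.n_keep > len(ga_subset):
        raise ConfigError(
            f"n_keep={rfe_cfg.n_keep} exceeds GA subset size {len(ga_subset)}")
    return rfe_select(X, y, rfe_cfg, columns=ga_subset)


def selection_report(history: list[float], mask: np.ndarray,
                     column_names: Sequence[str]) -> dict:
    """JSON-serializable summary of a selection run."""
    kept = [column_names[i] for i in np.flatnonzero(mask)]
    return {
        "per_generation_best_fitness": [float(f) for f in history],
        "final_mask": [bool(b) for b in mask],
        "kept_columns": kept,
    }
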