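"""Adaptive elephant-herd optimization (AEHOM).

A clan-structured population metaheuristic (minimization convention).  Per
generation, every clan member steps toward its clan's best elephant
(p' = p + c·(best - p)·r with per-dimension uniform r), the matriarch is
re-placed at l times the clan center, the worst members of each clan are
"separated" to fresh uniform positions in the search box, the best elephants
of randomly paired clans exchange a two-point-crossover gene segment (cut
points x1 = ⌊L/3⌋, x2 = x1 + ⌊L/2⌋), and genes mutate to fresh uniform
draws at a per-gene rate.  The best-ever position is retained elitely, so the
convergence history is non-increasing.

For weight training, herd positions decode to flattened network parameter
vectors and fitness is the training-set mean squared error; a schedule
interleaves herd generations with online backpropagation refinement of the
incumbent best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import mldcnn
from .records_io import DomainError


class ConfigError(ValueError):
    """Invalid herd configuration."""


class DivergenceError(RuntimeError):
    """Fitness became non-finite."""


@dataclass
class HerdConfig:
    """Herd geometry, operator scales and search-box bounds.

    ``c`` scales the pull toward the clan best; ``l`` scales the matriarch's
    jump to the clan center; ``n_worst`` elephants per clan are re-seeded
    uniformly each generation.
    """

    n_clans: int = 3
    clan_size: int = 10
    c: float = 0.5
    l: float = 0.1
    n_worst: int = 1
    p_min: float = -1.0
    p_max: float = 1.0
    dims: int = 2
    generations: int = 50
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.c <= 1) or not (0 <= self.l <= 1):
            raise ConfigError("c and l must lie in [0, 1]")
        if self.p_min >= self.p_max:
            raise ConfigError("p_min must be below p_max")
        if self.n_worst >= self.clan_size:
            raise ConfigError("n_worst must be below clan_size")
        if self.n_clans < 1 or self.clan_size < 1:
            raise ConfigError("herd must contain at least one clan and elephant")


@dataclass
class Herd:
    """Clan-indexed positions and fitnesses plus the elitist best-ever."""

    positions: np.ndarray  # (n_clans, clan_size, dims)
    fitnesses: np.ndarray  # (n_clans, clan_size)
    best_position: np.ndarray
    best_fitness: float


def _clip(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(p, lo, hi)


def clan_update(p: np.ndarray, clan_best: np.ndarray, c: float,
                r: np.ndarray | float,
                bounds: tuple[float, float] = (-np.inf, np.inf)) -> np.ndarray:
    """Step toward the clan best: p + c·(clan_best - p)·r, clipped to bounds."""
    p = np.asarray(p, dtype=float)
    clan_best = np.asarray(clan_best, dtype=float)
    if p.shape != clan_best.shape:
        raise DomainError("dimension mismatch between position and clan best")
    return _clip(p + c * (clan_best - p) * r, *bounds)


def clan_center(positions: np.ndarray) -> np.ndarray:
    """Per-dimension mean of the clan's positions."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise DomainError("empty clan has no center")
    return positions.mean(axis=0)


def matriarch_update(positions: np.ndarray, l: float,
                     bounds: tuple[float, float] = (-np.inf, np.inf)) -> np.ndarray:
    """New matriarch position l·(clan center), clipped to bounds."""
    return _clip(l * clan_center(positions), *bounds)


def separate_worst(positions: np.ndarray, fitnesses: np.ndarray,
                   bounds: tuple[float, float], n_worst: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Re-seed the n_worst lowest-fitness elephants uniformly in the box:
    p = P_min + (P_max - P_min)·k with fresh k ~ U(0,1) per dimension."""
    if n_worst >= len(fitnesses):
        raise ConfigError("n_worst must be below the clan size")
    out = np.array(positions, dtype=float)
    if n_worst == 0:
        return out
    worst = np.argsort(fitnesses, kind="stable")[-n_worst:]
    lo, hi = bounds
    for idx in worst:
        k = rng.uniform(size=out.shape[1])
        out[idx] = lo + (hi - lo) * k
    return out


def crossover_points(L: int) -> tuple[int, int]:
    """Two-point-crossover cut indices x1 = ⌊L/3⌋, x2 = x1 + ⌊L/2⌋."""
    x1 = L // 3
    x2 = x1 + L // 2
    if L < 6 or x1 < 1 or x2 > L or x1 >= x2:
        raise DomainError(f"two-point crossover undefined for L={L} (need L >= 6)")
    return x1, x2


def crossover_positions(p1: np.ndarray, p2: np.ndarray,
                        L: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Exchange genes in [x1, x2) between the parents."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise DomainError("parent dimension mismatch")
    L = p1.size if L is None else L
    x1, x2 = crossover_points(L)
    c1, c2 = p1.copy(), p2.copy()
    c1[x1:x2], c2[x1:x2] = p2[x1:x2], p1[x1:x2]
    return c1, c2


def mutate_position(p: np.ndarray, rate: float, bounds: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Each gene independently redrawn uniformly within bounds at ``rate``."""
    if not (0 <= rate <= 1):
        raise DomainError("mutation rate must be in [0, 1]")
    p = np.array(p, dtype=float)
    lo, hi = bounds
    hit = rng.uniform(size=p.size) < rate
    p[hit] = rng.uniform(lo, hi, size=int(hit.sum()))
    return p


def optimize(fitness_fn: Callable[[np.ndarray], float],
             cfg: HerdConfig,
             refine: Callable[[np.ndarray], np.ndarray] | None = None,
             refine_every: int = 0) -> tuple[np.ndarray, list[float]]:
    """Run the herd on ``fitness_fn`` (lower is better) over the box
    [p_min, p_max]^dims; returns the best-ever position and the per-generation
    best-ever fitness history (non-increasing).

    Two-point crossover needs at least 6 dimensions; in lower-dimensional
    spaces that operator is skipped and the remaining operators carry the
    search.

    ``refine``, when given, is called every ``refine_every`` generations with
    the incumbent best position; its (clipped) return value replaces the
    herd's currently worst elephant, and the best-ever is updated if the
    refinement improved on it — so the elitist history stays non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = (cfg.p_min, cfg.p_max)
    shape = (cfg.n_clans, cfg.clan_size, cfg.dims)
    positions = rng.uniform(cfg.p_min, cfg.p_max, size=shape)

    def evaluate(P: np.ndarray) -> np.ndarray:
        F = np.empty(P.shape[:2])
        for ci in range(P.shape[0]):
            for ei in range(P.shape[1]):
                F[ci, ei] = fitness_fn(P[ci, ei])
        if not np.all(np.isfinite(F)):
            raise DivergenceError("non-finite fitness encountered")
        return F

    fitnesses = evaluate(positions)
    flat = int(np.argmin(fitnesses))
    best_pos = positions.reshape(-1, cfg.dims)[flat].copy()
    best_fit = float(fitnesses.reshape(-1)[flat])
    history = [best_fit]

    can_cross = cfg.dims >= 6

    for gen in range(1, cfg.generations + 1):
        new_positions = np.empty_like(positions)
        for ci in range(cfg.n_clans):
            clan = positions[ci]
            fit = fitnesses[ci]
            best_idx = int(np.argmin(fit))
            clan_best = clan[best_idx]
            for ei in range(cfg.clan_size):
                if ei == best_idx:
                    new_positions[ci, ei] = matriarch_update(clan, cfg.l, bounds)
                else:
                    r = rng.uniform(size=cfg.dims)
                    new_positions[ci, ei] = clan_update(clan[ei], clan_best,
                                                        cfg.c, r, bounds)
            new_positions[ci] = separate_worst(new_positions[ci], fit, bounds,
                                               cfg.n_worst, rng)

        # crossover between the best elephants of randomly paired clans
        if can_cross and cfg.n_clans >= 2:
            order = rng.permutation(cfg.n_clans)
            for i in range(0, cfg.n_clans - 1, 2):
                ca, cb = order[i], order[i + 1]
                ba = int(np.argmin(fitnesses[ca]))
                bb = int(np.argmin(fitnesses[cb]))
                child_a, child_b = crossover_positions(new_positions[ca, ba],
                                                       new_positions[cb, bb])
                wa = int(np.argmax(fitnesses[ca]))
                wb = int(np.argmax(fitnesses[cb]))
                new_positions[ca, wa] = child_a
                new_positions[cb, wb] = child_b

        # mutation on every non-matriarch elephant
        for ci in range(cfg.n_clans):
            best_idx = int(np.argmin(fitnesses[ci]))
            for ei in range(cfg.clan_size):
                if ei != best_idx:
                    new_positions[ci, ei] = mutate_position(
                        new_positions[ci, ei], cfg.mutation_rate, bounds, rng)

        positions = new_positions
        fitnesses = evaluate(positions)
        flat = int(np.argmin(fitnesses))
        gen_best = float(fitnesses.reshape(-1)[flat])
        if gen_best < best_fit:
            best_fit = gen_best
            best_pos = positions.reshape(-1, cfg.dims)[flat].copy()

        if refine is not None and refine_every > 0 and gen % refine_every == 0:
            candidate = _clip(np.asarray(refine(best_pos.copy()), dtype=float),
                              *bounds)
            cand_fit = float(fitness_fn(candidate))
            worst = int(np.argmax(fitnesses))
            ci, ei = np.unravel_index(worst, fitnesses.shape)
            positions[ci, ei] = candidate
            fitnesses[ci, ei] = cand_fit
            if cand_fit < best_fit:
                best_fit = cand_fit
                best_pos = candidate.copy()

        history.append(best_fit)

    return best_pos, history


def encode_network(net: mldcnn.Network) -> np.ndarray:
    """Flatten the network layer-major: weights then biases per layer."""
    parts = []
    for W, b in zip(net.weights, net.biases):
        parts.append(W.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def decode_network(vector: np.ndarray, layer_sizes: Sequence[int]) -> mldcnn.Network:
    """Inverse of :func:`encode_network` for the given architecture."""
    vector = np.asarray(vector, dtype=float)
    expected = sum(n_in * n_out + n_out
                   for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]))
    if vector.size != expected:
        raise ConfigError(
            f"vector length {vector.size} does not match architecture "
            f"{tuple(layer_sizes)} ({expected} parameters)")
    weights, biases = [], []
    pos = 0
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(vector[pos:pos + n_in * n_out].reshape(n_out, n_in))
        pos += n_in * n_out
        biases.append(vector[pos:pos + n_out].copy())
        pos += n_out
    return mldcnn.Network(weights, biases)


@dataclass
class TrainingSchedule:
    """Interleaving of herd generations and backprop refinement epochs."""

    aehom_generations: int = 25
    backprop_every: int = 5
    backprop_epochs: int = 1
    final_backprop_epochs: int = 20


def train_network_aehom(net_cfg: mldcnn.NetworkConfig, X: np.ndarray,
                        y: np.ndarray, herd_cfg: HerdConfig | None = None,
                        schedule: TrainingSchedule | None = None
                        ) -> tuple[mldcnn.Network, list[float]]:
    """Optimize network weights with the herd, interleaved with backprop.

    Herd positions decode to full weight vectors and fitness is the
    training-set MSE.  Every ``backprop_every`` herd generations the incumbent
    best is refined by ``backprop_epochs`` online epochs and re-injected; a
    final backprop polish runs after the herd finishes.  With zero herd
    generations this reduces to pure backprop from the seeded random init.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    schedule = schedule or TrainingSchedule()
    dims = mldcnn.init_network(net_cfg).n_parameters
    if herd_cfg is None:
        herd_cfg = HerdConfig(dims=dims, seed=net_cfg.seed)
    if herd_cfg.dims != dims:
        raise ConfigError(
            f"herd dims {herd_cfg.dims} != network parameter count {dims}")

    def fitness(vec: np.ndarray) -> float:
        net = decode_network(vec, net_cfg.layer_sizes)
        preds = mldcnn.forward_batch(net, X)
        return float(np.mean((preds - y) ** 2))

    history: list[float] = []
    if schedule.aehom_generations > 0:
        bp_cfg = mldcnn.NetworkConfig(
            layer_sizes=net_cfg.layer_sizes, alpha=net_cfg.alpha,
            epochs=schedule.backprop_epochs, init_scale=net_cfg.init_scale,
            seed=net_cfg.seed, threshold=net_cfg.threshold)

        def refine(vec: np.ndarray) -> np.ndarray:
            net = decode_network(vec, net_cfg.layer_sizes)
            net, _ = mldcnn.train_backprop(net, X, y, bp_cfg)
            return encode_network(net)

        run_cfg = HerdConfig(**{**herd_cfg.__dict__,
                                "generations": schedule.aehom_generations})
        best_vec, hist = optimize(
            fitness, run_cfg,
            refine=refine if schedule.backprop_epochs > 0 else None,
            refine_every=schedule.backprop_every)
        history.extend(hist)
        start_net = decode_network(best_vec, net_cfg.layer_sizes)
    else:
        start_net = mldcnn.init_network(net_cfg)

    final_cfg = mldcnn.NetworkConfig(
        layer_sizes=net_cfg.layer_sizes, alpha=net_cfg.alpha,
        epochs=schedule.final_backprop_epochs, init_scale=net_cfg.init_scale,
        seed=net_cfg.seed, threshold=net_cfg.threshold)
    if schedule.final_backprop_epochs > 0:
        trained, final_hist = mldcnn.train_backprop(start_net, X, y, final_cfg)
        history.extend(final_hist)
    else:
        trained = start_net
    return trained, history
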