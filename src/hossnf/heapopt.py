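"""Heap-based optimizer (HBO).

A population metaheuristic modeled on a corporate hierarchy: the K search
agents are arranged in a d-ary min-heap keyed by fitness, so every agent has
an immediate "boss" (its heap parent) and "colleagues" (the parent's other
children).  Each iteration an agent proposes a move composed per dimension by
a roulette draw: keep the coordinate, move toward the boss, move toward a
better colleague, or push away from a worse one, with step sizes scaled by a
periodic control coefficient gamma that cycles between exploration (large
steps) and exploitation (near-zero steps).  Moves are accepted greedily —
only a strict fitness improvement changes an agent's position — so the
incumbent best never degrades.

Minimization convention throughout; negate a maximization objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ObjectiveError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HOConfig:
    dimensions: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    population_size: int = 20
    max_iterations: int = 100
    heap_degree: int = 3
    cycles: int | None = None  # default max(1, max_iterations // 25)
    per_agent_roulette: bool = False
    seed: int = 0
    #: optional (m, G) array of starting positions for the first m agents,
    #: e.g. a known good parameter vector; clipped into bounds.
    initial_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        if lo.size == 1:
            lo = np.full(self.dimensions, lo[0])
        if hi.size == 1:
            hi = np.full(self.dimensions, hi[0])
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        if lo.shape != (self.dimensions,) or hi.shape != (self.dimensions,):
            raise ConfigError("bounds must have length == dimensions")
        if not np.all(lo < hi):
            raise ConfigError("lower bounds must be elementwise below upper bounds")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.heap_degree < 2:
            raise ConfigError("heap_degree must be >= 2")

    @property
    def effective_cycles(self) -> int:
        if self.cycles is not None:
            return max(1, self.cycles)
        return max(1, self.max_iterations // 25)


@dataclass(frozen=True)
class RouletteSegments:
    """Cumulative branch probabilities 0 <= o1 <= o2 <= o3 = 1."""

    o1: float
    o2: float
    o3: float = 1.0


@dataclass
class HeapState:
    positions: np.ndarray          # (K, G)
    fitness: np.ndarray            # (K,)
    heap: np.ndarray               # heap order -> agent index
    heap_pos: np.ndarray           # agent index -> heap order
    iteration: int
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    rng: np.random.Generator
    n_evals: int = 0


@dataclass(frozen=True)
class HOResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    n_evals: int


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def gamma_schedule(p: int, P: int, C: int) -> float:
    """Periodic step-size coefficient gamma = |2 - (p mod T) / ceil(P / 4C)|
    with period T = ceil(P / C); sweeps 2 -> 0 -> 2 within each cycle."""
    period = math.ceil(P / C)
    quarter = math.ceil(P / (4 * C))
    return abs(2.0 - (p % period) / quarter)


def roulette_thresholds(p: int, P: int) -> RouletteSegments:
    """Branch probabilities: the keep probability o1 = 1 - p/P decays
    linearly, so move proposals become more frequent as the run progresses;
    the remaining mass is split evenly between the boss branch and the
    colleague branches."""
    o1 = 1.0 - p / P
    o2 = o1 + (1.0 - o1) / 2.0
    return RouletteSegments(o1=o1, o2=o2, o3=1.0)


# ---------------------------------------------------------------------------
# heap bookkeeping (array-encoded d-ary min-heap over agent indices)
# ---------------------------------------------------------------------------

def _key(state: HeapState, agent: int) -> tuple[float, int]:
    # fitness with agent index as deterministic tie-break
    return (state.fitness[agent], agent)


def _sift_up(state: HeapState, h: int, degree: int) -> None:
    heap, pos = state.heap, state.heap_pos
    while h > 0:
        parent = (h - 1) // degree
        if _key(state, heap[h]) < _key(state, heap[parent]):
            heap[h], heap[parent] = heap[parent], heap[h]
            pos[heap[h]] = h
            pos[heap[parent]] = parent
            h = parent
        else:
            break


def _build_heap(state: HeapState) -> None:
    order = sorted(range(len(state.fitness)), key=lambda a: _key(state, a))
    state.heap[:] = order
    state.heap_pos[state.heap] = np.arange(len(order))


def heap_is_valid(state: HeapState, degree: int) -> bool:
    """Exhaustive heap-property check (every parent key <= child key)."""
    K = len(state.heap)
    for h in range(1, K):
        parent = (h - 1) // degree
        if _key(state, state.heap[parent]) > _key(state, state.heap[h]):
            return False
    return True


# ---------------------------------------------------------------------------
# core steps
# ---------------------------------------------------------------------------

def initialize(cfg: HOConfig, f) -> HeapState:
    """Seeded uniform initialization within bounds, fitness evaluation and
    heap construction."""
    rng = np.random.default_rng(cfg.seed)
    K, G = cfg.population_size, cfg.dimensions
    positions = rng.uniform(cfg.lower_bounds, cfg.upper_bounds, size=(K, G))
    if cfg.initial_positions is not None:
        x0 = np.atleast_2d(np.asarray(cfg.initial_positions, dtype=float))
        m = min(len(x0), K)
        positions[:m] = np.clip(x0[:m], cfg.lower_bounds, cfg.upper_bounds)
    fitness = np.array([float(f(positions[i])) for i in range(K)])
    if not np.all(np.isfinite(fitness)):
        raise ObjectiveError("objective returned a non-finite value at initialization")
    state = HeapState(
        positions=positions,
        fitness=fitness,
        heap=np.zeros(K, dtype=int),
        heap_pos=np.zeros(K, dtype=int),
        iteration=0,
        best_position=positions[0].copy(),
        best_fitness=float("inf"),
        history=[],
        rng=rng,
        n_evals=K,
    )
    _build_heap(state)
    best = int(state.heap[0])
    state.best_position = positions[best].copy()
    state.best_fitness = float(fitness[best])
    state.history.append(state.best_fitness)
    return state


def _colleague(state: HeapState, h: int, degree: int) -> int:
    """A random sibling under the same heap parent; falls back to any other
    agent when the node has no siblings (or is the root)."""
    K = len(state.heap)
    if h > 0:
        parent = (h - 1) // degree
        first = degree * parent + 1
        sibs = [s for s in range(first, min(first + degree, K)) if s != h]
        if sibs:
            pick = sibs[int(state.rng.integers(len(sibs)))]
            return int(state.heap[pick])
    agent = int(state.heap[h])
    other = int(state.rng.integers(K - 1))
    return other + 1 if other >= agent else other


def propose_move(
    state: HeapState,
    i: int,
    gamma: float,
    segments: RouletteSegments,
    cfg: HOConfig,
) -> np.ndarray:
    """Candidate position for agent ``i`` (not yet accepted).

    Per dimension m a roulette draw o ~ U(0,1) selects among: keep the
    coordinate (o <= o1); step around the boss D (o1 < o <= o2); step around
    a better colleague N (o2 < o, g(N) < g(x)); or step away from a worse
    colleague relative to self (otherwise).  Steps are gamma * beta * |ref -
    x| with beta ~ U(-1, 1).  The root has no boss; its boss branch uses the
    colleague rule instead.  Result is clipped into the box bounds.
    """
    rng = state.rng
    G = cfg.dimensions
    x = state.positions[i]
    h = int(state.heap_pos[i])
    degree = cfg.heap_degree

    has_parent = h > 0
    if has_parent:
        boss = int(state.heap[(h - 1) // degree])
        D = state.positions[boss]
    colleague = _colleague(state, h, degree)
    N = state.positions[colleague]
    colleague_better = _key(state, colleague) < _key(state, i)

    if cfg.per_agent_roulette:
        o = np.full(G, rng.random())
    else:
        o = rng.random(G)
    beta = rng.uniform(-1.0, 1.0, G)

    cand = x.copy()
    boss_branch = (o > segments.o1) & (o <= segments.o2)
    coll_branch = o > segments.o2
    if not has_parent:
        coll_branch = coll_branch | boss_branch
        boss_branch = np.zeros(G, dtype=bool)

    if boss_branch.any():
        step = gamma * beta * np.abs(D - x)
        cand[boss_branch] = D[boss_branch] + step[boss_branch]
    if coll_branch.any():
        step = gamma * beta * np.abs(N - x)
        ref = N if colleague_better else x
        cand[coll_branch] = ref[coll_branch] + step[coll_branch]

    return np.clip(cand, cfg.lower_bounds, cfg.upper_bounds)


def step(state: HeapState, f, cfg: HOConfig) -> HeapState:
    """One HBO iteration: every agent proposes; strictly better candidates
    are accepted and the heap repaired; the best-so-far history grows by one
    entry (non-increasing by construction)."""
    p = state.iteration + 1
    gamma = gamma_schedule(p, cfg.max_iterations, cfg.effective_cycles)
    segments = roulette_thresholds(p, cfg.max_iterations)

    for i in range(cfg.population_size):
        cand = propose_move(state, i, gamma, segments, cfg)
        if np.array_equal(cand, state.positions[i]):
            continue  # all dims kept; objective is deterministic
        fc = float(f(cand))
        state.n_evals += 1
        if not np.isfinite(fc):
            logger.warning("non-finite candidate fitness for agent %d rejected", i)
            continue
        if fc < state.fitness[i]:
            state.positions[i] = cand
            state.fitness[i] = fc
            _sift_up(state, int(state.heap_pos[i]), cfg.heap_degree)
            if fc < state.best_fitness:
                state.best_fitness = fc
                state.best_position = cand.copy()

    state.iteration = p
    state.history.append(state.best_fitness)
    return state


def optimize(f, cfg: HOConfig) -> HOResult:
    """Run initialization plus ``max_iterations`` steps; deterministic given
    ``cfg.seed``."""
    state = initialize(cfg, f)
    for _ in range(cfg.max_iterations):
        step(state, f, cfg)
    return HOResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=list(state.history),
        n_evals=state.n_evals,
    )
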