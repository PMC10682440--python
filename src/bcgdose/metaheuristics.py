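"""Metaheuristic minimizers for the regimen search: PSO, SA and ACO.

All three work on a box-bounded objective ``f(x) -> float`` and are fully
seeded.  They are dimension-generic; the regimen problem uses the 3-vector
(d, g, N).

* PSO: velocity update V <- w*V + c1*r1*(p_best - P) + c2*r2*(g_best - P)
  with r1, r2 ~ U[0,1] per particle, per dimension, per iteration; positions
  clamped to the bounds.
* SA: Gaussian proposals (componentwise scale = proposal_scale * range,
  reflected at the bounds); downhill moves always accepted, uphill moves with
  probability exp(-delta_c / T); geometric cooling T <- T * Cr.
* ACO: each variable is discretized to a layer of levels; an ant picks one
  level per layer with probability proportional to pheromone^alpha *
  heuristic^beta; pheromone evaporates at rate eps and each ant deposits
  Q / cost on the levels it chose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PSOConfig",
    "SAConfig",
    "ACOConfig",
    "OptimizerResult",
    "pso_minimize",
    "sa_minimize",
    "aco_minimize",
    "acceptance_probability",
    "selection_probabilities",
    "minimize",
]


@dataclass
class PSOConfig:
    inertia: float = 0.5
    c1: float = 0.5
    c2: float = 0.5
    swarm_size: int = 100
    max_iters: int = 200
    seed: Optional[int] = None


@dataclass
class SAConfig:
    t0: float = 1.0
    cooling: float = 0.95           # geometric cooling ratio Cr
    proposal_scale: float = 0.1     # Gaussian sd as a fraction of each range
    moves_per_temp: int = 20        # proposals per temperature level (epoch)
    integer_move_prob: float = 0.3  # chance of a +-1 integer step on flagged dims
    integer_dims: tuple = (2,)      # dims with integer-well structure (N)
    max_iters: int = 200
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.cooling < 1:
            raise ValueError("cooling ratio must lie in (0, 1)")
        if self.moves_per_temp < 1:
            raise ValueError("moves_per_temp must be >= 1")


@dataclass
class ACOConfig:
    grids: Optional[Sequence[np.ndarray]] = None  # explicit levels per layer
    heuristics: Optional[Sequence[np.ndarray]] = None  # eta per level per layer
    exponent_alpha: float = 1.0     # pheromone exponent (not the model's alpha)
    exponent_beta: float = 1.0      # heuristic exponent (not the model's beta)
    evaporation: float = 0.1
    deposit: float = 1.0            # Q in the deposit rule Q / cost
    n_ants: int = 50
    max_iters: int = 200
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation rate must lie in (0, 1)")
        if self.exponent_alpha < 0 or self.exponent_beta < 0:
            raise ValueError("exponents must be nonnegative")


@dataclass
class OptimizerResult:
    best_point: np.ndarray
    best_cost: float
    history: np.ndarray        # best-ever cost after initialization and each iteration
    n_evaluations: int
    seed: Optional[int]


def _as_box(bounds) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SearchBounds-like object (lower/upper) or a (lo, hi) pair."""
    if hasattr(bounds, "lower") and hasattr(bounds, "upper"):
        lo, hi = np.asarray(bounds.lower, float), np.asarray(bounds.upper, float)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if lo.shape != hi.shape or np.any(lo >= hi):
        raise ValueError("bounds must satisfy lower < upper componentwise")
    return lo, hi


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    bounds,
    config: Optional[PSOConfig] = None,
    init_point=None,
) -> OptimizerResult:
    """Particle swarm minimization with position clamping at the bounds.

    One particle starts at ``init_point`` (if given), the rest uniformly in
    the box; velocities start uniform in +-(upper - lower), which keeps the
    swarm exploring for longer before the (strongly contracting) default
    coefficients collapse it.  ``max_iters=0`` degenerates to evaluating the
    initial swarm.
    """
    cfg = config or PSOConfig()
    if cfg.swarm_size < 1:
        raise ValueError("swarm_size must be >= 1")
    if cfg.max_iters < 0:
        raise ValueError("max_iters must be >= 0")
    lo, hi = _as_box(bounds)
    dim = lo.size
    rng = np.random.default_rng(cfg.seed)

    pos = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    if init_point is not None:
        pos[0] = np.clip(np.asarray(init_point, float), lo, hi)
    vel = rng.uniform(-(hi - lo), hi - lo, size=(cfg.swarm_size, dim))
    costs = np.array([objective(p) for p in pos])
    n_evals = cfg.swarm_size

    pbest = pos.copy()
    pbest_cost = costs.copy()
    g_idx = int(np.argmin(pbest_cost))
    gbest = pbest[g_idx].copy()
    gbest_cost = float(pbest_cost[g_idx])
    history = [gbest_cost]

    for _ in range(cfg.max_iters):
        r1 = rng.uniform(size=(cfg.swarm_size, dim))
        r2 = rng.uniform(size=(cfg.swarm_size, dim))
        vel = (cfg.inertia * vel
               + cfg.c1 * r1 * (pbest - pos)
               + cfg.c2 * r2 * (gbest - pos))
        pos = np.clip(pos + vel, lo, hi)
        costs = np.array([objective(p) for p in pos])
        n_evals += cfg.swarm_size
        improved = costs < pbest_cost
        pbest[improved] = pos[improved]
        pbest_cost[improved] = costs[improved]
        g_idx = int(np.argmin(pbest_cost))
        if pbest_cost[g_idx] < gbest_cost:
            gbest = pbest[g_idx].copy()
            gbest_cost = float(pbest_cost[g_idx])
        history.append(gbest_cost)

    return OptimizerResult(gbest, gbest_cost, np.array(history), n_evals, cfg.seed)


def acceptance_probability(delta_c: float, temperature: float) -> float:
    """Metropolis rule: 1 for improving moves, exp(-delta_c/T) otherwise."""
    if delta_c < 0:
        return 1.0
    if temperature <= 0:
        return 0.0
    return float(np.exp(-delta_c / temperature))


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold a point back into the box by reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def sa_minimize(
    objective: Callable[[np.ndarray], float],
    bounds,
    config: Optional[SAConfig] = None,
    init_point=None,
) -> OptimizerResult:
    """Simulated annealing: an epoch of proposals per temperature level.

    Each iteration holds the temperature fixed for ``moves_per_temp`` Gaussian
    proposals, then cools geometrically.  On dimensions listed in
    ``integer_dims`` a proposal is, with probability ``integer_move_prob``,
    replaced by an exact +-1 integer step: the integer-relaxation penalty of
    the regimen cost digs deep wells at integer treatment counts that purely
    Gaussian moves cross too rarely.
    """
    cfg = config or SAConfig()
    if cfg.max_iters < 0:
        raise ValueError("max_iters must be >= 0")
    lo, hi = _as_box(bounds)
    rng = np.random.default_rng(cfg.seed)

    x = (np.clip(np.asarray(init_point, float), lo, hi)
         if init_point is not None else rng.uniform(lo, hi))
    cost = objective(x)
    n_evals = 1
    best, best_cost = x.copy(), float(cost)
    history = [best_cost]
    temp = cfg.t0
    scale = cfg.proposal_scale * (hi - lo)
    integer_dims = [d for d in cfg.integer_dims if d < lo.size]

    for _ in range(cfg.max_iters):
        for _move in range(cfg.moves_per_temp):
            proposal = _reflect(x + rng.normal(0.0, scale), lo, hi)
            if integer_dims and rng.uniform() < cfg.integer_move_prob:
                for d in integer_dims:
                    proposal[d] = np.clip(
                        np.floor(x[d] + 0.5) + rng.choice([-1.0, 1.0]), lo[d], hi[d]
                    )
            new_cost = objective(proposal)
            n_evals += 1
            if rng.uniform() < acceptance_probability(new_cost - cost, temp):
                x, cost = proposal, new_cost
                if cost < best_cost:
                    best, best_cost = x.copy(), float(cost)
        temp *= cfg.cooling
        history.append(best_cost)

    return OptimizerResult(best, best_cost, np.array(history), n_evals, cfg.seed)


def selection_probabilities(pheromone: np.ndarray, heuristic: np.ndarray,
                            exponent_alpha: float, exponent_beta: float) -> np.ndarray:
    """Per-layer level probabilities, proportional to rho^alpha * eta^beta."""
    weights = pheromone ** exponent_alpha * heuristic ** exponent_beta
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("degenerate pheromone/heuristic weights (all zero)")
    return weights / total


def _is_regimen_box(lo: np.ndarray, hi: np.ndarray) -> bool:
    return lo.size == 3 and np.all(lo >= 0) and hi[1] > lo[1] >= 1 and lo[2] >= 1


def _default_grids(lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray]:
    """Layer levels for the regimen box: d in 0.1 steps, g and N integer.

    For generic problems each layer is a 21-point linspace.
    """
    if _is_regimen_box(lo, hi):
        d = np.round(np.arange(lo[0], hi[0] + 1e-9, 0.1), 10)
        g = np.arange(np.ceil(lo[1]), np.floor(hi[1]) + 1)
        n = np.arange(np.ceil(lo[2]), np.floor(hi[2]) + 1)
        return [d, g.astype(float), n.astype(float)]
    return [np.linspace(lo[i], hi[i], 21) for i in range(lo.size)]


def _default_heuristics(grids: Sequence[np.ndarray],
                        lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray]:
    """Prior attractiveness: prefer low dose (1/d), large gaps (g), few
    treatments (1/N); uniform for generic problems."""
    if _is_regimen_box(lo, hi):
        d, g, n = grids
        return [1.0 / np.maximum(d, 0.1), g.copy(), 1.0 / np.maximum(n, 1.0)]
    return [np.ones_like(grid) for grid in grids]


def aco_minimize(
    objective: Callable[[np.ndarray], float],
    bounds,
    config: Optional[ACOConfig] = None,
    init_point=None,
) -> OptimizerResult:
    """Ant colony optimization on a layered discretization of the box.

    ``init_point`` (if given) is evaluated once so all optimizers share the
    same starting incumbent; the colony itself starts from uniform pheromone.
    Costs are assumed positive (the deposit rule is Q / cost).
    """
    cfg = config or ACOConfig()
    if cfg.n_ants < 1 or cfg.max_iters < 0:
        raise ValueError("n_ants must be >= 1 and max_iters >= 0")
    lo, hi = _as_box(bounds)
    dim = lo.size
    grids = [np.asarray(g, float) for g in cfg.grids] if cfg.grids is not None \
        else _default_grids(lo, hi)
    if any(g.size == 0 for g in grids):
        raise ValueError("every layer must have at least one level")
    etas = [np.asarray(e, float) for e in cfg.heuristics] if cfg.heuristics is not None \
        else _default_heuristics(grids, lo, hi)
    rng = np.random.default_rng(cfg.seed)

    pheromone = [np.ones(g.size) for g in grids]
    best = None
    best_cost = np.inf
    n_evals = 0
    if init_point is not None:
        best = np.clip(np.asarray(init_point, float), lo, hi)
        best_cost = float(objective(best))
        n_evals = 1
    history = [best_cost]

    for _ in range(cfg.max_iters):
        deposits = [np.zeros(g.size) for g in grids]
        for _ant in range(cfg.n_ants):
            choice = np.empty(dim, dtype=np.int64)
            point = np.empty(dim)
            for layer in range(dim):
                probs = selection_probabilities(
                    pheromone[layer], etas[layer],
                    cfg.exponent_alpha, cfg.exponent_beta,
                )
                choice[layer] = rng.choice(probs.size, p=probs)
                point[layer] = grids[layer][choice[layer]]
            cost = float(objective(point))
            n_evals += 1
            if cost < best_cost:
                best, best_cost = point.copy(), cost
            for layer in range(dim):
                deposits[layer][choice[layer]] += cfg.deposit / max(cost, 1e-12)
        for layer in range(dim):
            pheromone[layer] = (1 - cfg.evaporation) * pheromone[layer] + deposits[layer]
        history.append(best_cost)

    if best is None:
        raise ValueError("zero iterations with no init point: nothing evaluated")
    return OptimizerResult(best, best_cost, np.array(history), n_evals, cfg.seed)


_METHODS = {"pso": (pso_minimize, PSOConfig),
            "sa": (sa_minimize, SAConfig),
            "aco": (aco_minimize, ACOConfig)}


def minimize(method: str, objective, bounds, init_point=None,
             seed: Optional[int] = None, max_iters: Optional[int] = None,
             config=None) -> OptimizerResult:
    """Dispatch to one of the three metaheuristics by name."""
    try:
        fn, cfg_cls = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    if config is None:
        config = cfg_cls(seed=seed)
        if max_iters is not None:
            config.max_iters = max_iters
    return fn(objective, bounds, config, init_point=init_point)
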