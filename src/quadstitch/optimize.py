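"""Genetic-algorithm minimization of the stitching cost, coarse to fine.

The search space is the 9-vector of (tx, ty, theta) for the three moving
quadrants (ur, ll, lr) relative to the fixed ul quadrant.  The coarsest
pyramid level is seeded by the geometric initialization and searched inside
wide bounds; each finer level re-centers a narrow local window on the
previous level's solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cost import CostConfig, CostEvaluator
from .preprocess import detect_corners_and_edges, initial_align
from .raster_core import Quadrant, QuadrantSet, TransformSet, build_pyramid


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    A generation holds ``population_size`` candidate solutions; optimization
    stops after ``stall_generations`` consecutive generations whose best cost
    improved by less than ``stall_tolerance`` (relative), or at
    ``max_generations``.
    """

    population_size: int = 20
    stall_generations: int = 25
    stall_tolerance: float = 1e-4
    max_generations: int = 500
    seed: int = 0
    tournament_k: int = 3
    mutation_sigma_frac: float = 0.1
    sigma_stall_decay: float = 0.85  # per stalled generation, floor 5%
    n_immigrants: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.stall_generations < 1:
            raise ValueError("stall_generations must be >= 1")


@dataclass
class StitchResult:
    """Final transforms plus the per-level optimization trace."""

    transforms: TransformSet
    final_cost: float
    cost_trace: list   # list (per level) of per-generation best costs
    levels_used: list  # pyramid factors, coarsest first

    def to_json(self) -> str:
        payload = {
            "transforms": json.loads(self.transforms.to_json()),
            "final_cost": self.final_cost,
            "cost_trace": self.cost_trace,
            "levels_used": self.levels_used,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def ga_minimize(cost_fn, bounds, cfg: GAConfig = None, x0=None, rng=None):
    """Elitist real-coded GA on a box.

    Tournament selection (k=3), per-gene uniform blend crossover, Gaussian
    mutation with sigma = ``mutation_sigma_frac`` of each bound's half-width,
    offspring clipped to bounds.  Returns ``(best_x, best_cost, trace)`` with
    ``trace`` the best cost per generation (non-increasing by elitism).
    """
    cfg = cfg or GAConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or \
            not np.all(np.isfinite(bounds)) or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be a finite (dim, 2) box with lo <= hi")
    dim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    half_width = np.maximum(0.5 * (hi - lo), 1e-12)
    sigma = cfg.mutation_sigma_frac * half_width
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    pop = rng.uniform(lo, hi, size=(cfg.population_size, dim))
    if x0 is not None:
        pop[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    costs = np.array([cost_fn(ind) for ind in pop])
    best_i = int(np.argmin(costs))
    best_x, best_c = pop[best_i].copy(), float(costs[best_i])
    trace = [best_c]
    stall = 0
    for _ in range(cfg.max_generations):
        new_pop = np.empty_like(pop)
        new_pop[0] = best_x  # elitism
        n_children = cfg.population_size - cfg.n_immigrants
        for j in range(1, cfg.population_size):
            if j >= n_children:
                # random immigrants keep the population from collapsing
                new_pop[j] = rng.uniform(lo, hi)
                continue
            pa = _tournament(costs, cfg.tournament_k, rng)
            pb = _tournament(costs, cfg.tournament_k, rng)
            u = rng.uniform(size=dim)
            child = u * pop[pa] + (1.0 - u) * pop[pb]
            # mutation anneals while the best is stalled, so the population
            # can refine locally once the basin is found
            scale = max(0.05, cfg.sigma_stall_decay ** stall)
            child += rng.normal(0.0, scale * sigma)
            new_pop[j] = np.clip(child, lo, hi)
        pop = new_pop
        costs = np.array([cost_fn(ind) for ind in pop])
        costs[0] = best_c
        gen_best = int(np.argmin(costs))
        prev = best_c
        if costs[gen_best] < best_c:
            best_x, best_c = pop[gen_best].copy(), float(costs[gen_best])
        trace.append(best_c)
        rel = (prev - best_c) / max(abs(prev), 1e-12)
        stall = 0 if rel > cfg.stall_tolerance else stall + 1
        if stall >= cfg.stall_generations:
            break
    return best_x, best_c, trace


def _tournament(costs: np.ndarray, k: int, rng) -> int:
    idx = rng.integers(0, len(costs), size=k)
    return int(idx[np.argmin(costs[idx])])


def _level_quadrants(pyramids: dict, level: int) -> dict:
    out = {}
    for lbl, pyr in pyramids.items():
        img, msk, _ = pyr.levels[level]
        q = Quadrant(lbl, img, msk)
        q.edges = detect_corners_and_edges(q)
        out[lbl] = q
    return out


def _vector_from_transforms(ts: TransformSet) -> np.ndarray:
    vec = []
    for lbl in ("ur", "ll", "lr"):
        t = ts[lbl]
        vec += [t.tx, t.ty, t.theta]
    return np.asarray(vec, dtype=float)


def hierarchical_stitch(qs: QuadrantSet, cost_cfg: CostConfig = None,
                        ga_cfg: GAConfig = None, factors=(8, 2, 1),
                        level0_translation_frac: float = 0.25,
                        level0_rotation_deg: float = 20.0,
                        window_translation_scale: float = 2.0,
                        window_rotation_deg: float = 3.0,
                        finest_restarts: int = 1) -> StitchResult:
    """Stitch four preprocessed quadrants by coarse-to-fine GA optimization.

    The coarsest level is seeded by :func:`initial_align` with translation
    bounds of ``level0_translation_frac`` of the image size and rotation
    bounds of ``level0_rotation_deg``; each finer level searches a local
    window of ``window_translation_scale * factor_ratio`` base px and
    ``window_rotation_deg`` degrees around the upscaled previous solution.
    """
    cost_cfg = cost_cfg or CostConfig()
    ga_cfg = ga_cfg or GAConfig()
    factors = [int(f) for f in factors]
    pyramids = {lbl: build_pyramid(q, factors) for lbl, q in qs.items()}

    traces = []
    x = None
    base_dim = max(qs["ul"].image.height, qs["ul"].image.width)
    for level, factor in enumerate(factors):
        level_qs = _level_quadrants(pyramids, level)
        ev = CostEvaluator(level_qs, factor, cost_cfg)
        if level == 0:
            init_ts = initial_align(QuadrantSet(level_qs), factor)
            x = _vector_from_transforms(init_ts)
            t_half = level0_translation_frac * base_dim
            r_half = level0_rotation_deg
        else:
            # local window around the previous solution; at least four pixels
            # of the coarser level (where that solution was estimated), since
            # its residual error is of that order
            ratio = factors[level - 1] / factor
            t_half = max(window_translation_scale * ratio * factor,
                         4.0 * factors[level - 1])
            r_half = window_rotation_deg
        half = np.tile([t_half, t_half, r_half], 3)
        bounds = np.column_stack([x - half, x + half])
        # the fine-resolution cost discriminates reliably between nearby
        # basins, so independent GA restarts are ranked by it; coarser costs
        # are only trusted for one seeded run
        n_runs = finest_restarts if level == len(factors) - 1 else 1
        best = None
        for run in range(n_runs):
            rng = np.random.default_rng(ga_cfg.seed + level + 1009 * run)
            xr, cr, trace = ga_minimize(ev.cost, bounds, ga_cfg, x0=x, rng=rng)
            if best is None or cr < best[1]:
                best = (xr, cr, trace)
        x, best_c, trace = best
        if not np.isfinite(best_c):
            raise RuntimeError(f"non-finite cost at level {level}: {x.tolist()}")
        traces.append(trace)

    # transforms carry base-resolution centers from the finest level
    transforms = ev.transforms_from_vector(x)
    ts = TransformSet(transforms, "ul")
    return StitchResult(ts, float(best_c), traces, factors)
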