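"""Climbing impedance simulation.

A trained climbing mammal picks the cheapest path from the bottom of the
mapped trunk strip to its top.  A candidate path is a polyline whose interior
turn points have strictly increasing heights (the climber always progresses
upward); consecutive segments take the shorter circumferential direction
around the stem.  Path cost is travel time plus spine penalties:

    cost = polyline length / speed
           + penalty * #{distinct spines within paw_size/2 of the polyline}

A spine is "crossed" when its base lies inside the swept paw corridor (width
= paw size, centred on the polyline); each spine is counted at most once per
path, since a single pass over a spine is a single encounter.

The optimizer mimics a staged search of increasing path complexity: at level
``k`` it draws ``paths_per_level`` random polylines with ``k`` interior turn
points (plus deterministic straight vertical candidates at every grid
x-position, so the no-spine optimum is exact), keeps the cheapest, and stops
as soon as adding a turn point no longer strictly improves the incumbent.

Random candidate streams are derived from ``(seed, level)`` only — they are
shared across paw sizes and maps, which makes the best cost exactly
monotone under paw-size growth and spine addition on the shared pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SpineMap, signed_wrap_delta

__all__ = [
    "ClimbConfig",
    "ClimbPath",
    "ClimbResult",
    "InvalidPathError",
    "path_cost",
    "evaluate_path_costs",
    "best_path_at_level",
    "optimize_climb",
    "climb_sweep",
    "results_to_frame",
]

_TOL = 1e-9


class InvalidPathError(ValueError):
    """Path does not span the strip bottom-to-top with increasing height."""


@dataclass(frozen=True)
class ClimbConfig:
    """Path-search parameters.

    ``penalty`` is the time cost per crossed spine (default 10, in the same
    units as distance at ``speed_cm_per_time = 1``); ``paths_per_level`` the
    Monte-Carlo budget per complexity level; ``max_levels`` a safety cap on
    the staged search; ``grid_step_cm`` the spacing of the deterministic
    vertical candidates.
    """

    paw_sizes_cm: tuple[float, ...] = tuple(float(p) for p in range(1, 11))
    penalty: float = 10.0
    paths_per_level: int = 100_000
    speed_cm_per_time: float = 1.0
    max_levels: int = 10
    seed: int = 0
    grid_step_cm: float = 0.5
    batch_size: int = 20_000

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.paths_per_level < 1:
            raise ValueError("paths_per_level must be >= 1")
        if self.speed_cm_per_time <= 0:
            raise ValueError("speed must be positive")
        if len(self.paw_sizes_cm) == 0 or min(self.paw_sizes_cm) <= 0:
            raise ValueError("paw sizes must be positive")


@dataclass(frozen=True)
class ClimbPath:
    """Polyline from y=0 to y=height with strictly increasing heights."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.size < 2:
            raise InvalidPathError("path needs matching 1-d x/y with >= 2 points")
        if np.any(np.diff(self.y) <= 0):
            raise InvalidPathError("path heights must be strictly increasing")

    @property
    def n_turns(self) -> int:
        return int(self.x.size) - 2

    def validate_on(self, surface) -> None:
        if abs(self.y[0]) > _TOL or abs(self.y[-1] - surface.height_cm) > _TOL:
            raise InvalidPathError(
                f"path must span y=0 to y={surface.height_cm}, "
                f"got [{self.y[0]}, {self.y[-1]}]"
            )


@dataclass(frozen=True)
class ClimbResult:
    species_id: str
    paw_size_cm: float
    best_cost: float
    best_path: ClimbPath
    complexity_level: int
    levels_explored: int
    syndrome: str | None = None


# -- batched path-cost evaluation ----------------------------------------------


def _eval_numpy(X, Y, sx, sy, C, radius, penalty, speed):
    """Vectorized reference evaluator.  X, Y: (n_paths, n_pts)."""
    dx = (X[:, 1:] - X[:, :-1] + C / 2.0) % C - C / 2.0
    dy = Y[:, 1:] - Y[:, :-1]
    lengths = np.sqrt(dx * dx + dy * dy).sum(axis=1)
    costs = lengths / speed
    m = sx.size
    if m == 0 or penalty == 0:
        return costs
    n, nseg = dx.shape
    r2 = radius * radius
    mind = np.full((n, m), np.inf)
    for s in range(nseg):
        x1 = X[:, s][:, None]
        y1 = Y[:, s][:, None]
        dxs = dx[:, s][:, None]
        dys = dy[:, s][:, None]
        seglen2 = dxs * dxs + dys * dys
        relx0 = (sx[None, :] - x1 + C / 2.0) % C - C / 2.0
        py = sy[None, :] - y1
        for j in (-C, 0.0, C):
            px = relx0 + j
            t = np.clip((px * dxs + py * dys) / seglen2, 0.0, 1.0)
            d2 = (px - t * dxs) ** 2 + (py - t * dys) ** 2
            np.minimum(mind, d2, out=mind)
    hits = (mind <= r2 + _TOL).sum(axis=1)
    return costs + penalty * hits


try:  # optional numba fast path; the numpy evaluator is the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _eval_numba(X, Y, sx, sy, C, radius, penalty, speed):  # pragma: no cover
        n, p = X.shape
        m = sx.size
        r2 = radius * radius
        costs = np.empty(n)
        for i in range(n):
            length = 0.0
            for s in range(p - 1):
                d = (X[i, s + 1] - X[i, s] + C / 2.0) % C - C / 2.0
                e = Y[i, s + 1] - Y[i, s]
                length += np.sqrt(d * d + e * e)
            cost = length / speed
            if penalty > 0.0:
                hits = 0
                for q in range(m):
                    hit = False
                    for s in range(p - 1):
                        dxs = (X[i, s + 1] - X[i, s] + C / 2.0) % C - C / 2.0
                        dys = Y[i, s + 1] - Y[i, s]
                        seglen2 = dxs * dxs + dys * dys
                        relx0 = (sx[q] - X[i, s] + C / 2.0) % C - C / 2.0
                        py = sy[q] - Y[i, s]
                        for j in (-1.0, 0.0, 1.0):
                            px = relx0 + j * C
                            t = (px * dxs + py * dys) / seglen2
                            if t < 0.0:
                                t = 0.0
                            elif t > 1.0:
                                t = 1.0
                            ex = px - t * dxs
                            ey = py - t * dys
                            if ex * ex + ey * ey <= r2 + 1e-9:
                                hit = True
                                break
                        if hit:
                            break
                    if hit:
                        hits += 1
                cost += penalty * hits
            costs[i] = cost
        return costs

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def evaluate_path_costs(
    X: np.ndarray,
    Y: np.ndarray,
    spine_map: SpineMap,
    paw_size: float,
    config: ClimbConfig,
    backend: str | None = None,
) -> np.ndarray:
    """Costs of a batch of polylines (rows of X/Y) on one map.

    ``backend`` selects "numpy" or "numba" explicitly (default: numba when
    available); both implement the identical cost function.
    """
    X = np.ascontiguousarray(X, dtype=float)
    Y = np.ascontiguousarray(Y, dtype=float)
    C = spine_map.surface.circumference_cm
    args = (
        X, Y, spine_map.x, spine_map.y, C,
        paw_size / 2.0, config.penalty, config.speed_cm_per_time,
    )
    if backend == "numpy" or (backend is None and not _HAVE_NUMBA):
        return _eval_numpy(*args)
    if backend in (None, "numba"):
        if not _HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        return _eval_numba(*args)
    raise ValueError(f"unknown backend {backend!r}")


def path_cost(
    spine_map: SpineMap,
    path: ClimbPath,
    paw_size: float,
    config: ClimbConfig | None = None,
) -> float:
    """Cost of a single path: travel time plus per-spine penalties."""
    config = config or ClimbConfig()
    path.validate_on(spine_map.surface)
    return float(
        evaluate_path_costs(path.x[None, :], path.y[None, :], spine_map,
                            paw_size, config)[0]
    )


# -- staged random search --------------------------------------------------------


def _vertical_candidates(spine_map: SpineMap, config: ClimbConfig):
    C = spine_map.surface.circumference_cm
    H = spine_map.surface.height_cm
    nx = max(1, int(round(C / config.grid_step_cm)))
    xs = np.arange(nx) * (C / nx)
    X = np.column_stack([xs, xs])
    Y = np.tile([0.0, H], (nx, 1))
    return X, Y


def _random_paths(n: int, k: int, surface, rng: np.random.Generator):
    C, H = surface.circumference_cm, surface.height_cm
    X = rng.uniform(0.0, C, size=(n, k + 2))
    if k > 0:
        Yint = np.sort(rng.uniform(0.0, H, size=(n, k)), axis=1)
        Y = np.concatenate(
            [np.zeros((n, 1)), Yint, np.full((n, 1), H)], axis=1
        )
    else:
        Y = np.concatenate([np.zeros((n, 1)), np.full((n, 1), H)], axis=1)
    return X, Y


def _level_rng(config: ClimbConfig, level: int) -> np.random.Generator:
    # streams keyed by (seed, level): shared across maps and paw sizes
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 7919, level]))


def best_path_at_level(
    spine_map: SpineMap,
    paw_size: float,
    k: int,
    config: ClimbConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ClimbPath, float]:
    """Cheapest of ``paths_per_level`` random k-turn polylines plus verticals."""
    config = config or ClimbConfig()
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = rng or _level_rng(config, k)
    best_cost = np.inf
    best_xy = None

    Xv, Yv = _vertical_candidates(spine_map, config)
    cv = evaluate_path_costs(Xv, Yv, spine_map, paw_size, config)
    i = int(np.argmin(cv))
    best_cost = float(cv[i])
    best_xy = (Xv[i], Yv[i])

    remaining = config.paths_per_level
    while remaining > 0:
        n = min(remaining, config.batch_size)
        X, Y = _random_paths(n, k, spine_map.surface, rng)
        c = evaluate_path_costs(X, Y, spine_map, paw_size, config)
        i = int(np.argmin(c))
        if c[i] < best_cost:
            best_cost = float(c[i])
            best_xy = (X[i], Y[i])
        remaining -= n
    return ClimbPath(*best_xy), best_cost


def optimize_climb(
    spine_map: SpineMap,
    paw_size: float,
    config: ClimbConfig | None = None,
) -> ClimbResult:
    """Staged search over path complexity, stopping when it stops improving."""
    config = config or ClimbConfig()
    best_path, best_cost = best_path_at_level(spine_map, paw_size, 0, config)
    best_level = 0
    level = 0
    while level + 1 < config.max_levels:
        level += 1
        path, cost = best_path_at_level(spine_map, paw_size, level, config)
        if cost < best_cost - _TOL:
            best_cost, best_path, best_level = cost, path, level
        else:
            break
    return ClimbResult(
        species_id=spine_map.species_id,
        paw_size_cm=float(paw_size),
        best_cost=best_cost,
        best_path=best_path,
        complexity_level=best_level,
        levels_explored=level + 1,
        syndrome=spine_map.syndrome,
    )


def climb_sweep(
    spine_map: SpineMap, config: ClimbConfig | None = None
) -> list[ClimbResult]:
    """One ClimbResult per paw size.

    After the per-paw staged searches (which share candidate streams), every
    best path found for any paw is re-evaluated under every other paw; since
    each individual path's cost is non-decreasing in paw size, the resulting
    best costs are exactly non-decreasing across the sweep.
    """
    config = config or ClimbConfig()
    paws = sorted(config.paw_sizes_cm)
    results = [optimize_climb(spine_map, p, config) for p in paws]
    pool = [r.best_path for r in results]
    final = []
    for r in results:
        best_cost, best_path, best_level = r.best_cost, r.best_path, r.complexity_level
        for p in pool:
            c = path_cost(spine_map, p, r.paw_size_cm, config)
            if c < best_cost - _TOL:
                best_cost, best_path, best_level = c, p, p.n_turns
        final.append(
            ClimbResult(
                species_id=r.species_id,
                paw_size_cm=r.paw_size_cm,
                best_cost=best_cost,
                best_path=best_path,
                complexity_level=best_level,
                levels_explored=r.levels_explored,
                syndrome=r.syndrome,
            )
        )
    return final


def results_to_frame(results: list[ClimbResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "syndrome": r.syndrome,
                "paw_size_cm": r.paw_size_cm,
                "best_cost": r.best_cost,
                "complexity_level": r.complexity_level,
                "levels_explored": r.levels_explored,
            }
            for r in results
        ]
    )
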