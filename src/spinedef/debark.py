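"""Bark-removal accessibility simulation.

A bark-feeding mammal is modelled by a square bite window (side = bite size,
1..10 cm).  At a candidate position the animal can insert its mouth iff no
spine base lies inside the window rectangle dilated by a safety margin
(default 1 cm) on all four sides, with circumferential distances computed
modulo the circumference.  Two curvature effects apply on thin stems: the
window width is capped at a fraction of the circumference (default one
quarter), and the wrap-aware distance means spines on the far side of the
stem never block a bite.

Two outputs per (map, bite size):

``accessible_fraction``
    The surface is rasterized at ``grid_step_cm``; a raster cell is removable
    iff at least one accessible window position covers it.  Reported as
    removable area / total area.
``ring_risk``
    For each candidate horizontal band (band height = bite size, bottoms on
    the raster), the band is ring-debarkable iff the accessible windows
    anchored in it cover the full circumference.  Reported as the fraction of
    ring-debarkable bands — the risk that the animal can girdle the stem.

Windows are clipped vertically (no wrap in y); candidate positions exclude
windows that would exceed the strip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, SpineMap, wrap_delta

__all__ = [
    "DebarkConfig",
    "DebarkResult",
    "InvalidWindowError",
    "window_is_accessible",
    "accessible_fraction",
    "ring_barking_risk",
    "debark_sweep",
    "results_to_frame",
]

_TOL = 1e-9


class InvalidWindowError(ValueError):
    """Bite window does not fit on the surface."""


@dataclass(frozen=True)
class DebarkConfig:
    """Bite-window sweep parameters.

    ``margin_cm`` realizes "any spine in or within a 1-cm range of the bite
    area blocks the bite" as rectangle dilation.  ``max_width_fraction`` caps
    the window width (only the width: curvature constrains circumferential
    mouth insertion, not vertical extent).  ``grid_step_cm`` is both the
    candidate-position step and the raster resolution of the outputs.
    """

    bite_sizes_cm: tuple[float, ...] = tuple(float(b) for b in range(1, 11))
    margin_cm: float = 1.0
    max_width_fraction: float = 0.25
    grid_step_cm: float = 0.5

    def __post_init__(self) -> None:
        if len(self.bite_sizes_cm) == 0 or min(self.bite_sizes_cm) <= 0:
            raise ValueError("bite sizes must be positive")
        if self.margin_cm < 0:
            raise ValueError("margin_cm must be >= 0")
        if not 0 < self.max_width_fraction <= 1:
            raise ValueError("max_width_fraction must be in (0, 1]")
        if self.grid_step_cm <= 0 or self.grid_step_cm > min(self.bite_sizes_cm) + _TOL:
            raise ValueError("grid_step_cm must be positive and <= min bite size")

    def window_width(self, bite_size: float, circumference: float) -> float:
        return min(bite_size, self.max_width_fraction * circumference)


@dataclass(frozen=True)
class DebarkResult:
    """Outputs of one (map, bite size) evaluation.

    ``n_cells`` is the raster-cell total behind ``accessible_fraction`` and
    ``n_bands`` the candidate-band total behind ``ring_risk``; downstream
    comparison models use them as binomial denominators.
    """

    species_id: str
    bite_size_cm: float
    accessible_fraction: float
    ring_risk: float
    n_cells: int
    n_bands: int
    syndrome: str | None = None
    grid_step_cm: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.accessible_fraction <= 1.0):
            raise ValueError("accessible_fraction must lie in [0, 1]")
        if not (0.0 <= self.ring_risk <= 1.0):
            raise ValueError("ring_risk must lie in [0, 1]")


def window_is_accessible(
    spine_map: SpineMap,
    center: tuple[float, float],
    bite_size: float,
    config: DebarkConfig | None = None,
) -> bool:
    """Can a mouth of the given size be inserted at ``center``?

    ``center`` is the window centre.  True iff no spine base lies inside the
    window rectangle dilated by ``margin_cm`` on all four sides (x wrap-aware).
    """
    config = config or DebarkConfig()
    C = spine_map.surface.circumference_cm
    H = spine_map.surface.height_cm
    w = config.window_width(bite_size, C)
    h = bite_size
    cx, cy = center
    if h > H + _TOL or cy - h / 2 < -_TOL or cy + h / 2 > H + _TOL:
        raise InvalidWindowError(
            f"bite window (height {h}) at y={cy} does not fit in [0, {H}]"
        )
    if spine_map.n_spines == 0:
        return True
    dx = wrap_delta(spine_map.x, cx, C)
    dy = np.abs(spine_map.y - cy)
    blocked = (dx <= w / 2 + config.margin_cm + _TOL) & (
        dy <= h / 2 + config.margin_cm + _TOL
    )
    return not bool(np.any(blocked))


def _grids(spine_map: SpineMap, bite_size: float, config: DebarkConfig):
    """Raster geometry: cell grid plus valid window-anchor positions."""
    C = spine_map.surface.circumference_cm
    H = spine_map.surface.height_cm
    w = config.window_width(bite_size, C)
    h = bite_size
    if h > H + _TOL:
        raise InvalidWindowError(f"bite window height {h} exceeds surface height {H}")
    g = config.grid_step_cm
    nx = max(1, int(round(C / g)))
    gx = C / nx
    ny = max(1, int(round(H / g)))
    gy = H / ny
    # window bottoms at iy*gy with iy*gy + h <= H
    n_wy = int(np.floor((H - h) / gy + _TOL)) + 1
    return C, H, w, h, nx, gx, ny, gy, n_wy


def _accessible_anchor_grid(spine_map: SpineMap, bite_size: float, config: DebarkConfig):
    """Boolean (n_wy, nx) grid: window with bottom-left (ix*gx, iy*gy) accessible?"""
    C, H, w, h, nx, gx, ny, gy, n_wy = _grids(spine_map, bite_size, config)
    m = config.margin_cm
    if spine_map.n_spines == 0:
        A = np.ones((n_wy, nx), dtype=bool)
    else:
        grid_x = np.arange(nx) * gx
        # x-block: spine within w/2+m of window centre (wrap-aware)
        dx = wrap_delta(spine_map.x[:, None], grid_x[None, :] + w / 2.0, C)
        xb = dx <= w / 2.0 + m + _TOL
        grid_wy = np.arange(n_wy) * gy
        yb = (spine_map.y[:, None] >= grid_wy[None, :] - m - _TOL) & (
            spine_map.y[:, None] <= grid_wy[None, :] + h + m + _TOL
        )
        blocked = yb.T.astype(np.float32) @ xb.astype(np.float32) > 0.5
        A = ~blocked
    return A, (C, H, w, h, nx, gx, ny, gy, n_wy)


def _band_coverage(A: np.ndarray, w: float, gx: float, nx: int) -> np.ndarray:
    """(n_wy, nx) bool: cell column covered by an accessible window in its band."""
    n_shift = int(np.floor(w / gx - 0.5 + 1e-6)) + 1  # cells with centre inside window
    B = np.zeros_like(A)
    for s in range(n_shift):
        B |= np.roll(A, s, axis=1)
    return B


def _evaluate(spine_map: SpineMap, bite_size: float, config: DebarkConfig):
    A, (C, H, w, h, nx, gx, ny, gy, n_wy) = _accessible_anchor_grid(
        spine_map, bite_size, config
    )
    B = _band_coverage(A, w, gx, nx)
    # vertical accumulation: cell row cy covered by window bottom iy iff the
    # cell centre (cy+0.5)*gy lies inside [iy*gy, iy*gy + h]
    n_sy = int(np.floor(h / gy - 0.5 + 1e-6)) + 1
    covered = np.zeros((ny, nx), dtype=bool)
    for s in range(n_sy):
        top = min(s + n_wy, ny)
        covered[s:top] |= B[: top - s]
    frac = float(covered.mean())
    ring = float(B.all(axis=1).mean())
    return frac, ring, ny * nx, n_wy


def accessible_fraction(
    spine_map: SpineMap, bite_size: float, config: DebarkConfig | None = None
) -> float:
    """Proportion of the bark surface removable by a mouth of ``bite_size``."""
    config = config or DebarkConfig()
    return _evaluate(spine_map, bite_size, config)[0]


def ring_barking_risk(
    spine_map: SpineMap, bite_size: float, config: DebarkConfig | None = None
) -> float:
    """Proportion of horizontal bands debarkable continuously around the stem."""
    config = config or DebarkConfig()
    return _evaluate(spine_map, bite_size, config)[1]


def debark_sweep(
    spine_map: SpineMap, config: DebarkConfig | None = None
) -> list[DebarkResult]:
    """Evaluate all configured bite sizes on one map, ordered by bite size."""
    config = config or DebarkConfig()
    out = []
    for bite in sorted(config.bite_sizes_cm):
        frac, ring, n_cells, n_bands = _evaluate(spine_map, bite, config)
        out.append(
            DebarkResult(
                species_id=spine_map.species_id,
                bite_size_cm=float(bite),
                accessible_fraction=frac,
                ring_risk=ring,
                n_cells=n_cells,
                n_bands=n_bands,
                syndrome=spine_map.syndrome,
                grid_step_cm=config.grid_step_cm,
            )
        )
    return out


def results_to_frame(results: list[DebarkResult]) -> pd.DataFrame:
    """Stack DebarkResults into a tidy DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
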