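"""Spine maps on a cylindrical trunk surface.

A spine map records the base position ``(x_cm, y_cm)`` and length of every
spine on an unrolled strip of trunk bark.  The strip is a plane projection of
a cylinder: the left and right edges are adjacent, so every circumferential
(x) computation is performed modulo the circumference ("torus wrap").  The
vertical (y) axis is not periodic; ``y = 0`` is the bottom of the strip and
climbing proceeds towards ``y = height_cm``.

Coordinates are continuous centimetres.  x is stored normalized to
``[0, circumference)``.  Spines are treated as point obstacles located at
their base; the recorded length is carried through I/O but does not enter the
default simulations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "MapFormatError",
    "TrunkSurface",
    "Spine",
    "SpineMap",
    "wrap_delta",
    "signed_wrap_delta",
    "map_density",
    "read_map",
    "write_map",
]

#: coordinate tolerance used when validating / normalizing map files
COORD_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid surface geometry or coordinates off the surface."""


class MapFormatError(ValueError):
    """Malformed map file (missing headers, bad columns, out-of-range rows)."""


@dataclass(frozen=True)
class TrunkSurface:
    """Cylindrical trunk patch, unrolled to a ``circumference x height`` strip.

    Parameters
    ----------
    circumference_cm
        Stem circumference; the period of the x axis.  Required per map
        because the bite-window width cap is a fraction of it.
    height_cm
        Vertical extent of the mapped strip (default 30 cm).
    """

    circumference_cm: float
    height_cm: float = 30.0

    def __post_init__(self) -> None:
        if not (self.circumference_cm > 0):
            raise GeometryError(
                f"circumference_cm must be positive, got {self.circumference_cm}"
            )
        if not (self.height_cm > 0):
            raise GeometryError(f"height_cm must be positive, got {self.height_cm}")

    @property
    def area_cm2(self) -> float:
        return self.circumference_cm * self.height_cm

    @property
    def area_m2(self) -> float:
        return self.area_cm2 / 1e4


@dataclass(frozen=True)
class Spine:
    """A single spine: base position on the surface plus its length."""

    x_cm: float
    y_cm: float
    length_cm: float = 0.0


def wrap_delta(x1, x2, circumference: float):
    """Shortest circumferential distance between x-coordinates on the cylinder.

    Returns ``min(|x1 - x2| mod C, C - |x1 - x2| mod C)``, which lies in
    ``[0, C/2]``.  Accepts scalars or arrays (broadcasting).
    """
    if not circumference > 0:
        raise GeometryError(f"circumference must be positive, got {circumference}")
    d = np.abs(np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)) % circumference
    out = np.minimum(d, circumference - d)
    if np.isscalar(x1) and np.isscalar(x2):
        return float(out)
    return out


def signed_wrap_delta(x_from, x_to, circumference: float):
    """Signed circumferential step ``x_from -> x_to`` taking the shorter way.

    Result lies in ``[-C/2, C/2)``; positive means increasing x.
    """
    if not circumference > 0:
        raise GeometryError(f"circumference must be positive, got {circumference}")
    d = (np.asarray(x_to, dtype=float) - np.asarray(x_from, dtype=float)
         + circumference / 2.0) % circumference - circumference / 2.0
    if np.isscalar(x_from) and np.isscalar(x_to):
        return float(d)
    return d


@dataclass
class SpineMap:
    """Spine point pattern on a :class:`TrunkSurface`.

    Spine coordinates are held as parallel numpy arrays (``x``, ``y``,
    ``length``) for fast geometric queries; :attr:`spines` offers the
    record view.
    """

    surface: TrunkSurface
    x: np.ndarray
    y: np.ndarray
    length: np.ndarray
    species_id: str = "unknown"
    syndrome: str | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float)).copy()
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float)).copy()
        self.length = np.atleast_1d(np.asarray(self.length, dtype=float)).copy()
        if self.x.size == 0:
            self.x = np.empty(0)
            self.y = np.empty(0)
            self.length = np.empty(0)
        if not (self.x.shape == self.y.shape == self.length.shape):
            raise GeometryError("x, y and length arrays must have equal shapes")
        C = self.surface.circumference_cm
        H = self.surface.height_cm
        self.x = self.x % C
        bad_y = (self.y < -COORD_TOL) | (self.y > H + COORD_TOL)
        if np.any(bad_y):
            rows = np.flatnonzero(bad_y).tolist()
            raise GeometryError(
                f"y coordinates outside [0, {H}] at rows {rows}"
            )
        self.y = np.clip(self.y, 0.0, H)
        if np.any(self.length < 0):
            rows = np.flatnonzero(self.length < 0).tolist()
            raise GeometryError(f"negative spine lengths at rows {rows}")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_spines(
        cls,
        surface: TrunkSurface,
        spines: Iterable[Spine] | Sequence[tuple],
        species_id: str = "unknown",
        syndrome: str | None = None,
    ) -> "SpineMap":
        rows = [
            (s.x_cm, s.y_cm, s.length_cm) if isinstance(s, Spine) else tuple(s)
            for s in spines
        ]
        if rows:
            arr = np.asarray(rows, dtype=float)
            if arr.shape[1] == 2:  # lengths optional
                arr = np.column_stack([arr, np.zeros(len(arr))])
            x, y, ln = arr.T
        else:
            x = y = ln = np.empty(0)
        return cls(surface, x, y, ln, species_id=species_id, syndrome=syndrome)

    @classmethod
    def empty(
        cls, surface: TrunkSurface, species_id: str = "unknown",
        syndrome: str | None = None,
    ) -> "SpineMap":
        return cls(surface, np.empty(0), np.empty(0), np.empty(0),
                   species_id=species_id, syndrome=syndrome)

    # -- views ---------------------------------------------------------------

    @property
    def n_spines(self) -> int:
        return int(self.x.size)

    @property
    def spines(self) -> list[Spine]:
        return [Spine(float(a), float(b), float(c))
                for a, b, c in zip(self.x, self.y, self.length)]

    # -- derived maps ----------------------------------------------------------

    def translated(self, dx_cm: float) -> "SpineMap":
        """Map with every spine shifted circumferentially by ``dx_cm``."""
        return replace(self, x=(self.x + dx_cm) % self.surface.circumference_cm)

    def with_spines(self, extra: Iterable[Spine]) -> "SpineMap":
        """Map with additional spines appended (used for nesting tests)."""
        extra = list(extra)
        return replace(
            self,
            x=np.concatenate([self.x, [s.x_cm for s in extra]]),
            y=np.concatenate([self.y, [s.y_cm for s in extra]]),
            length=np.concatenate([self.length, [s.length_cm for s in extra]]),
        )


def map_density(spine_map: SpineMap) -> float:
    """Spine density in spines per square metre of bark surface."""
    return spine_map.n_spines / spine_map.surface.area_m2


# -- map CSV dialect ----------------------------------------------------------
#
#   # species_id=<str>
#   # circumference_cm=<float>
#   # height_cm=<float>
#   [# syndrome=<str>]          (optional)
#   x_cm,y_cm,length_cm
#   ...
#
# UTF-8, '.' decimal separator, one file per species trunk.

_REQUIRED_HEADERS = ("species_id", "circumference_cm", "height_cm")
_IO_DECIMALS = 4


def write_map(spine_map: SpineMap, path: str | Path) -> None:
    """Write a map to the spinedef CSV dialect (4-decimal coordinates)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# species_id={spine_map.species_id}\n")
        fh.write(f"# circumference_cm={spine_map.surface.circumference_cm!r}\n")
        fh.write(f"# height_cm={spine_map.surface.height_cm!r}\n")
        if spine_map.syndrome is not None:
            fh.write(f"# syndrome={spine_map.syndrome}\n")
        fh.write("x_cm,y_cm,length_cm\n")
        for a, b, c in zip(spine_map.x, spine_map.y, spine_map.length):
            fh.write(f"{a:.{_IO_DECIMALS}f},{b:.{_IO_DECIMALS}f},{c:.{_IO_DECIMALS}f}\n")


def read_map(path: str | Path) -> SpineMap:
    """Read a map from the spinedef CSV dialect, validating coordinates.

    x-coordinates equal to the circumference are wrap-normalized to 0;
    y-coordinates outside ``[0, height]`` raise :class:`MapFormatError`
    listing the offending data rows.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                kv = stripped.lstrip("#").strip()
                if "=" in kv:
                    key, val = kv.split("=", 1)
                    headers[key.strip()] = val.strip()
            elif stripped:
                body_lines.append(line)
    missing = [h for h in _REQUIRED_HEADERS if h not in headers]
    if missing:
        raise MapFormatError(f"missing header fields: {missing} in {path}")
    try:
        surface = TrunkSurface(
            circumference_cm=float(headers["circumference_cm"]),
            height_cm=float(headers["height_cm"]),
        )
    except ValueError as exc:
        raise MapFormatError(f"bad surface headers in {path}: {exc}") from exc

    df = pd.read_csv(io.StringIO("".join(body_lines)))
    expected = ["x_cm", "y_cm", "length_cm"]
    if list(df.columns) != expected:
        raise MapFormatError(
            f"expected columns {expected}, got {list(df.columns)} in {path}"
        )
    H = surface.height_cm
    bad = df.index[(df["y_cm"] < -COORD_TOL) | (df["y_cm"] > H + COORD_TOL)].tolist()
    if bad:
        raise MapFormatError(
            f"y_cm outside [0, {H}] at data rows {bad} in {path}"
        )
    return SpineMap(
        surface,
        df["x_cm"].to_numpy(),
        df["y_cm"].to_numpy(),
        df["length_cm"].to_numpy(),
        species_id=headers["species_id"],
        syndrome=headers.get("syndrome"),
    )
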