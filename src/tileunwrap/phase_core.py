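"""Core data model for two-dimensional phase maps.

A phase map is a rectangular raster of phase values in radians.  A *wrapped*
map is only known modulo 2π, with every value confined to the half-open
interval [−π, π); the corresponding *unwrapped* map differs from it by a
pixelwise field of signed integer multiples of 2π (the jump map)::

    ϕ_w(x, y) = ϕ_u(x, y) − 2π·n(x, y),   ϕ_w ∈ [−π, π),  n ∈ ℤ

Phase unwrapping is the recovery of ``n`` from ``ϕ_w``.  This module provides
the wrap operator, wrapped forward differences (which estimate the unwrapped
gradient wherever the Itoh condition |Δϕ_u| < π holds), tessellation of a map
into rectangular tiles, per-tile 2π offsets, jump-map extraction, and residue
(plaquette charge) detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi

#: Tolerance (radians) below which a residual is accepted as an exact
#: 2π-lattice relationship.  Far above float64 rounding, far below 2π.
JUMP_TOLERANCE = 1e-6

# Slack for the wrapped-range invariant check; wrap() is accurate to well
# below this for the phase magnitudes that occur in imaging data.
_RANGE_TOL = 1e-9


def _wrap(values: np.ndarray) -> np.ndarray:
    """Branch-free wrap to [−π, π) without input validation (hot path)."""
    return values - TWO_PI * np.floor((values + math.pi) / TWO_PI)


def wrap(values):
    """Wrap phase values into the half-open interval [−π, π).

    Implements ``W(x) = x − 2π·floor((x + π) / 2π)``, so the boundary maps as
    ``wrap(π) == −π``.  The operator is idempotent and 2π-periodic.

    Parameters
    ----------
    values : scalar or array-like
        Phase values in radians; must be finite.

    Returns
    -------
    Wrapped value(s), same shape as the input; a Python float for scalar
    input.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap: input contains non-finite values")
    out = _wrap(arr)
    return float(out) if out.ndim == 0 else out


@dataclass(eq=False)
class PhaseMap:
    """A 2D raster of phase values (radians) with a wrapped-state flag.

    Attributes
    ----------
    values
        ``(N_Y, N_X)`` float array; row-major, 0-based pixel indices.
    wrapped
        If True, every value must lie in [−π, π).
    """

    values: np.ndarray
    wrapped: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("PhaseMap requires a non-empty 2D raster")
        if not np.all(np.isfinite(v)):
            raise ValueError("PhaseMap values must be finite")
        if self.wrapped and (
            v.min() < -math.pi - _RANGE_TOL or v.max() >= math.pi + _RANGE_TOL
        ):
            raise ValueError("wrapped PhaseMap values must lie in [-pi, pi)")
        self.values = v

    @property
    def n_y(self) -> int:
        return self.values.shape[0]

    @property
    def n_x(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "PhaseMap":
        return PhaseMap(self.values.copy(), self.wrapped)


def _values_of(map_or_array) -> np.ndarray:
    if isinstance(map_or_array, PhaseMap):
        return map_or_array.values
    return np.asarray(map_or_array, dtype=float)


def wrapped_difference(phase_map, axis: str) -> np.ndarray:
    """Wrapped forward differences W(δϕ_w) along one axis.

    Under the Itoh condition these equal the forward differences of the
    unwrapped phase.  ``axis='x'`` differences along columns (output drops one
    column), ``axis='y'`` along rows (output drops one row).  Only positions
    that have a forward neighbor contribute; no padding is applied.
    """
    if isinstance(phase_map, PhaseMap) and not phase_map.wrapped:
        raise ValueError("wrapped_difference requires a wrapped phase map")
    v = _values_of(phase_map)
    if axis == "x":
        return _wrap(np.diff(v, axis=1))
    if axis == "y":
        return _wrap(np.diff(v, axis=0))
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


@dataclass(eq=False)
class Tile:
    """A rectangular view into a phase map.

    ``row_range``/``col_range`` are half-open pixel index intervals into the
    parent raster; ``grid_pos`` is the (w, h) = (column, row) position of the
    tile in its tessellation grid.  Tiles are mutable views: writing through
    :meth:`set_values` or :func:`add_tile_offset` mutates the parent map.

    Each tile tracks a cumulative integer 2π offset applied by merging, so
    that repeated offsets are exact (applying k and then −k restores the
    stored base values bit-for-bit).
    """

    parent_values: np.ndarray
    base_values: np.ndarray
    row_range: tuple[int, int]
    col_range: tuple[int, int]
    grid_pos: tuple[int, int]
    offset: int = 0

    def __post_init__(self):
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        n_y, n_x = self.parent_values.shape
        if not (0 <= r0 < r1 <= n_y and 0 <= c0 < c1 <= n_x):
            raise ValueError("tile ranges must be nonempty and within bounds")

    @property
    def values(self) -> np.ndarray:
        """Writable view of the tile's pixels in the parent raster."""
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        return self.parent_values[r0:r1, c0:c1]

    @property
    def _base(self) -> np.ndarray:
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        return self.base_values[r0:r1, c0:c1]

    @property
    def height(self) -> int:
        return self.row_range[1] - self.row_range[0]

    @property
    def width(self) -> int:
        return self.col_range[1] - self.col_range[0]

    def set_values(self, new_values: np.ndarray) -> None:
        """Overwrite the tile's pixels (e.g. with its unwrapped values)."""
        arr = np.asarray(new_values, dtype=float)
        if arr.shape != (self.height, self.width):
            raise ValueError("set_values: shape mismatch")
        self.values[...] = arr
        self._base[...] = arr
        self.offset = 0


@dataclass(eq=False)
class Tessellation:
    """Partition of a phase map into an ``NτW × NτH`` grid of tiles.

    ``tiles[h][w]`` is the tile in tile-column w, tile-row h.  Tiles are
    pairwise disjoint and cover the raster exactly.
    """

    parent: PhaseMap
    tiles: list
    n_tiles_w: int
    n_tiles_h: int

    @property
    def n_tiles(self) -> int:
        return self.n_tiles_w * self.n_tiles_h

    def tile(self, w: int, h: int) -> Tile:
        return self.tiles[h][w]

    def __iter__(self):
        for row in self.tiles:
            yield from row


def _axis_edges(n: int, count: int) -> np.ndarray:
    # base size floor(n/count); the first (n mod count) tiles get one extra
    base, rem = divmod(n, count)
    sizes = np.full(count, base, dtype=int)
    sizes[:rem] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def tessellate(phase_map: PhaseMap, n_tiles_w: int, n_tiles_h: int) -> Tessellation:
    """Tessellate a phase map into ``n_tiles_w × n_tiles_h`` rectangular tiles.

    When a raster dimension is divisible by the tile count all tiles along
    that axis share the same extent; otherwise the first ``N mod count``
    tiles get one extra pixel.
    """
    n_y, n_x = phase_map.shape
    if not (1 <= n_tiles_w <= n_x) or not (1 <= n_tiles_h <= n_y):
        raise ValueError(
            f"tile counts ({n_tiles_w}x{n_tiles_h}) must be between 1 and the "
            f"raster dimensions ({n_x}x{n_y})"
        )
    col_edges = _axis_edges(n_x, n_tiles_w)
    row_edges = _axis_edges(n_y, n_tiles_h)
    base = phase_map.values.copy()
    tiles = [
        [
            Tile(
                parent_values=phase_map.values,
                base_values=base,
                row_range=(int(row_edges[h]), int(row_edges[h + 1])),
                col_range=(int(col_edges[w]), int(col_edges[w + 1])),
                grid_pos=(w, h),
            )
            for w in range(n_tiles_w)
        ]
        for h in range(n_tiles_h)
    ]
    return Tessellation(phase_map, tiles, n_tiles_w, n_tiles_h)


def add_tile_offset(tile: Tile, k: int) -> None:
    """Add 2π·k to every pixel of the tile (mutates the parent map).

    Offsets accumulate on the tile's integer counter and are applied from the
    stored base values, so k and −k cancel exactly.
    """
    tile.offset += int(k)
    tile.values[...] = tile._base + TWO_PI * tile.offset


def jump_map(wrapped: PhaseMap, unwrapped: PhaseMap, tolerance: float = JUMP_TOLERANCE) -> np.ndarray:
    """Integer jump field n with ϕ_u = ϕ_w + 2π·n, as a signed int array.

    Raises if the two maps are not a 2π-relabeling of each other (residual
    above ``tolerance``).
    """
    wv = _values_of(wrapped)
    uv = _values_of(unwrapped)
    if wv.shape != uv.shape:
        raise ValueError("jump_map: shape mismatch")
    n = np.rint((uv - wv) / TWO_PI)
    residual = np.abs(uv - wv - TWO_PI * n)
    worst = residual.max()
    if worst > tolerance:
        raise ValueError(
            f"maps are not related by integer 2π jumps (max residual {worst:.3g} rad)"
        )
    return n.astype(np.int64)


@dataclass(eq=False)
class ResidueMap:
    """Integer residue charges on the 2×2 plaquettes of a wrapped map.

    ``charges`` has shape (N_Y−1, N_X−1); charge (i, j) is the closed-loop
    sum of wrapped pairwise differences around the plaquette with corners
    (i, j), (i, j+1), (i+1, j+1), (i+1, j), divided by 2π.  For bounded input
    phase the charges lie in {−1, 0, +1}; a nonzero charge marks a residue.
    """

    charges: np.ndarray

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())

    @property
    def n_positive(self) -> int:
        return int((self.charges > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.charges < 0).sum())


def count_residues(phase_map) -> ResidueMap:
    """Detect phase residues of a wrapped map.

    The loop runs (i,j) → (i,j+1) → (i+1,j+1) → (i+1,j) → (i,j); by the
    discrete gradient theorem the charge is zero wherever the wrapped map is
    consistent with a single-valued phase sampled under the Itoh condition.
    """
    if isinstance(phase_map, PhaseMap) and not phase_map.wrapped:
        raise ValueError("count_residues requires a wrapped phase map")
    v = _values_of(phase_map)
    dx = _wrap(np.diff(v, axis=1))  # (H, W-1)
    dy = _wrap(np.diff(v, axis=0))  # (H-1, W)
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    charges = np.rint(loop / TWO_PI)
    # the loop sum is a sum of four wrapped values, hence an exact 2π multiple
    if np.abs(loop / TWO_PI - charges).max() > JUMP_TOLERANCE:
        raise AssertionError("plaquette loop sums are not integer 2π multiples")
    return ResidueMap(charges.astype(np.int64))
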