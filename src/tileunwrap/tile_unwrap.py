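"""Unwrapping of individual tiles.

Two tile unwrappers are provided:

* **Strand's unwrapper** — finds a single constant offset ρ ∈ [0, 2π) that,
  after re-wrapping the tile relative to ρ, minimizes a roughness penalty
  Π (mean squared *un-wrapped* forward differences).  Any phase wrap left in
  the tile contributes ≈(2π)² to Π, so the minimizing ρ removes the wrap
  line when the tile's phase range fits within one period.

* **MLSQU** (model-based least-squares unwrapper) — fits a smooth guess
  surface f(x, y) = ρ + Σ c_l ν_l(x, y) to the tile's wrapped gradient
  (which equals the unwrapped gradient under the Itoh condition), removes f,
  and applies Strand's constant-offset search to the wrapped remainder.  The
  output is f + ρ + W(ϕ_rem − ρ).  Because the model captures the in-tile
  surface, tiles containing several wrap lines unwrap correctly — the case
  where a constant offset alone must fail.

The least-squares system depends only on the tile geometry and the basis, so
its SVD is computed once per distinct (height, width, basis) and reused
across all tiles of that geometry (:class:`SystemCache`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phase_core import TWO_PI, Tile, _wrap


@dataclass(frozen=True)
class BasisSpec:
    """Monomial basis ν_l(x, y) = x^i y^j with (i, j) ≠ (0, 0).

    ``degree`` is the maximum power P per axis; the constant monomial is
    excluded because it is absorbed into the offset ρ, leaving
    N_B = (P+1)² − 1 functions.  Monomials are evaluated in per-tile
    normalized coordinates (each axis affinely mapped to [−1, 1]) for
    numerical conditioning; derivatives carry the corresponding chain-rule
    factor.
    """

    degree: int
    exponents: tuple = ()

    @property
    def n_functions(self) -> int:
        return len(self.exponents)


def monomial_basis(degree: int) -> BasisSpec:
    """Monomial basis of per-axis degree ``P``; P = 0 yields the empty basis
    (Strand's constant-only special case)."""
    if degree < 0:
        raise ValueError("polynomial degree must be >= 0")
    exps = tuple(
        (i, j)
        for i in range(degree + 1)
        for j in range(degree + 1)
        if (i, j) != (0, 0)
    )
    return BasisSpec(degree=degree, exponents=exps)


# ---------------------------------------------------------------------------
# Strand's constant-offset unwrapper
# ---------------------------------------------------------------------------

def _tile_values(tile_or_array) -> np.ndarray:
    if isinstance(tile_or_array, Tile):
        return np.asarray(tile_or_array.values, dtype=float)
    v = np.asarray(tile_or_array, dtype=float)
    if v.ndim != 2 or v.size == 0:
        raise ValueError("tile values must form a non-empty 2D array")
    return v


def strand_penalty(values) -> float:
    """Roughness penalty Π: mean squared forward differences, not wrapped.

    Averages run over valid difference positions only (pixels that have a
    forward neighbor); a 1×1 tile has no valid differences and Π = 0.  Phase
    wraps inside the tile contribute with ≈(2π)², making Π a proxy for the
    number of wrap lines.
    """
    v = _tile_values(values)
    pen = 0.0
    if v.shape[1] > 1:
        pen += float(np.mean(np.diff(v, axis=1) ** 2))
    if v.shape[0] > 1:
        pen += float(np.mean(np.diff(v, axis=0) ** 2))
    return pen


def _penalties_over_candidates(values: np.ndarray, rhos: np.ndarray) -> np.ndarray:
    """Π(W(values − ρ') + ρ') for every candidate ρ', vectorized."""
    t = _wrap(values[None, :, :] - rhos[:, None, None]) + rhos[:, None, None]
    pens = np.zeros(len(rhos))
    if values.shape[1] > 1:
        dx = np.diff(t, axis=2)
        pens += np.mean(dx * dx, axis=(1, 2))
    if values.shape[0] > 1:
        dy = np.diff(t, axis=1)
        pens += np.mean(dy * dy, axis=(1, 2))
    return pens


def strand_rho_search(values, n_rho: int = 40) -> float:
    """Exhaustive search for the offset ρ minimizing Π(W(values − ρ′) + ρ′).

    Candidates are the ``n_rho`` equidistant values 2πi/N_ρ, i = 0..N_ρ−1.
    Ties are broken toward the smallest candidate.
    """
    if n_rho < 1:
        raise ValueError("n_rho must be >= 1")
    v = _tile_values(values)
    rhos = TWO_PI * np.arange(n_rho) / n_rho
    pens = _penalties_over_candidates(v, rhos)
    return float(rhos[int(np.argmin(pens))])


def strand_unwrap_tile(values, n_rho: int = 40) -> np.ndarray:
    """Unwrap a tile with Strand's constant-offset method.

    Returns ``W(values − ρ) + ρ``; the output differs from the input by a
    pixelwise integer multiple of 2π.
    """
    v = _tile_values(values)
    rho = strand_rho_search(v, n_rho)
    return _wrap(v - rho) + rho


# ---------------------------------------------------------------------------
# MLSQU: least-squares surface fit to the wrapped gradient
# ---------------------------------------------------------------------------

def _axis_coords(n: int) -> tuple[np.ndarray, float]:
    """Normalized coordinates of n pixels on [−1, 1] and the scale dX/dx."""
    if n == 1:
        return np.zeros(1), 0.0
    scale = 2.0 / (n - 1)
    return -1.0 + scale * np.arange(n), scale


def _monomials(basis: BasisSpec, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """ν_l on the (ys × xs) grid, row-major rows, one column per function."""
    xx, yy = np.meshgrid(xs, ys)
    cols = [
        (xx ** i * yy ** j).ravel() for (i, j) in basis.exponents
    ]
    return np.column_stack(cols)


def _monomial_dx(basis: BasisSpec, xs: np.ndarray, ys: np.ndarray, scale: float) -> np.ndarray:
    xx, yy = np.meshgrid(xs, ys)
    cols = []
    for (i, j) in basis.exponents:
        if i == 0:
            cols.append(np.zeros(xx.size))
        else:
            cols.append((i * xx ** (i - 1) * yy ** j).ravel() * scale)
    return np.column_stack(cols)


def _monomial_dy(basis: BasisSpec, xs: np.ndarray, ys: np.ndarray, scale: float) -> np.ndarray:
    xx, yy = np.meshgrid(xs, ys)
    cols = []
    for (i, j) in basis.exponents:
        if j == 0:
            cols.append(np.zeros(xx.size))
        else:
            cols.append((j * yy ** (j - 1) * xx ** i).ravel() * scale)
    return np.column_stack(cols)


def system_matrix(height: int, width: int, basis: BasisSpec) -> np.ndarray:
    """Dense system matrix A: x-difference rows stacked over y-difference rows.

    Row (k, l) holds the analytic partial derivative of ν_l evaluated at the
    midpoint of forward-difference pair k, with k running row-major over
    valid positions: (W−1)·H rows for x, then W·(H−1) rows for y.  At the
    midpoint the analytic derivative coincides exactly with the forward
    difference of ν_l for per-axis degree ≤ 2.
    """
    if height < 1 or width < 1:
        raise ValueError("tile geometry must be non-empty")
    if basis.n_functions == 0:
        raise ValueError(
            "empty basis has no system matrix; use strand_unwrap_tile for the "
            "constant-only model"
        )
    xs, sx = _axis_coords(width)
    ys, sy = _axis_coords(height)
    # x-differences exist for width > 1 only (zero rows otherwise)
    if width > 1:
        xm = xs[:-1] + sx / 2.0
        a_x = _monomial_dx(basis, xm, ys, sx)
    else:
        a_x = np.zeros((0, basis.n_functions))
    if height > 1:
        ym = ys[:-1] + sy / 2.0
        a_y = _monomial_dy(basis, xs, ym, sy)
    else:
        a_y = np.zeros((0, basis.n_functions))
    return np.vstack([a_x, a_y])


@dataclass(eq=False)
class SystemFactors:
    """Reusable SVD factors of a tile-geometry system matrix.

    ``c = Vt.T @ (s_inv * (U.T @ g))`` is the minimum-norm least-squares
    solution; singular values below ``max(A.shape)·eps·σ_max`` are truncated.
    ``design_values`` holds ν_l at the pixel grid for evaluating the fitted
    surface.
    """

    height: int
    width: int
    basis: BasisSpec
    u: np.ndarray
    s_inv: np.ndarray
    vt: np.ndarray
    design_values: np.ndarray
    n_rows: int


@dataclass(eq=False)
class SystemCache:
    """Per-(height, width, basis) cache of :class:`SystemFactors`."""

    _store: dict = field(default_factory=dict)

    def get(self, key):
        return self._store.get(key)

    def put(self, key, factors):
        self._store[key] = factors


def build_system(height: int, width: int, basis: BasisSpec, cache: SystemCache | None = None) -> SystemFactors:
    """Build (or fetch from cache) the SVD factors for one tile geometry.

    A second call with the same (height, width, basis) key on the same cache
    returns the identical factor object without refactorization.
    """
    key = (height, width, basis)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    a = system_matrix(height, width, basis)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    if s.size and s[0] > 0:
        cutoff = max(a.shape) * np.finfo(float).eps * s[0]
        s_inv = np.where(s > cutoff, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    else:
        s_inv = np.zeros_like(s)
    xs, _ = _axis_coords(width)
    ys, _ = _axis_coords(height)
    factors = SystemFactors(
        height=height,
        width=width,
        basis=basis,
        u=u,
        s_inv=s_inv,
        vt=vt,
        design_values=_monomials(basis, xs, ys),
        n_rows=a.shape[0],
    )
    if cache is not None:
        cache.put(key, factors)
    return factors


def _gradient_vector(values: np.ndarray) -> np.ndarray:
    """g: wrapped forward differences, x-rows then y-rows, row-major."""
    gx = _wrap(np.diff(values, axis=1)).ravel()
    gy = _wrap(np.diff(values, axis=0)).ravel()
    return np.concatenate([gx, gy])


def fit_coefficients(values, factors: SystemFactors) -> np.ndarray:
    """Minimum-norm least-squares coefficients c minimizing ‖A·c − g‖²."""
    v = _tile_values(values)
    if v.shape != (factors.height, factors.width):
        raise ValueError("tile shape does not match the cached factors")
    g = _gradient_vector(v)
    return factors.vt.T @ (factors.s_inv * (factors.u.T @ g))


def mlsq_unwrap_tile(values, basis: BasisSpec, n_rho: int = 40, cache: SystemCache | None = None) -> np.ndarray:
    """Model-based least-squares unwrap of a single tile.

    Fits the guess surface f₀ (ρ = 0) to the wrapped gradient, forms the
    wrapped remainder ϕ_rem = W(values − f₀), finds the offset ρ by Strand's
    search on ϕ_rem, and returns ``f₀ + ρ + W(ϕ_rem − ρ)``.  With the empty
    basis this degenerates to Strand's method, to which it delegates.
    """
    v = _tile_values(values)
    if basis.n_functions == 0:
        return strand_unwrap_tile(v, n_rho)
    factors = build_system(v.shape[0], v.shape[1], basis, cache)
    c = fit_coefficients(v, factors)
    f0 = (factors.design_values @ c).reshape(v.shape)
    phi_rem = _wrap(v - f0)
    rho = strand_rho_search(phi_rem, n_rho)
    return f0 + rho + _wrap(phi_rem - rho)


def unwrap_tessellation(tess, unwrapper: str = "mlsq", poly_degree: int = 2,
                        n_rho: int = 40, cache: SystemCache | None = None) -> None:
    """Unwrap every tile of a tessellation in place.

    ``unwrapper`` is ``'mlsq'`` (with monomial basis of degree
    ``poly_degree``) or ``'strand'``.
    """
    if unwrapper == "strand":
        for tile in tess:
            tile.set_values(strand_unwrap_tile(tile.values, n_rho))
        return
    if unwrapper == "mlsq":
        basis = monomial_basis(poly_degree)
        if cache is None:
            cache = SystemCache()
        for tile in tess:
            tile.set_values(mlsq_unwrap_tile(tile.values, basis, n_rho, cache))
        return
    raise ValueError(f"unknown tile unwrapper {unwrapper!r}")
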