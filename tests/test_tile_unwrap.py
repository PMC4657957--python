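import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tileunwrap import (
    TWO_PI,
    SystemCache,
    build_system,
    fit_coefficients,
    mlsq_unwrap_tile,
    monomial_basis,
    strand_penalty,
    strand_rho_search,
    strand_unwrap_tile,
    system_matrix,
    tessellate,
    wrap,
)


def assert_2pi_lattice(output, input_values, tol=1e-6):
    """Unwrapper contract: output − input is a pixelwise 2π·integer field."""
    k = (output - input_values) / TWO_PI
    assert np.abs(k - np.rint(k)).max() < tol / TWO_PI * TWO_PI


class TestMonomialBasis:
    @pytest.mark.parametrize("degree,count", [(0, 0), (1, 3), (2, 8), (6, 48)])
    def test_function_count(self, degree, count):
        assert monomial_basis(degree).n_functions == count

    def test_degree_one_enumeration(self):
        assert set(monomial_basis(1).exponents) == {(1, 0), (0, 1), (1, 1)}

    def test_constant_excluded(self):
        assert (0, 0) not in monomial_basis(4).exponents

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            monomial_basis(-1)


class TestStrandPenalty:
    def test_constant_tile_zero(self):
        assert strand_penalty(np.full((4, 5), 1.3)) == 0.0

    def test_single_pixel_zero(self):
        assert strand_penalty(np.array([[0.7]])) == 0.0

    def test_wrap_free_ramp(self):
        # slope 0.5 in x only: Π = 0.5² + 0 (differences are NOT wrapped)
        v = np.tile(0.5 * np.arange(6), (3, 1))
        assert strand_penalty(v) == pytest.approx(0.25)

    def test_two_by_two_with_jump(self):
        big = TWO_PI - 0.1
        v = np.array([[0.0, 0.0], [0.0, big]])
        # per axis: mean of squared diffs {0, big²}
        assert strand_penalty(v) == pytest.approx(big**2, rel=1e-12)


class TestStrandRhoSearch:
    def test_constant_tile_ties_break_to_zero(self):
        assert strand_rho_search(np.full((3, 3), 1.0), 40) == 0.0

    def test_removes_single_wrap_line(self):
        v = np.array([[-3.1, 3.1]])
        rho = strand_rho_search(v, 40)
        t = wrap(v - rho) + rho
        assert abs(t[0, 1] - t[0, 0]) == pytest.approx(TWO_PI - 6.2, abs=1e-9)

    def test_agrees_with_exhaustive_sweep(self, rng):
        for _ in range(10):
            v = rng.uniform(-math.pi, math.pi, rng.integers(1, 6, 2))
            n_rho = 17
            # independent exhaustive oracle over the same candidate grid
            cands = TWO_PI * np.arange(n_rho) / n_rho
            pens = [strand_penalty(wrap(v - r) + r) for r in cands]
            assert strand_rho_search(v, n_rho) == pytest.approx(
                cands[int(np.argmin(pens))]
            )

    def test_two_wrap_lines_cannot_be_removed(self):
        # constant-offset unwrapping fails once a tile spans two wrap lines
        v = wrap(np.linspace(0.0, 4 * math.pi, 30)[None, :])
        for rho in TWO_PI * np.arange(40) / 40:
            assert strand_penalty(wrap(v - rho) + rho) > 1.0


class TestStrandUnwrap:
    def test_constant_unchanged(self):
        v = np.full((3, 4), -0.4)
        assert strand_unwrap_tile(v, 40) == pytest.approx(v)

    def test_single_jump_removed_on_lattice(self):
        v = np.array([[-3.1, 3.1]])
        out = strand_unwrap_tile(v, 40)
        assert_2pi_lattice(out, v)
        assert abs(np.diff(out)).max() < math.pi

    def test_recovers_ground_truth_within_one_period(self):
        # tile range < 2π − 2π/N_ρ and Itoh-valid: exact up to 2π constant
        truth = 0.15 * np.arange(20)[None, :] + 1.0
        out = strand_unwrap_tile(wrap(truth), 40)
        assert np.ptp(out - truth) < 1e-9
        k = (out - truth).mean() / TWO_PI
        assert abs(k - round(k)) < 1e-9


class TestSystem:
    def test_row_and_column_counts(self):
        f = build_system(30, 30, monomial_basis(2))
        assert f.n_rows == 2 * 30 * 29
        assert f.u.shape == (1740, 8)
        assert f.design_values.shape == (900, 8)

    def test_pure_x_basis_rows(self):
        from tileunwrap import BasisSpec

        basis = BasisSpec(degree=1, exponents=((1, 0),))
        a = system_matrix(4, 5, basis)
        n_x = 4 * 4  # (W−1)·H
        assert np.ptp(a[:n_x, 0]) == 0.0 and a[0, 0] != 0.0  # δx x constant
        assert (a[n_x:, 0] == 0.0).all()  # δy x ≡ 0

    def test_cache_returns_identical_factors(self):
        cache = SystemCache()
        basis = monomial_basis(2)
        f1 = build_system(7, 9, basis, cache)
        f2 = build_system(7, 9, basis, cache)
        assert f1 is f2

    def test_empty_basis_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            build_system(5, 5, monomial_basis(0))


class TestFitCoefficients:
    def test_matches_normal_equations_oracle(self, rng):
        basis = monomial_basis(2)
        for shape in [(12, 9), (6, 15), (10, 10)]:
            v = wrap(rng.uniform(-8, 8, shape))
            factors = build_system(*shape, basis)
            c = fit_coefficients(v, factors)
            # brute-force dense normal equations on the same system
            a = system_matrix(*shape, basis)
            g = np.concatenate(
                [wrap(np.diff(v, axis=1)).ravel(), wrap(np.diff(v, axis=0)).ravel()]
            )
            c_ref = np.linalg.solve(a.T @ a, a.T @ g)
            assert np.linalg.norm(c - c_ref) < 1e-8

    def test_plane_gradient_recovered(self):
        y, x = np.mgrid[0:14, 0:11]
        v = wrap(0.5 * x + 0.2 * y)
        factors = build_system(14, 11, monomial_basis(1))
        c = fit_coefficients(v, factors)
        f0 = (factors.design_values @ c).reshape(14, 11)
        assert np.diff(f0, axis=1) == pytest.approx(0.5, abs=1e-9)
        assert np.diff(f0, axis=0) == pytest.approx(0.2, abs=1e-9)

    def test_constant_tile_gives_zero_coefficients(self):
        factors = build_system(6, 6, monomial_basis(2))
        c = fit_coefficients(np.full((6, 6), 0.8), factors)
        assert np.abs(c).max() < 1e-14

    def test_in_span_quadratic_fits_exactly(self):
        y, x = np.mgrid[0:15, 0:15]
        truth = 0.9 + 0.31 * x + 0.17 * y - 0.012 * x * y + 0.011 * x**2 + 0.009 * y**2
        factors = build_system(15, 15, monomial_basis(2))
        c = fit_coefficients(wrap(truth), factors)
        a = system_matrix(15, 15, monomial_basis(2))
        g = np.concatenate(
            [np.diff(truth, axis=1).ravel(), np.diff(truth, axis=0).ravel()]
        )
        assert np.sum((a @ c - g) ** 2) < 1e-12


class TestMlsqUnwrap:
    def test_recovers_polynomial_surface_with_wraps(self):
        y, x = np.mgrid[0:24, 0:17]
        truth = 1.2 + 0.3 * x + 0.25 * y - 0.01 * x * y + 0.004 * x**2 + 0.003 * y**2
        out = mlsq_unwrap_tile(wrap(truth), monomial_basis(2), 40)
        assert np.ptp(out - truth) < 1e-6
        k = (out - truth).mean() / TWO_PI
        assert abs(k - round(k)) < 1e-6

    def test_degree_zero_equals_strand_bitwise(self, rng):
        v = wrap(rng.uniform(-9, 9, (8, 8)))
        mlsq = mlsq_unwrap_tile(v, monomial_basis(0), 40)
        strand = strand_unwrap_tile(v, 40)
        assert np.array_equal(mlsq, strand)

    def test_warm_and_cold_cache_agree_bitwise(self, rng):
        v = wrap(rng.uniform(-9, 9, (10, 12)))
        basis = monomial_basis(3)
        cold = mlsq_unwrap_tile(v, basis, 40, SystemCache())
        warm_cache = SystemCache()
        build_system(10, 12, basis, warm_cache)
        warm = mlsq_unwrap_tile(v, basis, 40, warm_cache)
        assert np.array_equal(cold, warm)

    def test_2pi_lattice_invariant(self, rng):
        v = wrap(rng.uniform(-9, 9, (9, 9)))
        out = mlsq_unwrap_tile(v, monomial_basis(2), 40)
        assert_2pi_lattice(out, v)

    def test_handles_multiple_wrap_lines_per_tile(self, small_truth):
        # tiles of the synthetic surface, several containing >1 wrap line,
        # all recovered up to a per-tile 2π constant
        from tileunwrap import PhaseMap

        pm = PhaseMap(wrap(small_truth.values), wrapped=True)
        tess = tessellate(pm, 10, 10)
        basis = monomial_basis(2)
        cache = SystemCache()
        for tile in tess:
            r0, r1 = tile.row_range
            c0, c1 = tile.col_range
            truth_tile = small_truth.values[r0:r1, c0:c1]
            out = mlsq_unwrap_tile(tile.values, basis, 40, cache)
            assert np.ptp(out - truth_tile) < 1e-6


class TestGuessFunctionIdentity:
    @given(st.integers(0, 2**31 - 1))
    def test_correction_reconstructs_phase(self, seed):
        # for any f with |ϕ_u − f| < π: ϕ_u = f + W(W(ϕ_u) − f)
        rng = np.random.default_rng(seed)
        f = rng.uniform(-20, 20) + rng.uniform(-0.2, 0.2, (5, 5)).cumsum(axis=1)
        phi_u = f + rng.uniform(-0.9 * math.pi, 0.9 * math.pi, (5, 5))
        reconstructed = f + wrap(wrap(phi_u) - f)
        assert reconstructed == pytest.approx(phi_u, abs=1e-9)
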