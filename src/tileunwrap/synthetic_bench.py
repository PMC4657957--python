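"""Synthetic ground truths, noise/residue scenarios, and the deviation metric.

The benchmark phase surface is a sum of two overlapping Gaussian bumps on an
N×N raster (default N = 600)::

    ϕ_u(x, y) = 4π·exp(−((x−N/3)² + (y−N/3)²) / (2·(N/6)²))
              + 8π·exp(−((x−2N/3)² + (y−2N/3)²) / (2·(N/8)²))

whose wrapped image shows several concentric wrap lines per bump while
satisfying the Itoh sampling condition, so noise-free unwrapping has a unique
exact solution.  A noisy realization adds zero-mean white Gaussian noise of
standard deviation σ before wrapping; results are scored against the *noisy*
ground truth ϕ_u^σ with the deviation

    D = (1/N_X N_Y) Σ |ϕ_u^alg − ϕ_u^σ − μ|²,   μ = ⟨ϕ_u^alg − ϕ_u^σ⟩,

which is invariant under a constant (e.g. 2πk) offset of either map.  The
residue scenario blurs a small rectangle of the wrapped map placed across a
wrap line, which severs the wrap isoline and leaves a ±1 residue pair at its
open ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phase_core import (
    PhaseMap,
    _values_of,
    count_residues,
    tessellate,
    wrap,
)
from .pixel_srncp import srncp_unwrap
from .tile_merge import MERGERS
from .tile_unwrap import SystemCache, unwrap_tessellation

#: Residue-injection rectangle on the default 600-pixel raster:
#: (row_start, row_stop, col_start, col_stop), half-open.  A 20×40 px box
#: straddling the outermost wrap line of the 8π bump (radius ≈ 153 px from
#: its center at (400, 400)).
DEFAULT_RESIDUE_RECT = (390, 410, 533, 573)

#: Gaussian blur kernel standard deviation (pixels) for residue injection.
DEFAULT_BLUR_WIDTH = 5.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-Gaussian phase surface.

    Amplitudes 4π and 8π, centers (N/3, N/3) and (2N/3, 2N/3), widths N/6 and
    N/8 by default; all overridable.
    """

    n: int = 600
    amplitudes: tuple = (4.0 * np.pi, 8.0 * np.pi)
    centers: tuple | None = None
    widths: tuple | None = None

    def resolved_centers(self) -> tuple:
        if self.centers is not None:
            return self.centers
        return ((self.n / 3.0, self.n / 3.0), (2.0 * self.n / 3.0, 2.0 * self.n / 3.0))

    def resolved_widths(self) -> tuple:
        if self.widths is not None:
            return self.widths
        return (self.n / 6.0, self.n / 8.0)


def gaussian_ground_truth(spec: SyntheticSpec | int = 600) -> PhaseMap:
    """Evaluate the two-Gaussian ground-truth surface on the pixel grid."""
    if not isinstance(spec, SyntheticSpec):
        spec = SyntheticSpec(n=int(spec))
    if spec.n < 2:
        raise ValueError("raster side must be at least 2")
    y = np.arange(spec.n)[:, None]
    x = np.arange(spec.n)[None, :]
    values = np.zeros((spec.n, spec.n))
    for amp, (cx, cy), width in zip(
        spec.amplitudes, spec.resolved_centers(), spec.resolved_widths()
    ):
        values += amp * np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width**2)
        )
    return PhaseMap(values, wrapped=False)


def add_noise(phase_map: PhaseMap, sigma: float, seed=None) -> PhaseMap:
    """Add zero-mean white Gaussian noise of standard deviation σ (radians).

    σ = 0 returns an exact copy; identical seeds give identical outputs.
    """
    if sigma < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if sigma == 0:
        return phase_map.copy()
    rng = np.random.default_rng(seed)
    noisy = phase_map.values + rng.normal(0.0, sigma, size=phase_map.shape)
    return PhaseMap(noisy, wrapped=False)


def make_wrapped(phase_map: PhaseMap) -> PhaseMap:
    """Wrap a phase map pixelwise and set the wrapped flag."""
    return PhaseMap(wrap(phase_map.values), wrapped=True)


def inject_residue(wrapped: PhaseMap, rect: tuple | None = None,
                   blur_width: float = DEFAULT_BLUR_WIDTH) -> PhaseMap:
    """Blur a rectangle of a wrapped map to create a residue pair.

    ``rect`` is (row_start, row_stop, col_start, col_stop), half-open; the
    default straddles the outermost wrap line of the 8π bump (scaled for
    non-default raster sizes).  Pixels inside the rectangle are replaced by
    Gaussian-blurred values, which smooths away the phase jump there and
    leaves residues of opposite charge near the rectangle's ends.  Warns when
    the rectangle contains no wrap line (no residues will be created).
    """
    if not wrapped.wrapped:
        raise ValueError("inject_residue requires a wrapped phase map")
    v = wrapped.values
    if rect is None:
        scale = wrapped.n_y / 600.0
        rect = tuple(int(round(r * scale)) for r in DEFAULT_RESIDUE_RECT)
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= wrapped.n_y and 0 <= c0 < c1 <= wrapped.n_x):
        raise ValueError("rectangle must lie within the raster")
    inside = v[r0:r1, c0:c1]
    has_jump = False
    if inside.shape[1] > 1:
        has_jump |= bool((np.abs(np.diff(inside, axis=1)) > np.pi).any())
    if inside.shape[0] > 1:
        has_jump |= bool((np.abs(np.diff(inside, axis=0)) > np.pi).any())
    if not has_jump:
        warnings.warn(
            "residue rectangle contains no wrap line; no residues will be created",
            stacklevel=2,
        )
    out = v.copy()
    if blur_width > 0:
        blurred = ndimage.gaussian_filter(v, sigma=blur_width)
        out[r0:r1, c0:c1] = blurred[r0:r1, c0:c1]
    return PhaseMap(out, wrapped=True)


def deviation(a, b) -> float:
    """Deviation D: mean squared difference after removing the mean offset."""
    av = _values_of(a)
    bv = _values_of(b)
    if av.shape != bv.shape:
        raise ValueError("deviation: shape mismatch")
    d = av - bv
    mu = d.mean()
    return float(np.mean((d - mu) ** 2))


def rms_deviation(a, b) -> float:
    """Root-mean-square deviation in radians: sqrt of :func:`deviation`.

    This is the scale on which unwrapping quality is usually quoted (an
    error field of isolated ±2π pixels with fraction f has RMS ≈ 2π·√f).
    """
    return float(np.sqrt(deviation(a, b)))


# ---------------------------------------------------------------------------
# Algorithm pipelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """A complete unwrapping pipeline: tile unwrapper + merger, or pixel SRNCP.

    ``unwrapper`` is one of ``'strand'``, ``'mlsq'``, ``'pixel-srncp'``.
    Tile-based unwrappers require ``tiles`` = (NτW, NτH) and a ``merger``
    (``'unidirectional'`` or ``'tsrncp'``); the pixel unwrapper forbids both.
    """

    name: str
    unwrapper: str
    merger: str | None = None
    tiles: tuple | None = None
    poly_degree: int = 2
    n_rho: int = 40

    def __post_init__(self):
        if self.unwrapper == "pixel-srncp":
            if self.merger is not None or self.tiles is not None:
                raise ValueError("pixel-srncp takes neither a merger nor a tessellation")
        elif self.unwrapper in ("strand", "mlsq"):
            if self.merger not in MERGERS:
                raise ValueError(f"tile-based pipelines need a merger from {sorted(MERGERS)}")
            if self.tiles is None:
                raise ValueError("tile-based pipelines need a tessellation (NτW, NτH)")
        else:
            raise ValueError(f"unknown unwrapper {self.unwrapper!r}")

    def run(self, wrapped: PhaseMap, cache: SystemCache | None = None) -> PhaseMap:
        """Unwrap a wrapped map; the input is not modified."""
        if self.unwrapper == "pixel-srncp":
            return PhaseMap(srncp_unwrap(wrapped), wrapped=False)
        work = PhaseMap(wrapped.values.copy(), wrapped=True)
        tess = tessellate(work, self.tiles[0], self.tiles[1])
        unwrap_tessellation(
            tess,
            unwrapper=self.unwrapper,
            poly_degree=self.poly_degree,
            n_rho=self.n_rho,
            cache=cache,
        )
        return MERGERS[self.merger](tess)


#: The proposed pipeline of the study: MLSQU (P=2, N_ρ=40) on 20×20 tiles,
#: merged with the τSRNCP merger.
MLSQU_TSRNCP = PipelineConfig("mlsq-p2-20x20-tsrncp", "mlsq", "tsrncp", (20, 20), 2, 40)

#: Strand's original algorithm: Strand tiles (N_ρ=20) on 40×40, merged
#: unidirectionally.
STRAND_UNIDIRECTIONAL = PipelineConfig(
    "strand-40x40-unidirectional", "strand", "unidirectional", (40, 40), n_rho=20
)

#: Pixel-based SRNCP reference (no tessellation).
PIXEL_SRNCP = PipelineConfig("pixel-srncp", "pixel-srncp")

BENCHMARK_CONFIGS = (MLSQU_TSRNCP, STRAND_UNIDIRECTIONAL, PIXEL_SRNCP)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, sigma_index: int, rep: int) -> int:
    """Deterministic per-(σ, repetition) child seed below 2³¹."""
    ss = np.random.SeedSequence([int(base_seed), int(sigma_index), int(rep)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(eq=False)
class BenchmarkResult:
    """Per-run deviations and their per-(algorithm, σ) means."""

    records: pd.DataFrame  # columns: algorithm, sigma, rep, seed, deviation

    def summary(self) -> pd.DataFrame:
        rec = self.records.assign(rms=np.sqrt(self.records["deviation"]))
        s = (
            rec.groupby(["algorithm", "sigma"], sort=True)
            .agg(reps=("deviation", "count"), mean_deviation=("deviation", "mean"),
                 mean_rms_deviation=("rms", "mean"))
            .reset_index()
        )
        return s

    def mean_deviation(self, algorithm: str, sigma: float) -> float:
        mask = (self.records["algorithm"] == algorithm) & np.isclose(
            self.records["sigma"], sigma
        )
        sub = self.records.loc[mask, "deviation"]
        if sub.empty:
            raise KeyError(f"no rows for {algorithm!r} at sigma={sigma}")
        return float(sub.mean())

    def mean_rms_deviation(self, algorithm: str, sigma: float) -> float:
        """Mean over repetitions of the per-map RMS deviation (radians)."""
        mask = (self.records["algorithm"] == algorithm) & np.isclose(
            self.records["sigma"], sigma
        )
        sub = self.records.loc[mask, "deviation"]
        if sub.empty:
            raise KeyError(f"no rows for {algorithm!r} at sigma={sigma}")
        return float(np.sqrt(sub).mean())

    def to_csv(self, path, summary_path=None) -> None:
        self.records.to_csv(path, index=False)
        if summary_path is not None:
            self.summary().to_csv(summary_path, index=False)


def noise_sweep(configs, sigmas, reps: int = 25, base_seed: int = 0,
                n: int = 600, spec: SyntheticSpec | None = None) -> BenchmarkResult:
    """Noise-robustness sweep: mean deviation per algorithm and noise level.

    For every (σ, repetition), one noisy ground truth ϕ_u^σ is generated with
    a seed derived from ``base_seed``; every algorithm unwraps the *identical*
    wrapped map and is scored against ϕ_u^σ.
    """
    if spec is None:
        spec = SyntheticSpec(n=n)
    phi_u = gaussian_ground_truth(spec)
    caches = {cfg.name: SystemCache() for cfg in configs}
    rows = []
    for si, sigma in enumerate(sigmas):
        for rep in range(reps):
            seed = derive_seed(base_seed, si, rep)
            noisy = add_noise(phi_u, float(sigma), seed)
            wrapped = make_wrapped(noisy)
            for cfg in configs:
                result = cfg.run(wrapped, cache=caches[cfg.name])
                rows.append(
                    {
                        "algorithm": cfg.name,
                        "sigma": float(sigma),
                        "rep": rep,
                        "seed": seed,
                        "deviation": deviation(result, noisy),
                    }
                )
    return BenchmarkResult(pd.DataFrame(rows))


#: Default configurations of the residue scenario comparison.
RESIDUE_CONFIGS = (
    PIXEL_SRNCP,
    STRAND_UNIDIRECTIONAL,
    PipelineConfig("mlsq-p2-20x20-unidirectional", "mlsq", "unidirectional", (20, 20), 2, 40),
    MLSQU_TSRNCP,
    PipelineConfig("mlsq-p6-2x2-tsrncp", "mlsq", "tsrncp", (2, 2), 6, 60),
)


@dataclass(eq=False)
class ResidueReport:
    """Outcome of the residue-containment experiment."""

    table: pd.DataFrame  # algorithm, deviation, affected_fraction
    n_positive_residues: int
    n_negative_residues: int


def residue_experiment(base_seed: int = 0, n: int = 600, sigma: float = 0.3,
                       rect: tuple | None = None,
                       blur_width: float = DEFAULT_BLUR_WIDTH,
                       configs=RESIDUE_CONFIGS) -> ResidueReport:
    """Residue scenario: blur a rectangle over a wrap line, add σ=0.3 noise,
    wrap, and unwrap with each configuration.

    Reports per configuration the deviation from the noisy (unblurred) truth
    and the affected-pixel fraction — the share of pixels whose error versus
    the noiseless truth exceeds π after mean-offset removal.  Residues of the
    wrapped input are counted as well.
    """
    spec = SyntheticSpec(n=n)
    phi_u = gaussian_ground_truth(spec)
    blurred = inject_residue(make_wrapped(phi_u), rect, blur_width)
    rng = np.random.default_rng(derive_seed(base_seed, 0, 0))
    eta = rng.normal(0.0, sigma, size=phi_u.shape) if sigma > 0 else 0.0
    wrapped_input = PhaseMap(wrap(blurred.values + eta), wrapped=True)
    truth_noisy = phi_u.values + eta

    residues = count_residues(wrapped_input)
    rows = []
    for cfg in configs:
        result = cfg.run(wrapped_input)
        err = result.values - phi_u.values
        err -= err.mean()
        rows.append(
            {
                "algorithm": cfg.name,
                "deviation": deviation(result, truth_noisy),
                "affected_fraction": float(np.mean(np.abs(err) > np.pi)),
            }
        )
    return ResidueReport(
        table=pd.DataFrame(rows),
        n_positive_residues=residues.n_positive,
        n_negative_residues=residues.n_negative,
    )
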