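# Methods

## Model and procedure

A wrapped phase map is a raster ϕ_w = ϕ_u − 2π·n with ϕ_w ∈ [−π, π) and
integer n. The wrap operator is implemented branch-free as
W(x) = x − 2π·floor((x + π)/2π), which realizes the half-open interval
exactly (W(π) = −π). Two facts drive everything else:

1. **Itoh**: if |δϕ_u| < π for neighboring pixels, the wrapped forward
   difference W(δϕ_w) equals δϕ_u, so the unwrapped gradient is observable
   from wrapped data.
2. **Guess-function identity**: for any surface f with |ϕ_u − f| < π
   pointwise, ϕ_u = f + W(ϕ_w − f).

The pipeline tessellates the raster into NτW × NτH rectangular tiles (base
size floor(N/count); the first N mod count tiles along each axis get one
extra pixel, so at most four distinct tile geometries occur), unwraps each
tile independently, and merges tiles by per-tile integer multiples of 2π.

### Tile unwrapping

**Strand's method.** The penalty Π(τ) is the mean of squared first forward
differences (x-axis plus y-axis terms), *without* wrapping, over positions
that have a forward neighbor; a wrap line inside the tile contributes ≈(2π)².
The offset ρ is the minimizer of Π(W(ϕ_w − ρ′) + ρ′) over the N_ρ equidistant
candidates ρ′ = 2πi/N_ρ, found by exhaustive evaluation (vectorized over
candidates); ties break toward the smallest ρ′. The tile unwrap is
W(ϕ_w − ρ) + ρ.

**MLSQU.** The guess surface is f = ρ + Σ c_l ν_l with monomials
ν_l = x^i y^j, 0 ≤ i, j ≤ P, (i, j) ≠ (0, 0) (the constant is absorbed into
ρ), giving N_B = (P+1)² − 1 coefficients. Coefficients solve
‖A·c − g‖² → min where g stacks the wrapped forward differences (x-rows then
y-rows, row-major) and A holds the corresponding basis-derivative values.
After the fit, ϕ_rem = W(ϕ_w − f₀) (f₀ is the fit with ρ = 0) is unwrapped
with Strand's offset search — the minimizer symbol in the offset-search
expression is read as acting on this remainder — and the output is
f₀ + ρ + W(ϕ_rem − ρ). With P = 0 the basis is empty and the method *is*
Strand's (the implementation delegates, bit-for-bit).

Numerical choices for the fit:

* **Valid-position rows only.** Forward differences are undefined on the last
  row/column, so A has (W−1)·H x-rows and W·(H−1) y-rows rather than the
  nominal 2·N_px; zero-padding boundary rows would bias the fit toward flat
  surfaces.
* **Midpoint derivative evaluation.** Row (k, l) of A is the analytic partial
  derivative of ν_l at the midpoint of pixel pair k. For per-axis degree ≤ 2
  the analytic midpoint derivative coincides *exactly* with the forward
  difference of the monomial, so in-span surfaces are recovered to machine
  precision; for higher degrees it is a standard second-order discretization.
* **Normalized coordinates.** Each tile's pixel coordinates are affinely
  mapped to [−1, 1]² before evaluating monomials (chain-rule factor on the
  derivatives). Raw pixel coordinates make the P = 6 system on 300-pixel
  tiles catastrophically ill-conditioned; normalization changes the
  coefficient values but not the fitted surface.
* **SVD with truncation.** A depends only on (height, width, basis), so its
  SVD is computed once per geometry and cached (`SystemCache`); the
  benchmark's uniform tessellations hit a single factorization. Singular
  values below max(A.shape)·eps·σ_max are zeroed, giving the minimum-norm
  solution on rank-deficient geometries (e.g. single-row tiles, where
  y-derivatives are unobservable).

### Tile merging

For adjacent tiles the junction difference set D(J_AB) = {P_B − P_A} over
border pixel pairs has mean Δ and *population* variance V_J (÷|D|, so
length-1 junctions are well-defined with V_J = 0; only the reliability
ordering matters). Merging A onto B adds 2π·round(Δ/2π) to A, with
round-half-away-from-zero (halves occur with probability zero; the convention
only pins determinism).

* **Unidirectional merger** visits tiles column-by-column left→right, within
  a column top→bottom, and shifts each tile by the 2π multiple nearest the
  *pooled* mean of the difference sets to its already-visited top and left
  junctions (pooling weights junctions by border length; with equal-size
  tiles it coincides with the mean of junction means). The applied quantity
  is the rounded 2π multiple — applying the raw mean would overwrite the tile
  unwrapper's result with junction averaging and break the 2π-lattice
  contract.
* **τSRNCP merger.** Tile reliability R = 1/(V + ε) with V the mean of the
  tile's 2–4 junction variances and ε = 1e−12 (guards the perfectly
  continuous case while preserving order); junction reliability is the
  product of its tiles'. Reliabilities are computed once, before merging —
  V_J is invariant under the 2π offsets merging applies. Junctions are
  processed in descending reliability (ties: row-major junction index, right
  junction before down junction, stable sort) with group bookkeeping: loners
  merge onto grouped tiles; two groups merge by shifting every tile of the
  smaller group by the 2π multiple computed at the current junction, the
  smaller group being absorbed into the larger (equal sizes: A's side moves,
  consistent with the ungrouped case); same-group junctions are no-ops.

### Pixel-based SRNCP baseline

Pixel reliability is 1/(mag + ε) with mag the root-sum-square of the wrapped
second differences along the horizontal, vertical and both diagonal
directions of the 3×3 neighborhood. Border pixels, lacking the full
neighborhood, are assigned the minimal reliability ε so their edges are
processed last — a conservative choice that only reorders the final,
lowest-quality merges. Edge reliability is the sum of its two pixels'.
Edges are processed in descending reliability with the same
smaller-group-shifts-onto-larger logic as the tile merger, implemented as a
weighted union-find (integer offset per node relative to its parent, path
compression, union by size) compiled with numba — a 600×600 map has ~7·10⁵
edges. Maps thinner than 3 pixels get all-border reliabilities, so the
processing order degenerates to sequential (Itoh) merging.

## Synthetic benchmark

The ground truth is
ϕ_u = 4π·exp(−((x−N/3)² + (y−N/3)²)/(2(N/6)²)) +
8π·exp(−((x−2N/3)² + (y−2N/3)²)/(2(N/8)²)) on an N×N raster, N = 600 by
default. The widths N/6 and N/8 (100 and 75 px at N = 600) produce ~4–5
visible wrap fringes per bump while keeping the maximum gradient ≈0.2 rad/px,
comfortably Itoh-valid; the surface is deliberately not polynomial, so the
monomial model never represents it exactly. A noisy realization adds i.i.d.
N(0, σ²) per pixel *before* wrapping; per-(σ, repetition) child seeds are
derived deterministically from one master seed so that every algorithm sees
the identical wrapped input.

**Deviation metric.** `deviation(a, b)` is the mean squared difference after
removing the mean offset μ = ⟨a − b⟩ (so any constant, in particular a global
2πk, is free). Summary tables additionally quote the per-map *RMS* deviation
(its square root, radians): an error field of isolated ±2π pixels with
fraction f has RMS ≈ 2π√f, which is the scale on which unwrapping quality is
conventionally compared, and the scale used for the headline σ = 1.0 figures.

**Residue scenario.** Starting from the noise-free wrapped map, a rectangle
(default rows [390, 410), cols [533, 573) at N = 600, scaled with N) placed
across the outermost wrap line of the 8π bump is replaced by its Gaussian
blur (kernel σ = 5 px, read as the blur "width"). The blur smooths away the
phase jump inside the box, severing the wrap isoline and leaving residues of
opposite charge near the box ends. Noise (σ = 0.3) is then added and the map
re-wrapped. Reported per pipeline: the deviation from the noisy unblurred
truth, and the *affected-pixel fraction* — the share of pixels whose error
versus the noiseless truth exceeds π after mean-offset removal. The exact
rectangle placement is a package choice (the scenario is qualitative); it is
overridable.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| N_ρ | 40 (20 for the Strand 40×40 reference) | offset-search grid size; quantizes ρ to 2π/N_ρ |
| P | 2 (6 for the 2×2-tile configuration) | per-axis monomial degree; N_B = (P+1)²−1 |
| Nτ | 20×20 for MLSQU, 40×40 for Strand | tile grid; Strand tiles must span < 2π of phase |
| σ grid | 0…1 step 0.1, 25 repetitions | noise sweep |
| jump tolerance | 1e−6 rad | residual accepted as an exact 2π relation |
| ε (reliability guard) | 1e−12 | caps reliabilities at 1e12, preserves ordering |

## What the synthetic tests do and do not show

The generator emulates smooth, strictly positive phase surfaces (cell-like
height profiles) under additive white Gaussian phase noise, and isolated
blur-induced residue pairs. It does not model speckle, shot noise, fringe
washout over extended regions, intensity-dependent phase error, or masked /
non-rectangular fields of view — so a pass here demonstrates noise robustness
and error containment of the unwrapping logic, not end-to-end performance on
any particular instrument's data. Real holographic maps with many interacting
residues remain outside the synthetic scope.

## Problem sizes

The full benchmark raster (600×600, 25 repetitions per noise level) is used
for the headline figures and the acceptance checks. Unit tests exercise the
identical code paths on a 150-pixel analogue of the same surface (same wrap
count, tiles scaled to the same fraction of a feature width), which keeps the
default suite fast while preserving every regime the algorithms must handle
(multiple wraps per tile, failing Strand tiles, residue pairs).

## Known limitations

* No masked/invalid-pixel support; rasters are assumed fully valid.
* Residues are detected and contained, never branch-cut; unwrapping a map
  with residues has no unique solution and the output commits to one.
* Only monomial bases are provided for MLSQU (the framework admits others).
* The unidirectional merger is inherently order-dependent; it is included as
  the fast/simple reference, not a recommendation.
* Reliability guards (ε) bound, but do not remove, the arbitrariness of
  processing order between exactly-tied junctions; determinism is guaranteed,
  optimality is not.
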