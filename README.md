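# tileunwrap

Modular tile-based two-dimensional phase unwrapping for quantitative phase
imaging (digital holography, interferometry, InSAR, MRI phase maps).

## The problem

Interferometric imaging measures phase only modulo 2π: the instrument returns
a *wrapped* phase map ϕ_w ∈ [−π, π) related to the physical phase ϕ_u by

    ϕ_w(x, y) = ϕ_u(x, y) − 2π·n(x, y),    n(x, y) ∈ ℤ.

Phase unwrapping recovers the integer jump field n(x, y). In one dimension
this is trivial when neighboring true-phase differences stay below π in
magnitude (the Itoh condition); in two dimensions, noise and *residues*
(2×2 pixel loops whose wrapped differences sum to ±2π) make it hard, and
naive path-following unwrappers propagate local failures across the image.

Tile-based unwrapping splits the problem: tessellate the map into rectangular
tiles, unwrap every tile independently, then *merge* the tiles by adding one
integer multiple of 2π per tile. Errors stay confined to tiles instead of
spreading along unwrapping paths.

## Algorithms

**Tile unwrappers**

* `strand` — Strand's constant-offset method: choose ρ from N_ρ equidistant
  candidates on [0, 2π) minimizing the roughness penalty
  Π = ⟨‖δ¹_x ϕ‖²⟩ + ⟨‖δ¹_y ϕ‖²⟩ of the re-wrapped tile W(ϕ_w − ρ) + ρ.
  Exact while the tile's phase range fits in one period.
* `mlsq` — model-based least-squares unwrapper (MLSQU): fit a monomial
  surface f = ρ + Σ c_l ν_l to the tile's wrapped gradient g = W(δ ϕ_w) by
  solving ‖A·c − g‖² → min with a reusable SVD of the system matrix A (one
  factorization per tile geometry), then unwrap the remainder W(ϕ_w − f) with
  Strand's offset search. Because |ϕ_u − f| < π implies
  ϕ_u = f + W(ϕ_w − f), tiles containing several wrap lines unwrap exactly —
  the case where a constant offset alone must fail.

**Tile mergers**

* `unidirectional` — column-wise pass; each tile is shifted by the 2π
  multiple nearest the pooled mean difference to its already-visited top and
  left junctions.
* `tsrncp` — reliability-guided merger: a tile's reliability is the inverse
  mean variance of its junction difference sets, a junction's reliability the
  product of its two tiles'; junctions are merged in descending reliability
  with group bookkeeping, so noisy or residue-crossed junctions are resolved
  last and cannot propagate errors.

**Baseline**: `pixel-srncp`, the classic pixel-granularity
sorting-by-reliability unwrapper (second-difference quality map), for
comparison.

## Worked example

```python
from tileunwrap import (MLSQU_TSRNCP, PIXEL_SRNCP, SyntheticSpec, add_noise,
                        count_residues, gaussian_ground_truth, make_wrapped,
                        rms_deviation)

truth = gaussian_ground_truth(SyntheticSpec(n=600))   # two-Gaussian surface
noisy = add_noise(truth, sigma=0.8, seed=7)           # heavy phase noise
wrapped = make_wrapped(noisy)
print("residues in wrapped input:", count_residues(wrapped).n_positive)
result = MLSQU_TSRNCP.run(wrapped)                    # MLSQU P=2, 20x20, tauSRNCP
print(f"MLSQU + tauSRNCP   RMS deviation: {rms_deviation(result, noisy):.4f} rad")
baseline = PIXEL_SRNCP.run(wrapped)
print(f"pixel SRNCP        RMS deviation: {rms_deviation(baseline, noisy):.4f} rad")
```

prints

```
residues in wrapped input: 3393
MLSQU + tauSRNCP   RMS deviation: 0.0977 rad
pixel SRNCP        RMS deviation: 0.3115 rad
```

At σ = 0.8 the noise violates the Itoh condition often enough to create
thousands of residues; the tile-based pipeline still reconstructs the surface
to a tenth of a radian RMS (errors confined to isolated pixels and tiles),
three times better than the pixel-based baseline, and the gap widens to an
order of magnitude at σ = 1.0.

The same pipelines are available from the shell:

```sh
tileunwrap simulate --output wrapped.tif --n 600 --sigma 0.5 --seed 1
tileunwrap unwrap --input wrapped.tif --output unwrapped.tif \
    --unwrapper mlsq --poly-degree 2 --n-rho 40 --tiles 20x20 --merger tsrncp
tileunwrap residues --input wrapped.tif
tileunwrap benchmark --out sweep.csv --summary-out summary.csv --reps 25
```

Phase maps are single-channel float32 TIFF (or headerless raw float32 with
`--width`/`--height`).

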