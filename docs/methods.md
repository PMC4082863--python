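# Methods

## Model

Nonlocal Means treats every voxel intensity X_i of a 3D image as a noisy
sample whose best restoration is a weighted mean of intensities elsewhere
in the image, weighted by *radiometric* similarity: how alike the local
intensity pattern (patch) around the candidate looks to the patch around
the voxel being restored. The classical formulation weights patch
differences with a Gaussian kernel of width `a`; the practical variant
implemented here replaces that smooth kernel by a **binary cut-off**: a
hard cubic patch boundary (the similarity box) and a hard cubic search
region (the search box), so the weight of candidate j for voxel i is

    w(i, j) = exp( − ‖B_j − B_i‖₂² / h² ),   j ∈ V_i,

with ‖B_j − B_i‖₂² the plain, unnormalised sum of squared intensity
differences over the aligned patch offsets (no division by patch size — a
deliberate fidelity choice; rescaling is absorbed into h), and the output
the w-weighted mean of the X_j. The self term j = i is kept with weight
exp(0) = 1, so the denominator is never zero. The classical Gaussian-kernel
form is retained in `reference_oracle.nlm_gaussian`, with the infinite
offset sum truncated to a cube of radius ⌈2a⌉ by default, as documentation
and as an independent cross-check of the weight machinery; the kernel
dimensionality exponent in (2π)^{n/2} is taken as n = 3.

Assumptions: noise is approximately i.i.d. across voxels and the image is
self-similar (each patch recurs elsewhere in the search region). Under
those assumptions NLM preserves edges and flat zones and maps white noise
to (approximately) white residuals — both properties are asserted by the
test suite on synthetic volumes.

## Parameters

| parameter | meaning | default / constraint |
|---|---|---|
| `search_edge` | odd edge of the search box V_i (voxels); cardinality edge³ | required; ≥ `sim_edge`. 7–11 is typical for MRI |
| `sim_edge` | odd edge of the similarity box (patch) | required; 3 or 5 typical |
| `h` | weight decay scale (intensity units) | either given directly… |
| `beta`, `sigma` | dimensionless tuning ≈ 1 and noise s.d. | …or h² = 2·β·σ²·search_edge³ |
| `include_self` | keep the j = i term | true |
| pad mode | boundary handling | reflect (edge/zero available) |

The h² rule scales the filter strength with the *search-box cardinality*,
so enlarging the search window also smooths more aggressively at fixed
(β, σ). This is implemented exactly as stated; users who prefer the more
common cardinality-independent tuning can pass `h` directly.

Window sizes are specified by their odd edge length because that is how
practitioners quote them ("11³, 3³"); a strict-inequality radius-M
definition of the boxes is representable as edge = 2M − 1.

## Boundary handling

The source formulation is silent on boundaries. This package reflect-pads
by `search_radius + sim_radius` (mirroring without repeating the edge
sample) before filtering, so every patch distance is a sum over the same
patch cardinality everywhere in the volume — the dominant convention in
published NLM implementations. Edge and zero padding are selectable;
reflect requires extent ≥ 2 along each padded axis.

## Numerical choices

* All accumulation is float64 regardless of storage dtype; output is cast
  back to the input dtype.
* Search-box terms are accumulated in fixed lexicographic offset order.
* Patch distances are computed per search offset as sliding-cube sums of
  the squared shifted difference, evaluated separably (axis 0, then 1,
  then 2) by direct correlation. The value at an interior position is
  independent of the surrounding array extent, which is what makes the
  chunked, column-traversal and voxel-traversal paths produce
  **bit-identical** results rather than merely close ones. The per-voxel
  helper `patch_sqdist` uses the same summation order.
* The literal nested-loop oracle accumulates its patch distance in a
  scalar triple loop — a different association order — so oracle agreement
  is asserted at 1e-10 relative, not bitwise (measured: ~1e-13).
* Degenerate settings: `search_edge = 1` is the identity map; constant
  volumes are exact fixed points; `h → 0` with the self term approaches
  the identity on volumes with all-distinct patches.

## Chunking and execution

Filtering keeps an input and an output copy resident, so a capacity of M
bytes admits reading at most ⌊M/2⌋ / (slice bytes) z-slices at a time.
Chunks are greedily maximal: each takes the largest core its read budget
allows after reserving halos of `search_radius + sim_radius` slices on
interior sides (the minimal halo for which a chunk's filtered core equals
the unsplit result; outer boundaries use the global padding, which the
read slab reproduces). Cores partition [0, L3); gather drops halos and
concatenates. Shrinking the budget increases the chunk count but never
changes the gathered output.

When G > 1 workers are requested, the chunk count is rounded up to a
multiple of G (near-equal cores) so a round-robin deal gives every worker
⌈N/G⌉ or ⌊N/G⌋ chunks; any disjoint assignment would satisfy the output
contract, round-robin is simply deterministic. Workers are threads running
the NumPy/SciPy kernels (which release the GIL); results are placed by
chunk index, so completion order cannot affect the output. The
`deterministic` flag on `ExecConfig` names the summation contract: this
CPU implementation always uses fixed-order accumulation, so both the
strict (1e-10 relative) and the loose (1e-6 of dynamic range) consistency
bounds hold; the loose bound is the portable contract a reordering
(e.g. GPU) backend would still meet.

The two traversal modes reproduce the two classic work mappings — one unit
per (x, y) column sweeping z versus one unit per voxel — as genuinely
different execution paths (per-column blocks vs one whole-volume sweep)
that perform identical per-voxel arithmetic.

## Synthetic data

The generator emulates the two validation scenarios: (i) an MRI-like
piecewise-constant phantom — nested ellipsoids with three tissue
intensities (60/120/200 on a 0–255 scale, zero background) on a 64×64×48
grid — standing in for a real T1 brain volume, with Gaussian or Rician
(`sqrt((X+ε₁)² + ε₂²)`) noise; and (ii) pure standard-normal volumes, the
classic synthetic benchmark input. Defaults: σ = 20 on the 0–255 phantom
scale for efficacy checks; β = 1. What it does **not** model: MRI bias
fields, partial-volume effects, spatially correlated noise, anisotropic
voxels, or realistic video content. Passing tests therefore demonstrate
algorithmic correctness and calibration, not clinical denoising quality on
real scanner data.

All randomness flows through NumPy's PCG64 (`default_rng(seed)`), making
every fixture bit-reproducible per seed and platform-stable.

## Problem sizes

Verification runs use volumes between 6³ and 16×16×40 against the
nested-loop oracle and for the invariance grids, 32³ for whiteness and
noise calibration, and the full 64×64×48 phantom for efficacy — sizes at
which the whole suite completes in well under a minute on one CPU while
still exercising multi-chunk plans (N up to 7) and all 12 mode × worker ×
budget configurations.

## Known limitations

* No fast approximations (integral images, FFT, locally constant weights):
  the filter is exact by design; cost grows as |V_i|·|B_i| per voxel.
* Splitting is z-only; a volume whose single slice exceeds the usable
  budget cannot be chunked.
* No σ estimation: the caller supplies σ (or h) explicitly.
* Rician-bias-corrected error measures and perceptual metrics (SSIM) are
  out of scope; `compare_volumes` reports MSE/PSNR/max-difference only.
* 4D (multichannel or time-resolved volumetric) data is not supported;
  video enters as a single 3D stack.
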