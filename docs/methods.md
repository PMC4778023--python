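# Methods

This document records the mathematical model, the numerical
conventions, and the known behaviors of the implementation.  Units are
cm and cm⁻¹ throughout.

## Forward model

Continuous-wave photon transport in a semi-infinite homogeneous medium
is modelled with the diffusion approximation.  With background
absorption μa and reduced scattering μs′:

* diffusion coefficient `D = 1 / (3 (μa + μs′))`
* effective attenuation `μ_eff = sqrt(μa / D)`
* infinite-medium Green's function `G∞(r) = exp(−μ_eff r) / (4π D r)`

The half-space solution uses the image-source construction about the
extrapolated boundary `z = −z_b`, `z_b = 2 A D` with boundary constant
`A = 2.0` by default:

```
G(r1, r2) = G∞(|r1 − r2|) − G∞(|r1 − r2*|)
```

where `r2*` mirrors `r2` across `z = −z_b`.  Sources are buried at the
effective depth `z0 = 1/(μa + μs′)`; detectors sit on the surface.
Defaults: μa = 0.03, μs′ = 10 (1 % intralipid-like), giving
D ≈ 0.03324 cm, μ_eff ≈ 0.9501 cm⁻¹.

The Rytov-normalized absorption sensitivity of voxel k (center r_k,
volume h³) in measurement (detector d, source s) is

```
A[(d,s), k] = (h³ / D) · G(r_s, r_k) G(r_k, r_d) / G(r_s, r_d)
```

so `y = A x` with `x` the per-voxel Δμa and `y` the positive Rytov
perturbation −ln(Φ/Φ₀).  All entries are nonnegative.  Voxel–optode
distances below h/2 are clamped to h/2.  Bifurcated layouts exclude the
degenerate co-located (d = s) pairs by default (SD-I: 600 rows; a flag
restores the full 625).

**Near-surface sensitivity.**  The extrapolated boundary pins the
fluence to zero just above the surface, so per-layer sensitivity does
*not* decay monotonically from layer 1: the mean column norm peaks at
the second layer, and the per-layer maximum singular value θ(A_i) peaks
around layer 3–4 (SD-I), before the diffuse exponential decay takes
over.  Depth-compensation weights are therefore slightly
non-monotonic in the top few layers; everything below the peak behaves
as expected (strictly decaying θ, strictly increasing weight).

## Grids, phantoms, voxelization

Grids are layer-major (all voxels of the shallowest layer first), so
per-depth-layer blocks of `A` occupy contiguous column ranges.  The
standard SD volume is 4×4×2.5 cm at h = 0.2 (20×20×13 = 5200 voxels);
the transrectal volume is 6×4×2.5 cm (30×20×13).

Inclusion membership is decided by the voxel **center** (no
partial-volume weighting).  Cylinder axial extent is half-open,
`[c − L/2, c + L/2)`.  Consequences worth knowing:

* the benchmark disk (1.1 cm diameter × 0.4 cm thick at 1.5 cm depth)
  rasterizes to exactly 48 voxels on the two layers with centers at
  z = 1.3 and 1.5 cm, so the **voxelized truth centroid sits at
  1.40 cm**, not 1.50 cm — reconstruction depths should be compared
  against 1.40;
* very small objects can vanish at coarse resolution: the 0.2 cm "Cs"
  cylinder contains no voxel center at h = 0.2 (nearest center is
  0.14 cm off-axis) and only appears for h ≲ 0.1;
* voxelized volumes converge to the analytic shape volume within 2 % by
  h = 0.05.

Measurements are simulated as `y = A x + e` with e i.i.d. Gaussian,
σ = noise_level × RMS(A x); the realized σ² is carried with the data
for the discrepancy-principle selector.  This is a self-consistent
(same-operator) simulation: the reconstruction sees the exact forward
model that generated the data.  See "Inverse-crime caveats" below.

## Solvers

**SALSA (ADMM).**  `min ‖Ax − y‖² + λ‖x‖₁ (x ≥ 0 optional)` with
splitting x = z: the x-update solves `(AᵀA + μI)x = Aᵀy + μ(z − u)`
through a one-time Cholesky factorization (Woodbury form
`(AAᵀ + μI)⁻¹` when underdetermined), the z-update is (one-sided)
soft-thresholding at λ/(2μ).  Zero initialization.  Iterations stop
when the **relative objective change drops below tol = 1e-5** (cap
2000), with one guard: the objective is a function of the sparse
iterate z alone, and z can sit bit-identical across an iteration (e.g.
an all-zero early iterate whose threshold has not yet been crossed)
while the splitting variables are still moving.  Such a frozen iterate
only counts as converged once the split has closed
(‖x − z‖ ≤ tol·max(1, ‖z‖)); without the guard the solver can stop at
iteration 1 with z = 0 on instances whose minimizer is nonzero.  The
sparse iterate z is returned, so zeros and nonnegativity are exact.

The early-stopping tolerance is part of the method, not a shortcut: on
the DOT systems here the exact ℓ1 minimizer is far spikier than the
tol = 1e-5 iterate (FWHM volume ratio collapses from ≈0.7 to ≈0.06 if
the solver is run to convergence).  Results also retain a mild
dependence on the ADMM penalty μ (default 1.0): on the SD-I disk
benchmark the median volume ratio moves from ≈0.67 (μ = 0.3) through
≈0.71 (μ = 1) to ≈0.92 (μ = 10).  μ is configurable but the default is
fixed at 1.0; an adaptive residual-balancing variant was evaluated and
rejected (it degraded the volume ratio).

**Tikhonov baseline.**  Closed form `x = Aᵀ(AAᵀ + γI)⁻¹y`, with γ
chosen by log-domain bisection so the mean squared residual matches σ².

**λ selection.**  The MAP view (Gaussian noise, Laplacian prior) maps a
sparsity parameter α to λ = 2σ²α.  The default grid is 12 log-spaced α
spanning 4 decades centered on 1/(expected Δμa × expected volume)
= 1/(0.2 × 0.4).  For each λ the ℓ1 problem is solved on the reduced
system and the winner is the λ whose per-channel mean squared residual
`‖y − Ax̂‖²/mq` is closest to σ² (ties toward smaller λ).  On the SD-I
benchmark the selected discrepancy lands within ~10 % of σ².

## The two-step pipeline

Order of operations in `run_dro_dot`:

1. depth-compensate `A` (optional, on by default);
2. group columns at τ (default 0.96, Pearson correlation; grouping is
   provably invariant to the per-column scaling of step 1);
3. select λ on the reduced system;
4. Step 1: nonnegative ℓ1 solve on the reduced system; groups with
   coefficient > ε·max (ε = 1e-3) are nonzero; their members form I′;
5. Step 2: nonnegative ℓ1 solve restricted to the I′ columns (same λ by
   default), embedded back into the grid;
6. inverse-weight correction `x_k ← w_layer(k) · x_k`, the exact
   algebraic inverse of the column scaling (so `Ã x̂ = A x̃`
   identically).

**Group representative.**  The reduced matrix uses the **group mean**
column by default.  The cheaper seed-column ("first") representative is
available behind a flag but mis-scales groups whose members are
correlated yet differ in magnitude: on the SD-I disk benchmark the
data-space approximation error of the reduced basis is 2.2 % with the
mean representative versus 20 % with the seed column, at the same
80.7 % dimensionality reduction.

**Depth compensation.**  θ_i is the maximum singular value of layer
block A_i and columns of layer i are scaled by `w_i = (θ_last/θ_i)^p`
(p = 1), boosting deep layers.  The correction in step 6 restores
quantification (noiseless recovery ≈ 88 %, see below).

**Approximation-error / τ selection.**  `select_tau` returns the
smallest grid threshold whose reduced-basis error stays below 5 %.  The
error is *not* strictly monotone in τ (the greedy partition changes
discontinuously); on SD-I the 5 % budget is met from τ = 0.93 and at
the default τ = 0.96 the error is 2.2 %.

## Quality metrics

FWHM segmentation thresholds at half the **global** maximum;
connected components use 26-connectivity.  Against the voxelized truth:

* AR — FWHM area over true area on the slice through the truth
  centroid (default);
* VR — FWHM volume over true volume;
* CR — mean reconstruction inside the true boundary over the mean over
  all outside voxels (+inf when the background is exactly zero);
* centroid depth — intensity-weighted centroid of the FWHM mask;
* recovery % — 100 × mean(reconstruction over the true region)/Δμa.

## Benchmark behavior and inverse-crime caveats

Representative figures on the SD-I disk benchmark (2 % noise, defaults,
10 seeds) produced by `scripts/acceptance.py`:

| quantity | value |
| --- | --- |
| dimensionality reduction at τ = 0.96 | 80.7 % |
| reduced-basis approximation error | 2.2 % |
| median volume ratio | ≈ 0.71 |
| CR fold-improvement over Tikhonov | ≈ 20× |
| centroid depth, with depth compensation | ≈ 1.41 cm |
| centroid depth, without depth compensation | ≈ 1.40 cm |
| noiseless quantification recovery | 87.8 % |

Three caveats for anyone comparing these to laboratory results:

1. **Volume ratio.**  The tol = 1e-5 iterate at μ = 1 under-fills the
   FWHM volume (VR ≈ 0.7 rather than ≈ 1).  VR is the single most
   μ-sensitive metric; localization (centroid within one voxel
   laterally) and contrast (CR in the hundreds) are robust.
2. **Depth bias without compensation.**  In a same-operator synthetic
   experiment the nonnegative ℓ1 solve localizes the true depth even
   *without* depth compensation (1.40 cm here, matching the voxelized
   truth centroid): the shallow-bias pathology familiar from real
   measurements requires model mismatch that a self-consistent
   simulation does not contain.  Depth compensation is still exercised
   end-to-end (it changes the support and quantification path), but
   this surrogate cannot demonstrate the shallow-bias failure mode.
   Tikhonov, by contrast, does show a mild shallow bias (≈ 1.3 cm).
3. **Quantification.**  Noiseless recovery saturates at ≈ 88 % because
   Step 1 keeps 43 of the 48 true voxels: the disk's outermost rim
   voxels belong to groups the reduced nonnegative solve zeroes even in
   the λ → 0 limit.  Recovery inside the recovered support is ≈ 100 %.

**Two-object resolution** is probed in the noise-free, small-λ limit
(the regime in which a resolution limit is well defined): the
transrectal probe separates two 0.85 cm cylinders with a 0.65 cm
surface gap into two FWHM components, while a 0.25 cm-gap variant
merges into one.  At 2 % noise with discrepancy-selected λ the outcome
is seed-dependent (the inter-object valley hovers around half max).
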