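# Methods

## Problem and model

The package reconstructs a 2D attenuation image from few-view fan-beam
projections.  The discrete forward model is

    g = A f + e,

where `f ∈ R^N` collects the pixel values of an n×n grid (N = n²),
`g ∈ R^M` the measurements (M = views × detector elements), and
`A = (a_mn)` the system matrix.  Each `a_mn` is the **interaction area**
(cm²) between pixel n's square and the finite-width beam of measurement m —
the wedge spanned by the two rays from the X-ray source to the endpoints of
one detector element.  Areas are exact convex polygon-clipping results
(shapely), with entries below 10⁻¹² cm² dropped.  Beams are non-overlapping
and tile the fan.

Geometry of the reference study: source on a circle of radius 57.0 cm, flat
equispatial virtual detector of length 20.0 cm through the rotation axis
(perpendicular to the source direction), 128 elements, views equiangular
over a full scan; image field 20 cm × 20 cm (pixel 0.15625 cm at n = 128),
compact support radius 10 cm.  For view angle θ the source sits at
(−R sin θ, R cos θ) and the detector axis is (cos θ, sin θ); any consistent
convention would do, this one is frozen for reproducibility.

## Reconstruction schemes

Classical SART updates

    f ← f + λ · Λ⁺ᴺ Aᵀ Λᴹ⁺ (g − A f),     0 < λ < 2,

with Λᴹ⁺ = diag(1/a_m+) and Λ⁺ᴺ = diag(1/a_+n) the row/column-sum
normalizers.  Measurements whose beam misses the grid (a_m+ = 0) are
excluded; pixels no beam touches (a_+n = 0) stay frozen (their diagonal
entries are set to zero).

The sparsity-constrained scheme replaces the fixed relaxation by an
adaptive projected-gradient step.  With r̃ the normalized residual above,
one iteration is

    f ← P_R( f + α β r̃ ),     β = ‖r̃‖² / ‖A r̃‖²,

where `P_R` projects the iterate's coefficients in an invertible
sparsifying basis onto the ℓp ball of radius R (1 ≤ p ≤ 2), and α rescales
the doubly-normalized residual back to the magnitude of a plain gradient:

    α = α₀ · sqrt( max_n (AᵀA·1)_n / max_n (Λ⁺ᴺAᵀΛᴹ⁺Λᴹ⁺AΛ⁺ᴺ·1)_n ).

α₀ defaults to 2.0; if a run diverges the documented protocol is to reduce
α₀ until it converges (the solver raises a `DivergenceError` with that
advice when the error exceeds 10× its initial value or turns non-finite).
The norm-bound estimate is meaningful for tomographic matrices, whose row
and column sums are fairly uniform; for unstructured (e.g. random sensing)
matrices it can be far too aggressive, and the α₀-reduction protocol is
then essential (the sparse-recovery test walks the fixed ladder
α₀ ∈ {2, 1, 0.5}).

Scheme labels used throughout:

| scheme | projection | weighting | α |
|--------|------------|-----------|---|
| A      | fixed radius R* | SART diagonals | estimated |
| B      | none            | SART diagonals | estimated |
| C      | growing radius R^k | SART diagonals | estimated |
| AD/BD/CD | as A/B/C     | identity (r̃ = Aᵀ(g−Af)) | 1 |

Scheme C uses the interior schedule
`R^k = (0.4 + 0.6 (k/max_iter)^0.05) R*`, which reaches R* exactly at the
iteration budget; it stabilizes strongly underdetermined cases (25 or 35
views) where committing to the full radius early is harmful.

R* is the ℓp radius of the ground-truth object's transform coefficients —
available in simulation, approximated in practice.  Iterations start at
f⁰ = 0 (so the initial relative error is 100%) and stop when the relative
reconstruction error

    E^k = 100 · ‖f^k − f*‖₂ / ‖f*‖₂   (percent, f* the true phantom)

drops below 0.1% or the budget (default 20000) is exhausted.

### Nonnegativity

Attenuation coefficients are physically nonnegative, and clamping negatives
each iteration is standard algebraic-reconstruction practice.  It is also
quantitatively essential here: without it the unregularized scheme's limit
point is the minimum-seminorm solution, which for the 55-view system lies
at ≈ 25% RRE, far above the ≈ 9% plateau the regularized-vs-unregularized
comparison is calibrated against.  The clamp is applied at the end of each
iteration, after the ball projection; the solver exposes it as
`SolverConfig.nonneg` (default True).  Because the clamp acts in the image
domain it can move the iterate marginally outside the ℓp ball; the strict
ball-membership invariant therefore holds exactly for `nonneg=False` runs
and only up to the clamp perturbation otherwise.

## Sparsifying transform and shrinkage

The concrete basis is the full-depth separable orthonormal 2D Haar
decomposition (unit-norm filters, `pywt` periodization mode), requiring a
dyadic grid.  Orthonormality gives Parseval's identity exactly, so ℓp radii
measured on coefficients match the analysis model; full depth maximizes
sparsity (the 128×128 phantom keeps ~1700 of 16384 coefficients).  The
interface is an abstract forward/inverse pair, so any invertible basis can
be substituted.

Generalized shrinkage: `F_{w,p}(x) = x + w p sgn(x)|x|^{p−1}` is strictly
increasing for p > 1, and `S_{w,p} = F⁻¹` is applied componentwise.  Closed
forms: soft threshold at p = 1, linear scaling at p = 2, and an explicit
root at p = 3/2 (implemented in a cancellation-free form).  Other p use
safeguarded Newton iteration bracketed in [0, |y|], to
|F(S(y)) − y| ≤ 10⁻¹⁰·max(1, |y|).

Projection onto the ℓp ball of radius R finds the adaptive threshold μ by
bisection on [0, max|ϕ|] (doubling the bracket for p > 1 if needed): the
shrunk radius is continuous and nonincreasing in μ, so bisection converges
globally; tolerance 10⁻⁸·max(1, R), cap 200 steps.  A vector already inside
the ball is returned unchanged with μ = 0; a zero-radius target returns the
zero vector with μ = max|ϕ|.

## Synthetic data

The test object is the canonical ten-ellipse modified (high-contrast)
Shepp-Logan phantom, point-sampled at pixel centers on the 20 cm field — no
anti-aliasing, so pixels outside every ellipse are exactly zero and the
Haar representation stays extremely sparse.  The nonzero-coefficient count
is sensitive at the level of a few counts to sub-pixel rasterization
conventions (grid offset/scaling, boundary handling); this package's frozen
convention yields 1711 coefficients above 10⁻⁸ at 128×128.

Measurement noise is additive i.i.d. Gaussian with σ = level · max(g)
(level 0.001 for "0.1% noise"), seeded and reproducible.  Real CT noise is
Poisson-dominated, object-dependent and correlated by detector physics —
none of which is modeled, so noisy-run results demonstrate stability of the
iteration under small perturbations, not clinical noise performance.  The
simulation also omits scatter, beam hardening (the model is monochromatic
and linear) and detector blur; passing tests validate the algorithmic
claims on the model's own terms only.

## Study harness and problem sizes

`run_experiment` reproduces the study grid: view counts (25, 35, 45, 55) ×
schemes, optional 0.1% noise, per-run convergence logs, result tables and
windowed ([0, 0.5]) image mosaics.  Full scale is 128×128 with a
20000-iteration budget (minutes per run); the package's reduced
configuration — 64×64 grid, 64 detectors, 2000 iterations, preserving the
measurement/unknown ratio — reproduces all qualitative orderings in
seconds per run and is what the CLI `--quick` mode and the scheme-ordering
tests use.  The sparse-recovery check uses a 32×32 object with 20 nonzero
Haar coefficients sensed by 160 fixed-degree binary random measurements.

## Numerical choices and degenerate inputs

- System-matrix entries below 10⁻¹² cm² are dropped; beams missing the grid
  and untouched pixels are excluded from the SART diagonals.
- The candidate-pixel prefilter (signed distance to the wedge's bounding
  rays, half-diagonal margin) is conservative: clipping decides membership.
- β is undefined for a zero residual — the solver stops (data consistent);
  `A r̃ = 0` with r̃ ≠ 0 raises a stagnation error.
- Ties in the ball projection (several |ϕ| = μ) need no special casing:
  soft thresholding is continuous there.
- Divergence detection (error > 10× initial, or non-finite) is a fail-fast
  implementation choice with actionable advice (reduce α₀).

## Known limitations

- Iteration counts and convergence-rate comparisons are projector-sensitive;
  only error levels and scheme orderings are stable surfaces.
- The Haar nonzero count depends on the rasterization convention at the
  ±few-count level (see above).
- 2D fan-beam only; no cone-beam/helical geometries, no ordered-subset or
  multiscale acceleration, no TV-type regularization.
- The α estimate assumes tomographic-like row/column sums; use the α₀
  reduction protocol (or the direct schemes) for generic matrices.
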