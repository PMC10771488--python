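# Methods

## Linear mixture model and solvers

Each pixel's emission spectrum is modeled as `S = s̄̄·k + n` with `s̄̄` the
m × l matrix of max-normalized elementary spectra and `k ≥ 0` the physical
abundances. Two estimators solve `min_k ‖S − s̄̄·k‖₂²` per pixel:

- **UCLS.** The closed form `k = (s̄̄ᵀs̄̄)⁻¹s̄̄ᵀS` is evaluated via
  `numpy.linalg.lstsq` (QR/SVD factorization), never the explicit inverse —
  the formula is the contract, the factorization the numeric path.
- **NNLS.** A Lawson–Hanson active-set iteration implemented in-package.
  Exit requires the KKT conditions within `1e-10 · ‖s̄̄ᵀS‖∞` (configurable
  via `kkt_tol_factor`); the iteration cap is `3·l·m` least-squares solves
  (`max_iter_factor`), standard active-set practice — exceeding it raises a
  convergence error rather than returning a doubtful answer. Tests
  cross-check the solver against `scipy.optimize.nnls` and against
  exhaustive active-set enumeration for l ≤ 3.

Pixels are independent and `unmix_stack` is an explicit per-pixel loop, so
whole-stack results are identical to single-vector calls by construction.
A rank-deficient endmember matrix (smallest singular value ≤ 1e-8 of the
largest, or more endmembers than channels) is refused at construction:
abundances are only interpretable when the design is identifiable, so no
minimum-norm fallback is offered. The non-negativity constrained mode is the
default everywhere; the unconstrained mode exists for speed and for
quantifying what the constraint buys (`compare_constraints` reports
per-endmember abundance standard deviations in a uniform region for both
modes; standard deviations at float-precision level are floored to zero so
noiseless input reports an undefined ratio rather than a ratio of
rounding errors).

## Determination of elementary spectra

1. **Substrate.** ROI-mean spectra of substrate-only regions are averaged
   with equal weight per ROI (not per pixel — large ROIs must not dominate),
   then max-normalized. Fewer than five ROIs triggers a warning.
2. **Decomposition.** A composite ROI spectrum is fit as
   `a₀·substrate + Σⱼ aⱼ·G(λ; μⱼ, σⱼ)` with all coefficients nonnegative
   (including `a₀`: emission cannot be negative). The fit uses variable
   projection: the outer nonlinear problem (`scipy.optimize.least_squares`,
   bounded) runs over the Gaussian shapes only, and for any shapes the
   amplitudes are the inner NNLS solution — more robust than a joint fit.
   Peak positions are seeded at the largest residual maxima of the
   substrate-only fit, widths at 20 nm; three jittered restarts (fixed RNG)
   guard against bad seeds, making the fit deterministic. Gaussians are
   added one at a time up to `max_gaussians` (default 3) and an extra
   component is kept only while it improves the residual norm by more than
   5% relative (`improvement_tol`).
3. **Candidates.** The substrate-free candidate is the composite minus the
   fitted substrate part, clipped at zero (negative channels are noise;
   clipping keeps candidates valid spectra). Peak = argmax channel; FWHM by
   linear interpolation of the half-maximum crossings, falling back to the
   window edge when a flank is truncated, and never below one channel width.
4. **Grouping.** Single-linkage: two candidates link iff peaks agree within
   `peak_tol_nm` (default 10 nm) *and* FWHMs within `width_tol_frac`
   (default 0.25) of the pair mean. The criteria in the source workflow are
   qualitative ("similar breadth and emission maximum"); these defaults are
   exposed and logged. Groups are sorted by mean peak, so output is
   order-independent.
5. **Finalization.** Per-group mean, max-normalized, substrate prepended;
   matrix construction performs the rank check and names the most collinear
   pair on failure.

**SHG rule.** The SHG endmember is only physical at excitations where the
half-wavelength line is generated (default: 920 nm). At other excitations
its column is zeroed and excluded from the design matrix and the rank check;
its abundance is reported as exactly 0. Zeroing is idempotent.

## Synthetic scenes

The generator emulates the three fossil settings with known ground truth:

| scenario | endmembers (peak σ in nm) | geometry |
|---|---|---|
| `matrix_only` | matrix 640/10 | matrix everywhere |
| `leaf_on_matrix` | matrix 640/10, leaf 630/30 | elliptical leaf patch |
| `leaf_three_layer` | matrix 640/10, exterior 620/30, interior 635/30 | nested rim + core |
| `amber_inclusion` | amber μ(exc), lignin 560/30, chl/tannins 650/30 | two blobs with an overlap zone |
| `silicified_wood` | S550/30, S570/30, ChMi 650/30, SHG exc/2 (width 5) | cellular lattice, sparse spots |

Peak positions follow the materials they emulate; the *widths* are not
published numbers, so the two breadth classes (sharp σ = 10 nm, broad
σ = 30 nm) are package constants chosen to reproduce the spectral overlap
that motivates the ANC. The amber emission shifts linearly from
μ = 490 → 560 nm and narrows σ = 45 → 25 nm as excitation rises 760 → 960 nm
(monotone by construction; the published behavior is qualitative —
"red-shifts and narrows"). The default axis is 200 channels × 1 nm over
460–660 nm, the one 200 nm window containing every generated peak; a
40-channel × 5 nm preset covers the same window (the coarse-acquisition
mode). The excitation series runs 760–960 nm in 40 nm steps: six scans per
field of view.

Abundance fields carry a smooth seeded texture (Gaussian-filtered noise
scaled to 0.7–1.3) emulating thickness and preservation variability; this
also makes recovery correlations well defined for single-material scenes.
Each scene ships `reference_rois` — substrate-only patches and inclusion
regions placed analytically in the geometry — used by the tests and the CLI.

**Detector model.** Expected counts are `exposure_scale · (s̄̄·k_true)`
(default 10⁴, a well-exposed acquisition); noise is Poisson on the expected
counts plus additive Gaussian read noise (sd 3 counts), clipped at zero.
The EMCCD excess-noise factor is deliberately omitted: it rescales variance
without changing any of the comparisons made here. All randomness derives
from one explicit seed (geometry and noise use separate spawned streams);
no global RNG state is touched.

What passing tests do *not* show about real data: real substrates are not
single Gaussians, real noise includes excess and structured components,
real elementary spectra are unknown rather than generated — so recovery
numbers here validate the algorithms, not instrument performance.

## Numerical choices and degenerate inputs

- Band intervals are closed on both ends (600–650 nm on a 1 nm axis = 51
  channels). A pixel belongs to an ROI iff its center lies inside the
  polygon, boundary inclusive — deterministic and testable against a
  brute-force rasterizer.
- Stitching averages overlapping pixels arithmetically (no published
  policy); uncovered canvas pixels are NaN with an explicit `missing` mask,
  never zero.
- Negative counts on read are rejected, not clipped: they indicate an
  upstream dark-correction problem.
- An all-zero composite, an empty ROI, an empty band, and an over-determined
  endmember set each raise a specific typed error.

## Problem sizes

Tests and the acceptance script run scenes of 16×16 to 64×64 pixels on the
200-channel axis — large enough for stable statistics (≥ 841 pixels per
uniform-region comparison, ≥ 2304 per recovery correlation) while keeping
the full suite under a minute. The data model accepts arbitrary dimensions;
440×300 is merely the conventional full-FOV size.

## Known limitations

- The per-pixel NNLS loop is pure Python/NumPy; a 440×300 stack takes on
  the order of a minute. Batching pixels through one factorization would be
  faster but is deliberately avoided where it could diverge bitwise from
  the per-pixel contract.
- Gaussian decomposition assumes bands are approximately Gaussian;
  strongly asymmetric emissions will spread over several components.
- The excitation-profile table treats endmember matrices per excitation as
  given; it does not itself re-extract endmembers per excitation.
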