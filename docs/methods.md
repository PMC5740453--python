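# Methods

This note documents the model, the numerical choices and the limits of the
synthetic-data based validation implemented in `saxstt`.

## Model and assumptions

Each voxel carries a reciprocal-space map `R(q̂) = A(q̂)²` with amplitude
`A = Σ a_lm Y_lm(θ', φ')` in real, orthonormal spherical harmonics (no
Condon–Shortley phase — only internal consistency matters because the
coefficients are free parameters).  The zenith of the local coordinates is the
voxel's preferred-orientation unit vector `u`, parameterized by two
unconstrained angles; `u → −u` leaves every even-degree map invariant, so
reported orientations are canonicalized to the hemisphere `u_z > 0` (ties
broken on `u_y`, then `u_x`).  The azimuth `φ'` is measured from the
projection of the object z axis onto the plane normal to `u`, with a
deterministic, logged fallback to the x axis when `u` is within `1e-6` of
`±z`; the azimuth origin only matters for bases with `m ≠ 0` orders.

Assumptions inherited from the acquisition model: single (kinematic)
scattering; zero-order Ewald expansion, so one projection probes the plane
`q_z = 0` in lab coordinates and each detector segment probes one constant
direction across the raster; scan step equal to voxel size; absorption
handled by dividing measured intensities by the transmitted intensity;
projections perfectly aligned (the synthetic generator produces aligned data
by construction — registration of real data is out of scope).

## Forward projection and adjoint

Rays are cast along the lab z axis through the rotated object; each sample
(one per voxel pitch) gathers from the voxel grid with trilinear weights,
which reduce to the classical bilinear in-plane weights for any single-axis
rotation.  The per-orientation ray transform is materialized as a sparse
matrix (cached per orientation and per grid), so the adjoint used by the
gradients is the exact transpose — certified by a dot-product identity at
1e-10.  Projected images are convolved per segment with the separable 3×3
pyramid kernel `[1,2,1]⊗[1,2,1]/16` (unit sum, zero-padded borders), which
emulates up/down-sampling and suppresses grid artifacts.

A consequence worth documenting: this kernel's frequency response has an
exact zero at the transverse Nyquist frequency, so intensity patterns
alternating at the voxel scale are almost invisible to the data.  These
quasi-null modes are the dominant ill-conditioning of the inverse problem and
motivate both the sieve regularization (below) and the smoothed
initialization of the schedule.

## Objective

Default data term: `ε = Σ W (√Î − √(I/T))²` — a first-order approximation to
the Poisson maximum-likelihood metric for counting noise; a plain
intensity-residual mode `Σ W (Î − I)²` is available as a config switch (the
amplitude mode recovered orientations markedly better in our phantom
studies).  The misfit is summed, not averaged, so the regularization weights
scale with problem size; the L-curve procedure absorbs that scale.  Masked-in
pixels with non-positive transmission are masked out and counted.  `√0`
guards use a `1e-30` floor, consistently in value and gradient.

Regularizers:

* **Sieve (coefficient) smoothing** — the coefficient gradients are convolved
  with a unit-sum 3³ (or 5³) Hamming window each iteration.  The 3³ window's
  DFT is strictly positive, so smoothing preserves stationary points while
  strongly damping steps along the kernel-nulled modes; the optimization
  solves for low and middle spatial frequencies first.  Angle gradients are
  never smoothed: a direction held by two coupled angles with a sign
  ambiguity does not convolve meaningfully.
* **Neighbor-orientation penalty** — `R_u = Σ (1 − |u·u'|)` over 6-connected
  forward neighbor pairs inside the support, weighted by `μ`.  The absolute
  value makes the penalty compatible with the `u → −u` ambiguity; the
  subgradient at exactly orthogonal neighbors is taken as 0 (a measure-zero
  event).
* **Optional coefficient bounds** — a once-differentiable quadratic hinge
  weighted by `λ`, off by default.

## Gradients

All gradients are analytic: residual → kernel adjoint (the kernel is
symmetric, so its adjoint is the same convolution) → ray-transform transpose
→ the factor `2A` of the squared amplitude → basis values and their
derivatives in `(t = cos θ', φ')` → the zenith angles through the local
frame.  Zonal bases use fused kernels with stable Legendre recurrences
(`P'_l = P'_{l−2} + (2l−1)P_{l−1}`); general orders differentiate the local
frame explicitly.  Gradients outside the binary support mask are zeroed.
Instead of transcribing the closed-form expressions, correctness is certified
against a central finite-difference oracle: relative error below 1e-4 (in
practice ~1e-7) across all parameter blocks, both residual modes, and both
regularizers — this certification is part of the test suite and of
`scripts/acceptance.py`.

## Optimization schedule

Polak–Ribière nonlinear CG (restart to steepest descent on loss of descent or
every `restart` iterations) with an Armijo backtracking line search refined
by one quadratic interpolation, which makes the search near-exact on locally
quadratic objectives.  The four steps:

1. **Isotropic** — `a00` only, against azimuthally averaged data.  Because
   φ-averaging scales each zonal degree by `P_l(0) ≠ 0` rather than removing
   it, this fit is *inconsistent* for anisotropic samples, and the
   inconsistency leaks into the weakly determined modes if over-converged;
   the default therefore stops early (40 iterations).  Step 1 exists to
   provide the support mask and a starting scale, not a quantitative map.
2. **Support** — threshold at 5% of the maximum `a00` (optional binary
   closing, off by default).  All parameters outside the support are zeroed
   (vacuum) and frozen; a frozen non-zero amplitude outside the support
   would project as an un-correctable background.  Inside the support the
   `a00` start for the following steps is a support-normalized 3³ Hamming
   average, so the quasi-null modes start clean.
3. **Angles** — anisotropic coefficients frozen at `a_l0 = s_l · a00`
   (defaults `s_2 = −0.3`, `s_4 = 0.1`, `s_6 = −0.05`, an equatorial-band
   profile typical of fibril scattering; tunable, and worth re-running with
   different values to detect local minima).  Zenith angles start from a
   seeded uniform-hemisphere draw.
4. **Coefficients**, then **everything jointly**.

Per-step iteration caps and tolerances are config values; the defaults
(40/40/40/60) suit the 16³ problems used throughout the validation, and the
deeper recovery experiments in the tests state their own caps.  Runs are
deterministic given the config seed.

## L-curve

`l_curve` sweeps ascending `μ`, warm-starting each reconstruction from the
previous one (a joint refinement), and reports data error vs orientation
penalty plus the maximum-curvature corner of the log–log curve.  The corner
is only reported, never silently applied — visual inspection may prefer a
point on the small-error side.  `warm_start=False` runs every `μ` from
scratch; the regularization-behavior test uses it so that all sweep points
receive equal optimization effort and the two terms are comparable.

## Synthetic data

The generator emulates a trabecular-bone-like specimen at desk scale: a ball
support (vacuum margin ≥ 1 voxel) split into `n_domains` connected regions
(nearest-seed Voronoi cells or axis-aligned slabs), each with one random
zenith and a common zonal coefficient profile, default
`(a00, a20, a40, a60) = (1, −0.3, 0.1, −0.05)` — an equatorial intensity band
perpendicular to the fibril axis.  Transmission images follow
`T = exp(−line integral)` of a uniform attenuation inside the support
(default 0, i.e. absorption-free); counting noise is Poisson at
`photons_per_pixel = 10⁴` (stored as counts divided by that scale so noisy
and noiseless stacks share units) — large enough for the amplitude residual's
Gaussian approximation, small enough to exercise the noise handling.

What the generator does *not* emulate: detector background and dark counts,
misalignment between projections, beam-profile and flux variations, q-range
mixing (one q bin per stack), intra-voxel orientation spread beyond the
band-limited model, and multiple scattering.  Passing the recovery tests
therefore demonstrates correctness of the model, gradients and optimizer on
in-model data, not robustness to every experimental artifact.

## Validation experiments and problem sizes

All validation runs use 16³ (recovery, sampling study) or 12³
(regularization sweep) volumes with 16 detector segments; these sizes keep a
full 240-projection reconstruction in the minutes range on one CPU while
preserving the geometry of the published acquisition (the 240/120/48/40
orientation subsets).  The sampling-isotropy study asserts only the published
*ordering* of full-grid misfits (near-isotropic 48 < single-axis 40, and 48 ≤
three-tilt 120) over ten phantom seeds, not magnitudes.  The thin-section
degree-sufficiency analysis uses seven tilts between ±45° and Poisson noise
at 10⁴ counts, reproducing the qualitative result that `l ≤ 6` suffices while
`l ≤ 8` adds nothing.

## Known limitations

* Reconstruction quality at the voxel scale is limited by the kernel-nulled
  modes; the deepest CG runs plateau at a few percent median intensity-map
  error on noiseless 16³ phantoms.  Sharper recovery would need either a
  different anti-aliasing scheme or curvature-aware optimization, both out
  of scope.
* Step 1's isotropic estimate is biased for strongly anisotropic samples
  (see above); do not use it quantitatively.
* The zonal fast path assumes `m = 0` bases; general orders use a slower
  per-orientation path (gradients equally certified).
* Per-q-bin independence: radial coupling across q is not modelled.
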