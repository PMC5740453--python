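# saxstt — small-angle X-ray scattering tensor tomography

`saxstt` reconstructs the three-dimensional nanostructure orientation inside a
bulk sample from scanning small-angle X-ray scattering (SAXS) projections.
Every voxel of the reconstruction holds not a scalar but a band-limited model
of its reciprocal-space map — the angular distribution of scattered intensity
at fixed momentum transfer — so the method is a *tensor* tomography.  It was
developed for hierarchical biological materials such as trabecular bone, where
the oriented mineralized collagen fibrils produce a strongly anisotropic SAXS
signal and domains of common orientation span many voxels.

## The model

The reciprocal-space map of voxel `r` is expanded in real spherical harmonics
evaluated in coordinates whose pole is the voxel's preferred orientation, a
unit vector `u(r)` parameterized by angles `(θ_op, φ_op)`:

    R(r, q̂) = [ Σ_{l,m} a_lm(r) · Y_lm(θ', φ') ]²,   cos θ' = q̂ · u(r)

The square keeps intensities non-negative; even degrees `l` enforce SAXS point
symmetry; for fibril-like scatterers with one symmetry axis, zero-order
(`m = 0`, zonal) terms with `l ≤ 6` suffice.  A projection at sample rotation
`α` (about the object y axis) and tilt `β` (about the lab x axis) probes, in
each of the K azimuthal detector segments, the in-plane direction
`q̂_k = Rᵀ(cos φ_k, sin φ_k, 0)`; the modelled raster image is the beam-path
sum of per-voxel intensities, sampled with trilinear weights and convolved
with a 3×3 pyramidal anti-aliasing kernel.

Reconstruction minimizes the masked, absorption-normalized misfit

    ε = Σ_n Σ_{x,y,k} W · ( √Î_n − √(I_n / T_n) )²

(a first-order approximation to the Poisson maximum-likelihood metric) with
nonlinear conjugate gradients and analytic gradients, in four steps: isotropic
term against azimuthally averaged data; zenith angles with coefficients frozen
at fixed ratios `s_l·a00`; coefficients; everything jointly.  Two
regularizers address voxel-scale noise: Hamming-window smoothing of the
coefficient gradients (Grenander's method of sieves) and a neighbor-orientation
penalty `R_u = Σ (1 − |u·u'|)` weighted by `μ` and selected via an L-curve.

## Worked example

```python
import numpy as np
import saxstt as st

# a 12^3 synthetic sample: two domains of uniform fibril orientation,
# measured with Poisson counting noise at 1e4 photons per pixel
spec = st.PhantomSpec(shape=(12, 12, 12), n_domains=2, seed=3)
volume, truth = st.make_phantom(spec)

# near-isotropic two-axis sampling: Δα = 22.5° over [0°, 180°),
# Δβ = 15° over [−30°, 45°]  →  48 projections, 16 detector segments
grid = st.subset_grid(st.orientation_grid(), alpha_keep_step=22.5)
det = st.DetectorGeometry()
data = st.simulate_stack(volume, grid, det, spec, noise=True, seed=3)

cfg = st.ReconstructionConfig(seed=11, mu=0.2)  # orientation regularization on
result = st.reconstruct_full(data, cfg, shape=(12, 12, 12))

summary = st.summarize(result.volume)
rho = summary.rho[result.volume.support]
print(f"{len(grid)} projections, {int(result.volume.support.sum())} support voxels")
print(f"median degree of orientation: {np.median(rho):.2f}")
for d, u_true in enumerate(truth["domain_u"]):
    sel = (truth["labels"] == d) & result.volume.support
    dots = np.abs(summary.u[sel] @ u_true)
    err = np.median(np.degrees(np.arccos(np.clip(dots, 0, 1))))
    print(f"domain {d}: median zenith error {err:.1f} deg")
```

which prints (about a minute on one CPU)

```
48 projections, 308 support voxels
median degree of orientation: 0.84
domain 0: median zenith error 1.7 deg
domain 1: median zenith error 1.5 deg
```

i.e. the reconstructed voxels carry the strong anisotropy (ρ ≈ 0.84) implied
by the phantom's equatorial-band coefficient profile, and the recovered
per-domain fibril orientations agree with the generating directions to under
two degrees — from only 48 noisy projections, thanks to the near-isotropic
angular sampling.  `st.export_orientation_field(result.volume, "field.vtk")`
writes the orientation vectors for any VTK-capable 3D viewer.

A command-line interface wraps the same functions:

```bash
saxstt make-phantom --out phantom.h5 --shape 16 --domains 2 --seed 3
saxstt simulate --phantom-file phantom.h5 --out stack.h5 --seed 3
saxstt reconstruct --stack stack.h5 --out result.h5 --seed 11
saxstt summarize --result result.h5 --out field.vtk
saxstt lcurve --stack stack.h5 --mus 0,0.01,0.03,0.1,0.3
```

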