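"""Synthetic tensor-volume phantoms and simulated scanning-SAXS stacks.

The generator emulates, at desk scale, a specimen like trabecular bone: a
compact support containing a few connected domains, each with a uniform
nanostructure orientation and an even-degree zonal reciprocal-space map whose
equatorial band mimics scattering from mineralized fibrils.  Projection
stacks are produced by the package's own forward model, with transmission
images from a line-integral attenuation model and optional Poisson counting
noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import (
    DetectorGeometry,
    TensorVolume,
    project,
    project_scalar,
    segment_q_directions,
)
from .geometry import OrientationGrid, SampleOrientation
from .harmonics import SHBasisSpec, VoxelSH, amplitude_many, canonicalize_zenith, unit_to_angles
from .objective import MeasuredProjection

__all__ = ["PhantomSpec", "make_phantom", "simulate_stack", "azimuthal_profile_simulator"]

#: Default zonal coefficient profile: an equatorial band (intensity ring
#: perpendicular to the zenith) typical of fibril scattering.  Package
#: defaults, not measured values.
DEFAULT_COEFF_PROFILE = {0: 1.0, 2: -0.3, 4: 0.1, 6: -0.05}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic sample and its measurement."""

    shape: tuple = (16, 16, 16)
    n_domains: int = 2
    domain_geometry: str = "voronoi"  # or "blocks"
    coeff_profile: dict = field(default_factory=lambda: dict(DEFAULT_COEFF_PROFILE))
    attenuation: float = 0.0  # per-voxel linear attenuation inside the support
    photons_per_pixel: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if any(s < 4 for s in self.shape):
            raise ValueError("each axis must have at least 4 voxels")
        if self.photons_per_pixel < 0 or self.attenuation < 0:
            raise ValueError("photons and attenuation must be non-negative")
        if self.domain_geometry not in ("voronoi", "blocks"):
            raise ValueError(f"unknown domain geometry {self.domain_geometry!r}")


def _ball_support(shape) -> np.ndarray:
    """Compact support with a vacuum margin of at least one voxel per face."""
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2.0 for s in shape], indexing="ij")
    radius = min(shape) / 2.0 - 2.0
    return sum(g * g for g in grids) <= radius * radius


def make_phantom(spec: PhantomSpec, basis: SHBasisSpec | None = None):
    """Build a domained TensorVolume plus its ground-truth record.

    Domains are connected regions of constant zenith and coefficients:
    nearest-seed (Voronoi) cells or axis-aligned slabs.  Returns
    (volume, truth) where ``truth`` holds the domain label field (-1 outside
    the support), the per-domain zeniths and the coefficient table.
    """
    if basis is None:
        basis = SHBasisSpec(tuple(sorted(spec.coeff_profile)))
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    support = _ball_support(shape)
    n_inside = int(support.sum())
    if spec.n_domains > n_inside:
        raise ValueError("more domains than support voxels")

    inside = np.argwhere(support)
    if spec.domain_geometry == "voronoi":
        seeds = inside[rng.choice(n_inside, size=spec.n_domains, replace=False)]
        d2 = ((inside[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        inside_labels = np.argmin(d2, axis=1)
    else:  # blocks: slabs along the longest axis
        axis = int(np.argmax(shape))
        coords = inside[:, axis]
        edges = np.quantile(coords, np.linspace(0, 1, spec.n_domains + 1)[1:-1])
        inside_labels = np.searchsorted(edges, coords, side="right")

    labels = np.full(shape, -1, dtype=int)
    labels[tuple(inside.T)] = inside_labels

    # per-domain zeniths: uniform on the canonical hemisphere
    v = rng.normal(size=(spec.n_domains, 3))
    domain_u = canonicalize_zenith(v / np.linalg.norm(v, axis=1, keepdims=True))

    volume = TensorVolume.zeros(shape, basis)
    volume.support = support
    theta_d, phi_d = unit_to_angles(domain_u)
    coeff_row = np.zeros(basis.size)
    for l, value in spec.coeff_profile.items():
        coeff_row[basis.index_of(l, 0)] = value
    for d in range(spec.n_domains):
        sel = labels == d
        volume.theta[sel] = theta_d[d]
        volume.phi[sel] = phi_d[d]
        volume.coeffs[sel] = coeff_row

    truth = {
        "labels": labels,
        "domain_u": domain_u,
        "coeffs": coeff_row,
        "support": support,
    }
    return volume, truth


def simulate_stack(phantom: TensorVolume, grid: OrientationGrid, det: DetectorGeometry,
                   spec: PhantomSpec, noise: bool = True, seed: int | None = None):
    """Forward-simulate a measured stack for every orientation of the grid.

    Transmission images follow T = exp(-line integral of the attenuation
    field); stored intensities are the attenuated model, with Poisson counts
    at scale ``photons_per_pixel`` (divided back by the scale, so noiseless
    and noisy stacks share units) when noise is enabled.  Masks start all
    valid and can be edited to emulate bad segments.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    att = np.where(phantom.support, spec.attenuation, 0.0)
    out = []
    for orient in grid:
        img = project(phantom, orient, det).intensities
        T = np.exp(-project_scalar(att, orient))
        I = img * T[..., None]
        if noise:
            scale = spec.photons_per_pixel
            if scale <= 0:
                raise ValueError("photons_per_pixel must be positive for noisy simulation")
            I = rng.poisson(scale * I).astype(float) / scale
        out.append(
            MeasuredProjection(
                intensities=I,
                transmission=T,
                mask=np.ones(I.shape, dtype=bool),
                orientation=orient,
            )
        )
    return out


def azimuthal_profile_simulator(voxel: VoxelSH, basis: SHBasisSpec, beta_list,
                                n_segments: int = 16) -> np.ndarray:
    """Single-voxel thin-section profiles: intensity vs detector azimuth.

    For each tilt beta of the section about the in-plane rotation axis the
    one-voxel beam path gives intensity A(q_k)^2 in each azimuthal segment.
    Returns an array (len(beta_list), n_segments).
    """
    det = DetectorGeometry(n_segments=n_segments)
    profiles = np.empty((len(beta_list), n_segments))
    for i, beta in enumerate(beta_list):
        orient = SampleOrientation(float(beta), 0.0)  # tilt about the object y axis
        q = segment_q_directions(det, orient)
        A = amplitude_many(voxel.coeffs[None, :], voxel.u[None, :], basis, q)
        profiles[i] = A[0] ** 2
    return profiles
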