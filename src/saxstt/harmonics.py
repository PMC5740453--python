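"""Real spherical-harmonics model of the per-voxel reciprocal-space map.

Each voxel carries a band-limited function on the sphere of scattering
directions: the amplitude is a linear combination of real, orthonormal
spherical harmonics evaluated in coordinates whose zenith is the voxel's
preferred-orientation unit vector ``u``; the modelled intensity is the square
of that amplitude, which keeps it non-negative without constraints.  SAXS
point symmetry (intensity(q) = intensity(-q)) is enforced by restricting the
basis to even degrees; a nanostructure with a single symmetry axis needs only
zero-order (zonal) terms.

Conventions: real harmonics without the Condon-Shortley phase, orthonormal on
the unit sphere.  The azimuth of the zenith-relative frame is measured from
the projection of the object z axis (deterministic fallback to x when the
zenith is within 1e-6 of +/-z; the fallback is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.special import eval_legendre, lpmv

logger = logging.getLogger(__name__)

__all__ = [
    "SHBasisSpec",
    "VoxelSH",
    "real_sph_harm",
    "local_polar",
    "rs_amplitude",
    "rs_intensity_map",
    "fibonacci_sphere",
    "angles_to_unit",
    "unit_to_angles",
    "canonicalize_zenith",
]

_POLE_TOL = 1e-6


# ---------------------------------------------------------------------------
# basis specification

@dataclass(frozen=True)
class SHBasisSpec:
    """Ordered set of even-degree (l, m) pairs; default zonal l in {0,2,4,6}."""

    degrees: tuple = (0, 2, 4, 6)
    orders: dict = field(default=None)

    def __post_init__(self):
        degrees = tuple(int(l) for l in self.degrees)
        if any(l < 0 or l % 2 for l in degrees):
            raise ValueError("degrees must be even and non-negative")
        if len(set(degrees)) != len(degrees):
            raise ValueError("duplicate degrees")
        orders = self.orders
        if orders is None:
            orders = {l: (0,) for l in degrees}
        orders = {int(l): tuple(int(m) for m in ms) for l, ms in orders.items()}
        for l in degrees:
            ms = orders.get(l, (0,))
            if any(abs(m) > l for m in ms):
                raise ValueError(f"|m| > l for degree {l}")
            if len(set(ms)) != len(ms):
                raise ValueError(f"duplicate orders for degree {l}")
            orders[l] = ms
        object.__setattr__(self, "degrees", degrees)
        object.__setattr__(self, "orders", orders)

    @property
    def lm_pairs(self) -> tuple:
        return tuple((l, m) for l in self.degrees for m in self.orders[l])

    @property
    def size(self) -> int:
        return len(self.lm_pairs)

    @property
    def is_zonal(self) -> bool:
        return all(m == 0 for _, m in self.lm_pairs)

    def index_of(self, l: int, m: int = 0) -> int:
        return self.lm_pairs.index((l, m))

    def truncated(self, lmax: int) -> "SHBasisSpec":
        degrees = tuple(l for l in self.degrees if l <= lmax)
        return SHBasisSpec(degrees, {l: self.orders[l] for l in degrees})


@dataclass
class VoxelSH:
    """Spherical-harmonics coefficients plus zenith angles for one voxel."""

    coeffs: np.ndarray
    theta_op: float = 0.0
    phi_op: float = 0.0

    def __post_init__(self):
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))

    @property
    def u(self) -> np.ndarray:
        return angles_to_unit(self.theta_op, self.phi_op)


# ---------------------------------------------------------------------------
# direction parameterization

def angles_to_unit(theta, phi) -> np.ndarray:
    """Unit vector(s) from polar angle theta and azimuth phi (radians)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def unit_to_angles(u) -> tuple:
    u = np.asarray(u, dtype=float)
    theta = np.arccos(np.clip(u[..., 2], -1.0, 1.0))
    phi = np.arctan2(u[..., 1], u[..., 0])
    return theta, phi


def canonicalize_zenith(u: np.ndarray) -> np.ndarray:
    """Map each zenith to the canonical hemisphere u_z > 0 (ties: u_y, then u_x).

    Even-degree maps are invariant under u -> -u, so the sign is a pure
    reporting convention.
    """
    u = np.array(u, dtype=float, copy=True)
    flat = u.reshape(-1, 3)
    z, y, x = flat[:, 2], flat[:, 1], flat[:, 0]
    flip = (z < 0) | ((np.abs(z) == 0) & ((y < 0) | ((y == 0) & (x < 0))))
    flat[flip] *= -1.0
    return flat.reshape(u.shape)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform sphere sampling with n points."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


# ---------------------------------------------------------------------------
# real spherical harmonics

def _norm_lm(l: int, m: int) -> float:
    am = abs(m)
    return np.sqrt((2 * l + 1) / (4.0 * np.pi) * factorial(l - am) / factorial(l + am))


def _assoc_legendre(l: int, m: int, t: np.ndarray) -> np.ndarray:
    """Associated Legendre P_l^m(t) without the Condon-Shortley phase."""
    if m == 0:
        return eval_legendre(l, t)
    return (-1.0) ** m * lpmv(m, l, t)


def _assoc_legendre_dt(l: int, m: int, t: np.ndarray) -> np.ndarray:
    """d/dt of the unphased associated Legendre function.

    m = 0 uses the exact polynomial derivative (stable at the poles); m > 0
    uses (1 - t^2) dP/dt = (l + m) P_{l-1}^m - l t P_l^m with the poles
    clamped (the pole set is measure zero for the optimizer).
    """
    t = np.asarray(t, dtype=float)
    if m == 0:
        c = np.zeros(l + 1)
        c[l] = 1.0
        dc = np.polynomial.legendre.legder(c)
        return np.polynomial.legendre.legval(t, dc)
    omt2 = np.maximum(1.0 - t * t, 1e-12)
    pl = _assoc_legendre(l, m, t)
    plm1 = _assoc_legendre(l - 1, m, t) if l - 1 >= m else np.zeros_like(t)
    return ((l + m) * plm1 - l * t * pl) / omt2


# Horner forms of the even Legendre polynomials (and derivatives) in s = t^2,
# used on the optimizer's hot path; higher degrees fall back to scipy.
_LEGENDRE_EVEN = {
    0: lambda t, s: np.ones_like(t),
    2: lambda t, s: 1.5 * s - 0.5,
    4: lambda t, s: (4.375 * s - 3.75) * s + 0.375,
    6: lambda t, s: ((14.4375 * s - 19.6875) * s + 6.5625) * s - 0.3125,
    8: lambda t, s: (((50.2734375 * s - 93.84375) * s + 54.140625) * s - 9.84375) * s
    + 0.2734375,
}
_LEGENDRE_EVEN_DERIV = {
    0: lambda t, s: np.zeros_like(t),
    2: lambda t, s: 3.0 * t,
    4: lambda t, s: t * (17.5 * s - 7.5),
    6: lambda t, s: t * ((86.625 * s - 78.75) * s + 13.125),
    8: lambda t, s: t * (((402.1875 * s - 563.0625) * s + 216.5625) * s - 19.6875),
}


def legendre_even(l: int, t: np.ndarray, s: np.ndarray | None = None) -> np.ndarray:
    s = t * t if s is None else s
    fn = _LEGENDRE_EVEN.get(l)
    if fn is not None:
        return fn(t, s)
    return eval_legendre(l, t)


def legendre_even_deriv(l: int, t: np.ndarray, s: np.ndarray | None = None) -> np.ndarray:
    s = t * t if s is None else s
    fn = _LEGENDRE_EVEN_DERIV.get(l)
    if fn is not None:
        return fn(t, s)
    c = np.zeros(l + 1)
    c[l] = 1.0
    return np.polynomial.legendre.legval(t, np.polynomial.legendre.legder(c))


def real_sph_harm(l: int, m: int, theta, phi) -> np.ndarray:
    """Real orthonormal spherical harmonic Y_lm(theta, phi).

    m = 0 members depend on theta only; m > 0 pair with cos(m phi), m < 0
    with sin(|m| phi).
    """
    if abs(m) > l or l < 0:
        raise ValueError(f"invalid (l, m) = ({l}, {m})")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    t = np.cos(theta)
    am = abs(m)
    val = _norm_lm(l, m) * _assoc_legendre(l, am, t)
    if m > 0:
        val = val * np.sqrt(2.0) * np.cos(m * phi)
    elif m < 0:
        val = val * np.sqrt(2.0) * np.sin(am * phi)
    else:
        val = val * np.ones_like(phi)
    return val


# ---------------------------------------------------------------------------
# zenith-oriented local coordinates

def _reference_vectors(u: np.ndarray, reference=None) -> np.ndarray:
    """Per-zenith azimuth reference; canonical z with deterministic fallback."""
    u = np.atleast_2d(u)
    if reference is None:
        ref = np.tile(np.array([0.0, 0.0, 1.0]), (u.shape[0], 1))
    else:
        ref = np.broadcast_to(np.asarray(reference, dtype=float), u.shape).copy()
    aligned = np.abs(np.einsum("ij,ij->i", ref, u)) > 1.0 - _POLE_TOL
    if np.any(aligned):
        logger.info(
            "azimuth reference parallel to zenith for %d voxel(s); falling back to x axis",
            int(aligned.sum()),
        )
        ref[aligned] = np.array([1.0, 0.0, 0.0])
        still = np.abs(np.einsum("ij,ij->i", ref, u)) > 1.0 - _POLE_TOL
        ref[still] = np.array([0.0, 1.0, 0.0])
    return ref


def local_frames(u: np.ndarray, reference=None) -> tuple:
    """Orthonormal frames (e1, e2, u) defining the zenith-relative azimuth."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    ref = _reference_vectors(u, reference)
    v = ref - np.einsum("ij,ij->i", ref, u)[:, None] * u
    e1 = v / np.linalg.norm(v, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def local_polar(q_dir, u, reference=None) -> tuple:
    """Zenith-relative polar coordinates (theta', phi') of a direction.

    theta' = arccos(q . u); phi' is measured about u from the projection of
    the reference vector (object z by default) onto the plane normal to u.
    """
    q_dir = np.asarray(q_dir, dtype=float)
    u = np.asarray(u, dtype=float)
    for name, vec in (("q_dir", q_dir), ("u", u)):
        if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
            raise ValueError(f"{name} must be unit norm")
    e1, e2 = local_frames(u[None, :], reference)
    t = float(np.clip(np.dot(q_dir, u), -1.0, 1.0))
    theta_p = np.arccos(t)
    phi_p = float(np.arctan2(np.dot(q_dir, e2[0]), np.dot(q_dir, e1[0])))
    return theta_p, phi_p


# ---------------------------------------------------------------------------
# amplitude / intensity evaluation

def sph_basis_matrix(basis: SHBasisSpec, t: np.ndarray, phi_p: np.ndarray | None) -> np.ndarray:
    """Basis values Y_j stacked along the last axis; t = cos(theta')."""
    t = np.asarray(t, dtype=float)
    cols = []
    for l, m in basis.lm_pairs:
        am = abs(m)
        col = _norm_lm(l, m) * _assoc_legendre(l, am, t)
        if m > 0:
            col = col * np.sqrt(2.0) * np.cos(m * phi_p)
        elif m < 0:
            col = col * np.sqrt(2.0) * np.sin(am * phi_p)
        cols.append(col)
    return np.stack(cols, axis=-1)


def sph_basis_matrix_deriv(basis: SHBasisSpec, t: np.ndarray, phi_p: np.ndarray | None) -> tuple:
    """(dY/dt, dY/dphi') stacked along the last axis."""
    t = np.asarray(t, dtype=float)
    d_t, d_p = [], []
    for l, m in basis.lm_pairs:
        am = abs(m)
        n = _norm_lm(l, m)
        dp = n * _assoc_legendre_dt(l, am, t)
        p = n * _assoc_legendre(l, am, t)
        if m > 0:
            trig = np.sqrt(2.0) * np.cos(m * phi_p)
            dtrig = -m * np.sqrt(2.0) * np.sin(m * phi_p)
        elif m < 0:
            trig = np.sqrt(2.0) * np.sin(am * phi_p)
            dtrig = am * np.sqrt(2.0) * np.cos(am * phi_p)
        else:
            trig = np.ones_like(t)
            dtrig = np.zeros_like(t)
        d_t.append(dp * trig)
        d_p.append(p * dtrig)
    return np.stack(d_t, axis=-1), np.stack(d_p, axis=-1)


def amplitude_many(coeffs: np.ndarray, u: np.ndarray, basis: SHBasisSpec, q_dirs: np.ndarray) -> np.ndarray:
    """Amplitude A for coefficient rows (N, J), zeniths (N, 3), directions (K, 3).

    Returns (N, K).  Zonal bases avoid the local-frame construction entirely.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    u = np.asarray(u, dtype=float)
    q_dirs = np.atleast_2d(np.asarray(q_dirs, dtype=float))
    t = np.clip(u @ q_dirs.T, -1.0, 1.0)  # (N, K)
    if basis.is_zonal:
        A = np.zeros_like(t)
        for j, (l, _) in enumerate(basis.lm_pairs):
            A += coeffs[:, j][:, None] * (_norm_lm(l, 0) * eval_legendre(l, t))
        return A
    e1, e2 = local_frames(u)
    c = e1 @ q_dirs.T
    s = e2 @ q_dirs.T
    phi_p = np.arctan2(s, c)
    Y = sph_basis_matrix(basis, t, phi_p)  # (N, K, J)
    return np.einsum("nkj,nj->nk", Y, coeffs)


def rs_amplitude(voxel: VoxelSH, basis: SHBasisSpec, q_dir) -> float:
    """Amplitude of the voxel's reciprocal-space map along one direction."""
    if voxel.coeffs.size != basis.size:
        raise ValueError("coefficient count does not match basis size")
    q = np.atleast_2d(np.asarray(q_dir, dtype=float))
    A = amplitude_many(voxel.coeffs[None, :], voxel.u[None, :], basis, q)
    return float(A[0, 0]) if q.shape[0] == 1 else A[0]


def rs_intensity_map(voxel: VoxelSH, basis: SHBasisSpec, sphere_grid) -> np.ndarray:
    """Non-negative modelled intensity A^2 on a grid of unit directions."""
    grid = np.atleast_2d(np.asarray(sphere_grid, dtype=float))
    A = amplitude_many(voxel.coeffs[None, :], voxel.u[None, :], basis, grid)
    return (A[0] ** 2)
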