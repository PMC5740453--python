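"""Anisotropic tomographic forward projection and its exact adjoint.

For one sample orientation the zero-order SAXS geometry makes the probed
reciprocal-space direction of each detector segment constant across the raster
scan, so the modelled projection factorizes into (i) a per-voxel, per-segment
intensity A(r, q_k)^2 and (ii) a scalar ray transform along the lab z axis.
The ray transform samples the rotated object on a lab-aligned grid with one
sample per voxel pitch and trilinear gather weights (bilinear in the two
transverse dimensions whenever a rotation keeps an object axis grid-aligned),
and is materialized as a sparse matrix per orientation so that the adjoint is
exact by construction.  Projected images are finally convolved with a 3x3
pyramidal kernel emulating up-/down-sampling to suppress grid artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .geometry import SampleOrientation
from .harmonics import SHBasisSpec, amplitude_many, angles_to_unit

__all__ = [
    "DetectorGeometry",
    "TensorVolume",
    "ProjectionImage",
    "segment_q_directions",
    "pyramid_kernel",
    "project",
    "project_adjoint",
    "project_scalar",
    "pixel_count",
]


# ---------------------------------------------------------------------------
# containers

def default_segment_azimuths(n_segments: int = 16) -> tuple:
    """Detector segment centers at (k + 1/2) * 2 pi / K, spanning [0, 2 pi)."""
    return tuple((k + 0.5) * 2.0 * np.pi / n_segments for k in range(n_segments))


@dataclass(frozen=True)
class DetectorGeometry:
    """Azimuthal segmentation of the 2D detector for one q bin."""

    n_segments: int = 16
    segment_azimuths: tuple = None
    q_bin: tuple = (0.0379, 0.0758)  # 1/nm, metadata only

    def __post_init__(self):
        if self.segment_azimuths is None:
            object.__setattr__(
                self, "segment_azimuths", default_segment_azimuths(self.n_segments)
            )
        az = tuple(float(a) for a in self.segment_azimuths)
        if len(az) != self.n_segments:
            raise ValueError("segment count mismatch")
        if self.n_segments % 2:
            raise ValueError("n_segments must be even (point-symmetric pairs)")
        if any(b <= a for a, b in zip(az, az[1:])) or az[0] < 0 or az[-1] >= 2 * np.pi:
            raise ValueError("azimuths must be strictly increasing within [0, 2 pi)")
        object.__setattr__(self, "segment_azimuths", az)


@dataclass
class TensorVolume:
    """Per-voxel spherical-harmonics coefficients, zenith angles and support."""

    basis: SHBasisSpec
    coeffs: np.ndarray  # (Nx, Ny, Nz, J)
    theta: np.ndarray  # (Nx, Ny, Nz), radians
    phi: np.ndarray  # (Nx, Ny, Nz), radians
    support: np.ndarray  # (Nx, Ny, Nz), bool
    voxel_size: float = 1.0  # micrometres

    def __post_init__(self):
        self.coeffs = np.ascontiguousarray(self.coeffs, dtype=float)
        self.theta = np.ascontiguousarray(self.theta, dtype=float)
        self.phi = np.ascontiguousarray(self.phi, dtype=float)
        self.support = np.ascontiguousarray(self.support, dtype=bool)
        if self.coeffs.shape[:3] != self.theta.shape or self.theta.shape != self.phi.shape:
            raise ValueError("inconsistent field shapes")
        if self.support.shape != self.theta.shape:
            raise ValueError("support shape mismatch")
        if self.coeffs.shape[3] != self.basis.size:
            raise ValueError("coefficient count does not match basis")

    @classmethod
    def zeros(cls, shape, basis: SHBasisSpec, voxel_size: float = 1.0) -> "TensorVolume":
        shape = tuple(int(s) for s in shape)
        return cls(
            basis=basis,
            coeffs=np.zeros(shape + (basis.size,)),
            theta=np.zeros(shape),
            phi=np.zeros(shape),
            support=np.ones(shape, dtype=bool),
            voxel_size=voxel_size,
        )

    @property
    def shape(self) -> tuple:
        return self.theta.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def u_field(self) -> np.ndarray:
        return angles_to_unit(self.theta, self.phi)

    def copy(self) -> "TensorVolume":
        return TensorVolume(
            basis=self.basis,
            coeffs=self.coeffs.copy(),
            theta=self.theta.copy(),
            phi=self.phi.copy(),
            support=self.support.copy(),
            voxel_size=self.voxel_size,
        )


@dataclass
class ProjectionImage:
    """Modelled scanning-SAXS raster for one orientation, (nx, ny, K)."""

    intensities: np.ndarray
    orientation: SampleOrientation


# ---------------------------------------------------------------------------
# geometry of the measured reciprocal-space directions

def segment_q_directions(det: DetectorGeometry, orientation: SampleOrientation) -> np.ndarray:
    """Object-frame unit directions probed by each detector segment.

    The zero-order Ewald expansion confines the measurement to the lab plane
    q_z = 0; segment k probes (cos phi_k, sin phi_k, 0) pulled back by R^T.
    """
    az = np.asarray(det.segment_azimuths)
    lab = np.stack([np.cos(az), np.sin(az), np.zeros_like(az)], axis=-1)
    return lab @ orientation.R  # rows: R^T @ lab_k


# ---------------------------------------------------------------------------
# ray transform

def pixel_count(shape) -> int:
    """Raster size covering any rotation of the volume, plus kernel margin."""
    return int(np.ceil(np.sqrt(3.0) * max(shape))) + 4


_RAY_CACHE: dict = {}
_RAY_CACHE_MAX = 400


def ray_matrix(shape, orientation: SampleOrientation, npix: int | None = None) -> sp.csr_matrix:
    """Sparse lab-z ray-summation operator (npix^2 pixels x Nvox voxels).

    Rays step one voxel pitch along lab z; each sample gathers from the object
    grid with trilinear weights; samples outside the volume contribute zero.
    Matrices are cached per (shape, orientation).
    """
    shape = tuple(int(s) for s in shape)
    if npix is None:
        npix = pixel_count(shape)
    key = (shape, npix, round(float(orientation.alpha), 7), round(float(orientation.beta), 7))
    cached = _RAY_CACHE.get(key)
    if cached is not None:
        return cached

    R = orientation.R
    half = (npix - 1) / 2.0
    coords = np.arange(npix) - half
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    p_lab = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    p_obj = p_lab @ R  # row-wise R^T @ p_lab
    # fractional voxel indices (voxel centers at integer indices)
    offs = (np.asarray(shape) - 1) / 2.0
    f = p_obj + offs

    i0 = np.floor(f).astype(np.int64)
    frac = f - i0
    pixel_rows = np.repeat(np.arange(npix * npix), npix)

    rows_all, cols_all, data_all = [], [], []
    for corner in range(8):
        dx, dy, dz = (corner >> 2) & 1, (corner >> 1) & 1, corner & 1
        idx = i0 + np.array([dx, dy, dz])
        w = (
            (frac[:, 0] if dx else 1.0 - frac[:, 0])
            * (frac[:, 1] if dy else 1.0 - frac[:, 1])
            * (frac[:, 2] if dz else 1.0 - frac[:, 2])
        )
        valid = (
            (idx[:, 0] >= 0) & (idx[:, 0] < shape[0])
            & (idx[:, 1] >= 0) & (idx[:, 1] < shape[1])
            & (idx[:, 2] >= 0) & (idx[:, 2] < shape[2])
            & (w > 0)
        )
        lin = (idx[valid, 0] * shape[1] + idx[valid, 1]) * shape[2] + idx[valid, 2]
        rows_all.append(pixel_rows[valid])
        cols_all.append(lin)
        data_all.append(w[valid])

    mat = sp.coo_matrix(
        (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(npix * npix, int(np.prod(shape))),
    ).tocsr()
    if len(_RAY_CACHE) >= _RAY_CACHE_MAX:
        _RAY_CACHE.pop(next(iter(_RAY_CACHE)))
    _RAY_CACHE[key] = mat
    return mat


_BLOCK_CACHE: dict = {}
_BLOCK_CACHE_MAX = 6


def batched_ray_operators(shape, orientations, chunk: int = 64):
    """Chunked block-diagonal ray operators for a whole orientation set.

    Returns a list of dicts {"sl": slice, "B": csr, "BT": csr, "npix": int};
    applying B to per-orientation voxel columns stacked as (C * Nvox, K)
    projects every orientation of the chunk in one sparse matvec.  BT is the
    transpose stored in CSR for a fast adjoint.  Cached per (shape, grid).
    """
    shape = tuple(int(s) for s in shape)
    key = (
        shape,
        tuple((round(float(o.alpha), 7), round(float(o.beta), 7)) for o in orientations),
        chunk,
    )
    cached = _BLOCK_CACHE.get(key)
    if cached is not None:
        return cached
    npix = pixel_count(shape)
    batches = []
    orientations = list(orientations)
    for i0 in range(0, len(orientations), chunk):
        mats = [ray_matrix(shape, o, npix) for o in orientations[i0: i0 + chunk]]
        B = sp.block_diag(mats, format="csr")
        batches.append({"sl": slice(i0, i0 + len(mats)), "B": B, "BT": B.T.tocsr(), "npix": npix})
    if len(_BLOCK_CACHE) >= _BLOCK_CACHE_MAX:
        _BLOCK_CACHE.pop(next(iter(_BLOCK_CACHE)))
    _BLOCK_CACHE[key] = batches
    return batches


def pyramid_kernel() -> np.ndarray:
    """Separable 3x3 triangle (pyramid) kernel, unit sum."""
    k1 = np.array([1.0, 2.0, 1.0]) / 4.0
    return np.outer(k1, k1)


def _convolve_segments(images: np.ndarray) -> np.ndarray:
    """Apply the pyramid kernel over the two raster axes, zero-padded.

    Accepts (nx, ny, K) or batched (C, nx, ny, K) images; the kernel only
    mixes the raster dimensions.
    """
    kern = pyramid_kernel()[:, :, None]
    if images.ndim == 4:
        kern = kern[None]
    return ndimage.convolve(images, kern, mode="constant", cval=0.0)


def voxel_intensities(volume: TensorVolume, q_dirs: np.ndarray) -> np.ndarray:
    """Per-voxel modelled intensities A^2, flattened to (Nvox, K)."""
    coeffs = volume.coeffs.reshape(-1, volume.basis.size)
    u = volume.u_field.reshape(-1, 3)
    A = amplitude_many(coeffs, u, volume.basis, q_dirs)
    return A * A


def project(volume: TensorVolume, orientation: SampleOrientation,
            det: DetectorGeometry) -> ProjectionImage:
    """Modelled scanning-SAXS projection for one orientation."""
    q_dirs = segment_q_directions(det, orientation)
    I_vox = voxel_intensities(volume, q_dirs)
    P = ray_matrix(volume.shape, orientation)
    npix = int(np.sqrt(P.shape[0]))
    img = (P @ I_vox).reshape(npix, npix, det.n_segments)
    return ProjectionImage(_convolve_segments(img), orientation)


def project_scalar(field: np.ndarray, orientation: SampleOrientation) -> np.ndarray:
    """Plain line integral of a scalar voxel field (no kernel), (npix, npix)."""
    field = np.asarray(field, dtype=float)
    P = ray_matrix(field.shape, orientation)
    npix = int(np.sqrt(P.shape[0]))
    return (P @ field.reshape(-1)).reshape(npix, npix)


def project_adjoint(residual_image: np.ndarray, orientation: SampleOrientation,
                    det: DetectorGeometry, volume_shape) -> np.ndarray:
    """Exact adjoint of [ray summation o kernel convolution].

    Maps a residual image (npix, npix, K) back to a per-voxel, per-segment
    accumulation grid (Nx, Ny, Nz, K).  The kernel is symmetric, so its
    adjoint is the same convolution.
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    residual_image = np.asarray(residual_image, dtype=float)
    P = ray_matrix(volume_shape, orientation)
    npix = int(np.sqrt(P.shape[0]))
    if residual_image.shape[:2] != (npix, npix) or residual_image.shape[2] != det.n_segments:
        raise ValueError("residual shape does not match projector geometry")
    smeared = _convolve_segments(residual_image)
    back = P.T @ smeared.reshape(npix * npix, det.n_segments)
    return back.reshape(volume_shape + (det.n_segments,))
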