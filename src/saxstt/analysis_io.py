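"""Derived orientation outputs, thin-section fitting, and file surfaces.

Scalar summaries: the degree of orientation rho = (I_max - I_min) /
(I_max + I_min) of each voxel's reciprocal-space map, sampled on a fixed
Fibonacci direction lattice (rho = 0 for isotropic voxels, 1 when the
amplitude touches zero somewhere on the sphere); main orientations are
reported on the canonical hemisphere u_z > 0.  The thin-section mode fits a
single voxel's map to azimuthal profiles measured at several section tilts
and reports misfit as a function of the maximum harmonic degree, which shows
how many degrees the data actually require.

Containers are single HDF5 files (layout documented in ``write_stack`` /
``write_result``); orientation fields can additionally be exported as legacy
ASCII VTK point vectors for external 3D viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .forward_model import DetectorGeometry, TensorVolume
from .geometry import OrientationGrid, _build_grid
from .harmonics import (
    SHBasisSpec,
    VoxelSH,
    amplitude_many,
    angles_to_unit,
    canonicalize_zenith,
    fibonacci_sphere,
    unit_to_angles,
)
from .objective import MeasuredProjection
from .reconstruct import ReconstructionResult, cg_minimize

__all__ = [
    "OrientationSummary",
    "degree_of_orientation",
    "summarize",
    "thin_section_fit",
    "select_projections",
    "write_stack",
    "read_stack",
    "write_result",
    "read_result",
    "export_orientation_field",
]

_VERSION = "1.0"
_RHO_GRID = 2000


# ---------------------------------------------------------------------------
# degree of orientation

def _rho_from_intensities(I: np.ndarray) -> np.ndarray:
    imax = I.max(axis=-1)
    imin = I.min(axis=-1)
    denom = imax + imin
    return np.where(denom > 0, (imax - imin) / np.where(denom > 0, denom, 1.0), 0.0)


def degree_of_orientation(voxel: VoxelSH, basis: SHBasisSpec) -> float:
    """Anisotropy contrast of one voxel's map, in [0, 1]."""
    grid = fibonacci_sphere(_RHO_GRID)
    A = amplitude_many(voxel.coeffs[None, :], voxel.u[None, :], basis, grid)
    return float(_rho_from_intensities(A * A)[0])


@dataclass
class OrientationSummary:
    """Per-voxel main orientation, isotropic strength and degree of orientation."""

    u: np.ndarray  # (..., 3), canonical hemisphere, zero outside support
    a00: np.ndarray
    rho: np.ndarray
    support: np.ndarray


def summarize(volume: TensorVolume) -> OrientationSummary:
    """Vectorized per-voxel summary over the support."""
    basis = volume.basis
    coeffs = volume.coeffs.reshape(-1, basis.size)
    u = volume.u_field.reshape(-1, 3)
    grid = fibonacci_sphere(_RHO_GRID)
    A = amplitude_many(coeffs, u, basis, grid)
    rho = _rho_from_intensities(A * A).reshape(volume.shape)
    a00 = volume.coeffs[..., basis.index_of(0, 0)].copy()
    u_can = canonicalize_zenith(volume.u_field)
    out = ~volume.support
    rho[out] = 0.0
    a00[out] = 0.0
    u_can[out] = 0.0
    return OrientationSummary(u=u_can, a00=a00, rho=rho, support=volume.support.copy())


# ---------------------------------------------------------------------------
# thin-section single-voxel fitting

def _profile_misfit(params: np.ndarray, basis: SHBasisSpec, q_all: np.ndarray,
                    sqrt_data: np.ndarray, grad: bool):
    """Amplitude-mode misfit of a single voxel against stacked profiles."""
    J = basis.size
    coeffs, theta, phi = params[:J], params[J], params[J + 1]
    u = angles_to_unit(theta, phi)
    A = amplitude_many(coeffs[None, :], u[None, :], basis, q_all)[0]
    I = A * A
    sq = np.sqrt(np.maximum(I, 1e-30))
    r = sq - sqrt_data
    value = float(r @ r)
    if not grad:
        return value, None
    h = 1e-6
    g = np.empty(J + 2)
    for i in range(J + 2):  # small dense problem: central differences suffice
        p1, p2 = params.copy(), params.copy()
        p1[i] += h
        p2[i] -= h
        g[i] = (_profile_misfit(p1, basis, q_all, sqrt_data, False)[0]
                - _profile_misfit(p2, basis, q_all, sqrt_data, False)[0]) / (2 * h)
    return value, g


def _fit_single(basis: SHBasisSpec, q_all: np.ndarray, data: np.ndarray,
                max_iter: int = 120) -> tuple:
    sqrt_data = np.sqrt(np.maximum(data, 0.0))
    a00 = np.sqrt(4.0 * np.pi * max(float(data.mean()), 1e-12))
    best = None
    # deterministic multi-start over candidate zeniths (the angle landscape is
    # multimodal for band-limited maps)
    for u0 in fibonacci_sphere(14):
        if u0[2] < 0:
            continue
        th, ph = unit_to_angles(u0)
        x0 = np.zeros(basis.size + 2)
        x0[basis.index_of(0, 0)] = a00
        for j, (l, _) in enumerate(basis.lm_pairs):
            if l > 0:
                x0[j] = -0.1 * a00 if l == 2 else 0.0
        x0[-2], x0[-1] = th, ph
        x, f, _ = cg_minimize(
            lambda p: _profile_misfit(p, basis, q_all, sqrt_data, False)[0],
            lambda p: _profile_misfit(p, basis, q_all, sqrt_data, True)[1],
            x0, max_iter=max_iter, tol=1e-10, restart=10,
        )
        if best is None or f < best[1]:
            best = (x, f)
    x, f = best
    voxel = VoxelSH(coeffs=x[: basis.size], theta_op=float(x[-2]), phi_op=float(x[-1]))
    return voxel, f


def thin_section_fit(profiles: np.ndarray, beta_list, basis: SHBasisSpec | None = None,
                     lmax_list=(2, 4, 6, 8), n_segments: int | None = None) -> tuple:
    """Fit a single voxel's map to per-tilt azimuthal profiles.

    ``profiles`` has shape (n_beta, n_segments); tilts are rotations of the
    section about the in-plane rotation axis.  Returns (VoxelSH fitted with
    the requested basis, report dict) where the report maps each maximum
    degree in ``lmax_list`` to its misfit -- the degree-sufficiency curve.
    A single tilt leaves the 3D orientation under-determined; the fit still
    runs but the report flags it.
    """
    from .forward_model import segment_q_directions
    from .geometry import SampleOrientation

    profiles = np.asarray(profiles, dtype=float)
    beta_list = list(beta_list)
    if profiles.shape[0] != len(beta_list):
        raise ValueError("profiles/beta count mismatch")
    K = profiles.shape[1] if n_segments is None else n_segments
    det = DetectorGeometry(n_segments=K)
    q_all = np.concatenate(
        [segment_q_directions(det, SampleOrientation(float(b), 0.0)) for b in beta_list]
    )
    data = profiles.reshape(-1)

    report = {"under_determined": len(set(beta_list)) < 2, "misfit_by_lmax": {}}
    max_l = max(lmax_list)
    full = SHBasisSpec(tuple(range(0, max_l + 1, 2))) if basis is None else basis
    fitted = None
    for lmax in sorted(lmax_list):
        b = full.truncated(lmax)
        voxel, misfit = _fit_single(b, q_all, data)
        report["misfit_by_lmax"][lmax] = misfit
        if basis is None and lmax == 6 or basis is not None and lmax == max(lmax_list):
            fitted = (voxel, b)
    if fitted is None:
        fitted = (voxel, b)
    report["basis"] = fitted[1]
    return fitted[0], report


def select_projections(projections, grid: OrientationGrid):
    """Pick the projections matching a (decimated) orientation grid, in order."""
    by_key = {
        (round(p.orientation.alpha, 6), round(p.orientation.beta, 6)): p
        for p in projections
    }
    try:
        return [by_key[(round(o.alpha, 6), round(o.beta, 6))] for o in grid]
    except KeyError as exc:
        raise ValueError(f"stack has no projection at orientation {exc.args[0]}") from None


# ---------------------------------------------------------------------------
# HDF5 container

def _require(h5, name: str):
    if name not in h5:
        raise IOError(f"malformed container: missing node {name!r} in {h5.file.filename}")
    return h5[name]


def _check_version(f: h5py.File):
    ver = f.attrs.get("saxstt_version")
    if ver is None:
        raise IOError("malformed container: missing 'saxstt_version' attribute")
    if str(ver).split(".")[0] != _VERSION.split(".")[0]:
        raise IOError(f"unsupported container major version {ver!r}")


def write_stack(path, projections, grid: OrientationGrid, det: DetectorGeometry,
                voxel_size: float = 1.0) -> None:
    """Write a projection stack.

    Layout: /projections/<n>/{intensities, transmission, mask, alpha, beta},
    /geometry/{segments, q_bin, voxel_size, alpha_values, beta_values,
    alpha_step, beta_step}.
    """
    with h5py.File(path, "w") as f:
        f.attrs["saxstt_version"] = _VERSION
        g = f.create_group("geometry")
        g.create_dataset("segments", data=np.asarray(det.segment_azimuths))
        g.create_dataset("q_bin", data=np.asarray(det.q_bin, dtype=float))
        g.attrs["voxel_size"] = float(voxel_size)
        g.create_dataset("alpha_values", data=np.asarray(grid.alpha_values))
        g.create_dataset("beta_values", data=np.asarray(grid.beta_values))
        g.attrs["alpha_step"] = grid.alpha_step
        g.attrs["beta_step"] = grid.beta_step
        pg = f.create_group("projections")
        for n, p in enumerate(projections):
            gn = pg.create_group(str(n))
            gn.create_dataset("intensities", data=p.intensities)
            gn.create_dataset("transmission", data=p.transmission)
            gn.create_dataset("mask", data=p.mask.astype(np.uint8))
            gn.attrs["alpha"] = p.orientation.alpha
            gn.attrs["beta"] = p.orientation.beta


def read_stack(path):
    """Read a stack container -> (projections, grid, detector, voxel_size)."""
    from .geometry import SampleOrientation

    with h5py.File(path, "r") as f:
        _check_version(f)
        g = _require(f, "geometry")
        az = tuple(float(a) for a in _require(g, "segments")[()])
        det = DetectorGeometry(
            n_segments=len(az), segment_azimuths=az,
            q_bin=tuple(_require(g, "q_bin")[()]),
        )
        grid = _build_grid(
            _require(g, "alpha_values")[()], _require(g, "beta_values")[()],
            g.attrs["alpha_step"], g.attrs["beta_step"],
        )
        voxel_size = float(g.attrs["voxel_size"])
        pg = _require(f, "projections")
        projections = []
        for n in sorted(pg, key=int):
            gn = pg[n]
            projections.append(
                MeasuredProjection(
                    intensities=_require(gn, "intensities")[()],
                    transmission=_require(gn, "transmission")[()],
                    mask=_require(gn, "mask")[()].astype(bool),
                    orientation=SampleOrientation(float(gn.attrs["alpha"]), float(gn.attrs["beta"])),
                )
            )
    return projections, grid, det, voxel_size


def write_result(path, result: ReconstructionResult) -> None:
    """Write a reconstruction: /result/{coeffs, theta, phi, support, trace}."""
    v = result.volume
    with h5py.File(path, "w") as f:
        f.attrs["saxstt_version"] = _VERSION
        g = f.create_group("result")
        g.create_dataset("coeffs", data=v.coeffs)
        g.create_dataset("theta", data=v.theta)
        g.create_dataset("phi", data=v.phi)
        g.create_dataset("support", data=v.support.astype(np.uint8))
        g.attrs["voxel_size"] = v.voxel_size
        g.create_dataset("lm_pairs", data=np.asarray(v.basis.lm_pairs, dtype=int))
        trace = np.array(
            [[t.data_term, t.orientation_term, t.coeff_penalty, t.mu, t.lam]
             for t in result.objective_trace]
        ).reshape(-1, 5)
        g.create_dataset("trace", data=trace)
        g.create_dataset("step_boundaries", data=np.asarray(result.step_boundaries, dtype=int))


def read_result(path) -> TensorVolume:
    """Read the reconstructed volume from a result container."""
    with h5py.File(path, "r") as f:
        _check_version(f)
        g = _require(f, "result")
        lm = [tuple(p) for p in _require(g, "lm_pairs")[()]]
        degrees = tuple(dict.fromkeys(l for l, _ in lm))
        orders = {l: tuple(m for ll, m in lm if ll == l) for l in degrees}
        basis = SHBasisSpec(degrees, orders)
        return TensorVolume(
            basis=basis,
            coeffs=_require(g, "coeffs")[()],
            theta=_require(g, "theta")[()],
            phi=_require(g, "phi")[()],
            support=_require(g, "support")[()].astype(bool),
            voxel_size=float(g.attrs["voxel_size"]),
        )


def export_orientation_field(volume_or_result, path) -> int:
    """Export support-voxel orientations as legacy ASCII VTK point vectors.

    Writes POINTS (voxel centers, micrometres), VECTORS (canonical-hemisphere
    unit zeniths) and SCALARS (degree of orientation).  Returns the number of
    exported points.
    """
    volume = (
        volume_or_result.volume
        if isinstance(volume_or_result, ReconstructionResult)
        else volume_or_result
    )
    summary = summarize(volume)
    idx = np.argwhere(volume.support)
    pts = (idx - (np.asarray(volume.shape) - 1) / 2.0) * volume.voxel_size
    vecs = summary.u[volume.support]
    rho = summary.rho[volume.support]
    n = idx.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("saxstt orientation field\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS orientation float\n")
        for v in vecs:
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        fh.write("SCALARS degree_of_orientation float 1\nLOOKUP_TABLE default\n")
        for r in rho:
            fh.write(f"{r:.8g}\n")
    return n
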