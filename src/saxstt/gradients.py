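"""Analytic gradients of the reconstruction objective.

The gradient of the data term chains through: residual of the (amplitude or
intensity) misfit -> adjoint of the kernel-convolved ray transform -> the
factor 2A of the squared amplitude -> the spherical-harmonics basis values and
their derivatives in zenith-relative coordinates -> the zenith angles through
the local-coordinate relation.  Gradients of the neighbor-orientation
regularizer and the optional coefficient penalty are added for the selected
parameter blocks, and every gradient entry outside the binary support mask is
set to zero (parameters there are frozen).

Because the number of parameters is large, correctness is certified against a
central finite-difference oracle rather than asserted symbolically; the
``finite_difference_oracle`` below is the reference used by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels as _K
from .forward_model import (
    DetectorGeometry,
    TensorVolume,
    batched_ray_operators,
    ray_matrix,
    segment_q_directions,
    _convolve_segments,
)
from .harmonics import (
    _norm_lm,
    legendre_even,
    legendre_even_deriv,
    local_frames,
    sph_basis_matrix,
    sph_basis_matrix_deriv,
)
from .objective import (
    ObjectiveValue,
    _neighbor_dots,
    coeff_penalty,
    normalize_stack,
    orientation_regularizer,
    total_objective,
)

__all__ = [
    "GradientSet",
    "grad_total",
    "finite_difference_oracle",
    "sieve_smooth",
    "hamming_window_3d",
    "TTProblem",
]

_SQRT_FLOOR = 1e-30
_BLOCKS = ("coeffs", "angles", "both")


@dataclass
class GradientSet:
    """Gradients per voxel: coefficients (..., J) and both zenith angles."""

    d_coeffs: np.ndarray
    d_theta: np.ndarray
    d_phi: np.ndarray


def hamming_window_3d(n: int) -> np.ndarray:
    """Separable 3D Hamming window of edge length n, normalized to unit sum."""
    if n % 2 == 0:
        raise ValueError("window edge must be odd")
    w = np.hamming(n)
    w3 = w[:, None, None] * w[None, :, None] * w[None, None, :]
    return w3 / w3.sum()


def sieve_smooth(grads: GradientSet, window, support: np.ndarray | None = None) -> GradientSet:
    """Method-of-sieves smoothing of the coefficient gradients.

    Convolves each coefficient-gradient volume with a unit-sum 3D Hamming
    window (edge 3 or 5); angle gradients are left untouched because a
    direction represented by two coupled angles with a u <-> -u ambiguity
    does not convolve meaningfully.  Support zeroing is re-applied.
    """
    if window in (None, "none"):
        return grads
    w3 = hamming_window_3d(int(window))
    d_coeffs = np.empty_like(grads.d_coeffs)
    for j in range(grads.d_coeffs.shape[-1]):
        d_coeffs[..., j] = ndimage.convolve(
            grads.d_coeffs[..., j], w3, mode="constant", cval=0.0
        )
    if support is not None:
        d_coeffs[~support] = 0.0
    return GradientSet(d_coeffs=d_coeffs, d_theta=grads.d_theta, d_phi=grads.d_phi)


# ---------------------------------------------------------------------------
# evaluator

class TTProblem:
    """Objective/gradient evaluator bound to one measured stack.

    Precomputes absorption-normalized data, masks and probed directions once;
    ray matrices are cached by the forward model.  This is the workhorse
    behind ``grad_total`` and the conjugate-gradient reconstruction.
    """

    def __init__(self, data, det: DetectorGeometry, mu: float = 0.0, lam: float = 0.0,
                 mode: str = "amplitude", bounds_spec: dict | None = None):
        if mode not in ("amplitude", "intensity"):
            raise ValueError(f"unknown residual mode {mode!r}")
        self.det = det
        self.mu = float(mu)
        self.lam = float(lam)
        self.mode = mode
        self.bounds_spec = bounds_spec
        normalized, self.n_bad_pixels = normalize_stack(data)
        self.entries = []
        for d_norm, w, orient in normalized:
            if np.any(d_norm[w] < 0):
                raise ValueError("negative masked-in measured intensity")
            self.entries.append(
                {
                    "orientation": orient,
                    "data": d_norm,
                    "sqrt_data": np.sqrt(np.maximum(d_norm, 0.0)),
                    "mask": w,
                }
            )

    # -- batched data-side state ------------------------------------------

    def _batch_state(self, shape):
        """Chunked operators plus stacked masks/data aligned with the chunks."""
        if getattr(self, "_batches_key", None) == shape:
            return self._batches
        ops = batched_ray_operators(shape, [e["orientation"] for e in self.entries])
        batches = []
        for op in ops:
            chunk = self.entries[op["sl"]]
            q = np.stack(
                [segment_q_directions(self.det, e["orientation"]) for e in chunk]
            )  # (C, K, 3)
            batches.append(
                {
                    "B": op["B"],
                    "BT": op["BT"],
                    "npix": op["npix"],
                    "q": q,
                    "qf": q.reshape(-1, 3),
                    "W": np.stack([e["mask"] for e in chunk]),
                    "D": np.stack([e["data"] for e in chunk]),
                    "sqrtD": np.stack([e["sqrt_data"] for e in chunk]),
                }
            )
        self._batches = batches
        self._batches_key = shape
        return batches

    def _misfit_and_residual(self, img, w, data, sqrt_data, want_grad: bool):
        if self.mode == "amplitude":
            sq = np.sqrt(np.maximum(img, _SQRT_FLOOR))
            r = np.where(w, sq - sqrt_data, 0.0)
            value = float(np.sum(r * r))
            dresid = (r / sq) if want_grad else None  # d/dI of (sqrt I - sqrt D)^2
        else:
            r = np.where(w, img - data, 0.0)
            value = float(np.sum(r * r))
            dresid = (2.0 * r) if want_grad else None
        return value, dresid

    def data_value_and_grad(self, volume: TensorVolume, which: str = "both",
                            want_grad: bool = True):
        """Data misfit and its gradient w.r.t. the selected parameter block."""
        if which not in _BLOCKS:
            raise ValueError(f"unknown parameter block {which!r}")
        basis = volume.basis
        shape = volume.shape
        n_vox = volume.n_voxels
        coeffs = volume.coeffs.reshape(n_vox, basis.size)
        theta = volume.theta.reshape(-1)
        phi = volume.phi.reshape(-1)
        st, ct = np.sin(theta), np.cos(theta)
        sp_, cp = np.sin(phi), np.cos(phi)
        u = np.stack([st * cp, st * sp_, ct], axis=-1)
        want_coeffs = want_grad and which in ("coeffs", "both")
        want_angles = want_grad and which in ("angles", "both")
        if want_angles:
            du_dth = np.stack([ct * cp, ct * sp_, -st], axis=-1)
            du_dph = np.stack([-st * sp_, st * cp, np.zeros_like(st)], axis=-1)

        value = 0.0
        g_coeffs = np.zeros((n_vox, basis.size)) if want_coeffs else None
        g_theta = np.zeros(n_vox) if want_angles else None
        g_phi = np.zeros(n_vox) if want_angles else None

        if basis.is_zonal:
            K = self.det.n_segments
            degrees = [l for l, _ in basis.lm_pairs]
            norms = np.array([_norm_lm(l, 0) for l in degrees])
            cs = coeffs * norms[None, :]  # normalization folded in
            deg_arr = np.asarray(degrees, dtype=np.int64)
            use_kernels = _K.HAVE_NUMBA
            for b in self._batch_state(shape):
                C = b["q"].shape[0]
                npix = b["npix"]
                if use_kernels:
                    A = np.empty((C, n_vox, K))
                    t = np.empty((C, n_vox, K))
                    _K.zonal_forward(u, cs, deg_arr, b["q"], A, t)
                else:
                    t = np.ascontiguousarray(
                        (u @ b["qf"].T).reshape(n_vox, C, K).transpose(1, 0, 2)
                    )
                    np.minimum(t, 1.0, out=t)
                    np.maximum(t, -1.0, out=t)
                    s = t * t
                    A = np.zeros_like(t)
                    for j, l in enumerate(degrees):
                        A += cs[:, j][None, :, None] * legendre_even(l, t, s)
                img = (b["B"] @ (A * A).reshape(C * n_vox, K)).reshape(C, npix, npix, K)
                img = _convolve_segments(img)
                v, dresid = self._misfit_and_residual(
                    img, b["W"], b["D"], b["sqrtD"], want_grad
                )
                value += v
                if not want_grad:
                    continue
                G = (b["BT"] @ _convolve_segments(dresid).reshape(C * npix * npix, K))
                G = G.reshape(C, n_vox, K)
                if use_kernels:
                    _K.zonal_backward(
                        u,
                        du_dth if want_angles else u,
                        du_dph if want_angles else u,
                        cs, norms, deg_arr, b["q"], G, A, t,
                        g_coeffs if want_coeffs else np.zeros((0, basis.size)),
                        g_theta if want_angles else np.zeros(0),
                        g_phi if want_angles else np.zeros(0),
                        want_coeffs, want_angles,
                    )
                else:
                    F = 2.0 * G * A
                    s = t * t
                    if want_coeffs:
                        for j, (l, c) in enumerate(zip(degrees, norms)):
                            g_coeffs[:, j] += c * np.einsum(
                                "cnk,cnk->n", F, legendre_even(l, t, s)
                            )
                    if want_angles:
                        dA = np.zeros_like(t)
                        for j, l in enumerate(degrees):
                            if l == 0:
                                continue
                            dA += cs[:, j][None, :, None] * legendre_even_deriv(l, t, s)
                        FB = F * dA
                        M = np.matmul(
                            FB.transpose(1, 0, 2).reshape(n_vox, -1), b["qf"]
                        )  # (N, 3): sum over (C, K)
                        g_theta += np.einsum("nj,nj->n", M, du_dth)
                        g_phi += np.einsum("nj,nj->n", M, du_dph)
            out_c = g_coeffs.reshape(volume.coeffs.shape) if want_coeffs else None
            out_t = g_theta.reshape(shape) if want_angles else None
            out_p = g_phi.reshape(shape) if want_angles else None
            return value, out_c, out_t, out_p

        # general (m != 0) bases: per-orientation path
        e1, e2 = local_frames(u)
        for entry in self.entries:
            orient = entry["orientation"]
            q = segment_q_directions(self.det, orient)  # (K, 3)
            t = np.clip(u @ q.T, -1.0, 1.0)  # (N, K)
            cc = e1 @ q.T
            ss = e2 @ q.T
            phi_p = np.arctan2(ss, cc)
            Y = sph_basis_matrix(basis, t, phi_p)  # (N, K, J)
            A = np.einsum("nkj,nj->nk", Y, coeffs)

            Pm = ray_matrix(shape, orient)
            npix = int(np.sqrt(Pm.shape[0]))
            K = self.det.n_segments
            img = _convolve_segments((Pm @ (A * A)).reshape(npix, npix, K))
            v, dresid = self._misfit_and_residual(
                img, entry["mask"], entry["data"], entry["sqrt_data"], want_grad
            )
            value += v
            if not want_grad:
                continue
            # back through kernel (self-adjoint) and ray transform
            G = (Pm.T @ _convolve_segments(dresid).reshape(npix * npix, K))  # (N, K)
            F = 2.0 * G * A
            if want_coeffs:
                g_coeffs += np.einsum("nk,nkj->nj", F, Y)
            if want_angles:
                dY_dt, dY_dp = sph_basis_matrix_deriv(basis, t, phi_p)
                At = np.einsum("nkj,nj->nk", dY_dt, coeffs)
                Ap = np.einsum("nkj,nj->nk", dY_dp, coeffs)
                denom = np.maximum(cc * cc + ss * ss, 1e-12)
                for du, g in ((du_dth, g_theta), (du_dph, g_phi)):
                    dt = du @ q.T
                    de1, de2 = _frame_derivative(u, e1, du)
                    dcc = de1 @ q.T
                    dss = de2 @ q.T
                    dphip = (cc * dss - ss * dcc) / denom
                    g += np.sum(F * (At * dt + Ap * dphip), axis=1)
        out_c = g_coeffs.reshape(volume.coeffs.shape) if want_coeffs else None
        out_t = g_theta.reshape(shape) if want_angles else None
        out_p = g_phi.reshape(shape) if want_angles else None
        return value, out_c, out_t, out_p

    # -- regularizer gradients --------------------------------------------

    def _orientation_grad(self, volume: TensorVolume):
        """Gradient of sum (1 - |u.u'|) w.r.t. the zenith angles."""
        u = volume.u_field
        g_u = np.zeros_like(u)
        for dot, pair, _, sl_a, sl_b in _neighbor_dots(u, volume.support):
            s = np.where(pair, np.sign(dot), 0.0)  # subgradient 0 at the kink
            g_u[sl_a] -= s[..., None] * u[sl_b]
            g_u[sl_b] -= s[..., None] * u[sl_a]
        st, ct = np.sin(volume.theta), np.cos(volume.theta)
        sp_, cp = np.sin(volume.phi), np.cos(volume.phi)
        du_dth = np.stack([ct * cp, ct * sp_, -st], axis=-1)
        du_dph = np.stack([-st * sp_, st * cp, np.zeros_like(st)], axis=-1)
        return np.einsum("...i,...i->...", g_u, du_dth), np.einsum("...i,...i->...", g_u, du_dph)

    def _penalty_grad(self, volume: TensorVolume) -> np.ndarray:
        g = np.zeros_like(volume.coeffs)
        if not self.bounds_spec:
            return g
        sup = volume.support
        for (l, m), (lo, hi) in self.bounds_spec.items():
            j = volume.basis.index_of(l, m)
            a = volume.coeffs[..., j]
            gj = np.zeros_like(a)
            if hi is not None:
                gj += 2.0 * np.maximum(a - hi, 0.0)
            if lo is not None:
                gj -= 2.0 * np.maximum(lo - a, 0.0)
            g[..., j] = np.where(sup, gj, 0.0)
        return g

    # -- public evaluation --------------------------------------------------

    def value(self, volume: TensorVolume) -> ObjectiveValue:
        data_term, _, _, _ = self.data_value_and_grad(volume, want_grad=False)
        return ObjectiveValue(
            data_term=data_term,
            orientation_term=orientation_regularizer(volume),
            coeff_penalty=coeff_penalty(volume, self.bounds_spec),
            mu=self.mu,
            lam=self.lam,
        )

    def value_and_grad(self, volume: TensorVolume, which: str = "both"):
        data_term, g_c, g_t, g_p = self.data_value_and_grad(volume, which=which)
        val = ObjectiveValue(
            data_term=data_term,
            orientation_term=orientation_regularizer(volume),
            coeff_penalty=coeff_penalty(volume, self.bounds_spec),
            mu=self.mu,
            lam=self.lam,
        )
        shape = volume.shape
        if g_c is None:
            g_c = np.zeros_like(volume.coeffs)
        elif self.lam != 0.0:
            g_c = g_c + self.lam * self._penalty_grad(volume)
        if g_t is None:
            g_t = np.zeros(shape)
            g_p = np.zeros(shape)
        elif self.mu != 0.0:
            rt, rp = self._orientation_grad(volume)
            g_t = g_t + self.mu * rt
            g_p = g_p + self.mu * rp
        out = ~volume.support
        g_c[out] = 0.0
        g_t[out] = 0.0
        g_p[out] = 0.0
        return val, GradientSet(d_coeffs=g_c, d_theta=g_t, d_phi=g_p)


def _ref_vectors(u: np.ndarray) -> np.ndarray:
    from .harmonics import _reference_vectors

    return _reference_vectors(u)


def _frame_derivative(u: np.ndarray, e1: np.ndarray, du: np.ndarray):
    """Derivatives of the local frame (e1, e2) for a zenith perturbation du."""
    r = _ref_vectors(u)
    ru = np.einsum("nj,nj->n", r, u)
    rdu = np.einsum("nj,nj->n", r, du)
    v = r - ru[:, None] * u
    vnorm = np.linalg.norm(v, axis=1)
    dv = -rdu[:, None] * u - ru[:, None] * du
    de1 = (dv - np.einsum("nj,nj->n", e1, dv)[:, None] * e1) / vnorm[:, None]
    de2 = np.cross(du, e1) + np.cross(u, de1)
    return de1, de2


# ---------------------------------------------------------------------------
# public operations

def grad_total(volume: TensorVolume, data, det: DetectorGeometry,
               mu: float = 0.0, lam: float = 0.0, which: str = "both",
               mode: str = "amplitude", bounds_spec: dict | None = None) -> GradientSet:
    """Analytic gradient of the total objective for the selected block(s)."""
    if which not in _BLOCKS:
        raise ValueError(f"unknown parameter block {which!r}")
    problem = TTProblem(data, det, mu=mu, lam=lam, mode=mode, bounds_spec=bounds_spec)
    _, grads = problem.value_and_grad(volume, which=which)
    return grads


def finite_difference_oracle(volume: TensorVolume, data, det: DetectorGeometry,
                             param_index, step: float,
                             mu: float = 0.0, lam: float = 0.0,
                             mode: str = "amplitude",
                             bounds_spec: dict | None = None) -> float:
    """Central finite difference of the total objective in one parameter.

    ``param_index`` is ("coeff", ix, iy, iz, j), ("theta", ix, iy, iz) or
    ("phi", ix, iy, iz).
    """
    if step == 0:
        raise ValueError("step must be non-zero")
    step = abs(step)  # central difference: symmetric in the step sign

    def _eval(delta: float) -> float:
        v = volume.copy()
        kind = param_index[0]
        if kind == "coeff":
            _, ix, iy, iz, j = param_index
            v.coeffs[ix, iy, iz, j] += delta
        elif kind == "theta":
            _, ix, iy, iz = param_index
            v.theta[ix, iy, iz] += delta
        elif kind == "phi":
            _, ix, iy, iz = param_index
            v.phi[ix, iy, iz] += delta
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
        return total_objective(v, data, det, mu=mu, lam=lam, mode=mode,
                               bounds_spec=bounds_spec).total

    return (_eval(step) - _eval(-step)) / (2.0 * step)
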