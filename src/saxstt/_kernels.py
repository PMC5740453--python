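"""Fused numba kernels for the zonal (m = 0) evaluation hot path.

The reconstruction objective evaluates, for every (orientation, voxel,
segment) triple, a short even-degree Legendre series in t = u . q and its
derivative.  Doing this with numpy materializes several hundred megabytes of
temporaries per pass; the fused loops below keep everything in registers.
Legendre values use the standard three-term recurrence and derivatives the
recurrence P'_l = P'_{l-2} + (2l - 1) P_{l-1}, both stable on [-1, 1].

Importing numba is optional: callers must check ``HAVE_NUMBA`` and fall back
to the vectorized numpy path otherwise.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(fastmath=True, cache=False)
def zonal_forward(u, cs, degrees, q, A, t):
    """Amplitude A[c, n, k] = sum_j cs[n, j] P_{l_j}(u[n] . q[c, k]).

    ``cs`` are coefficients with the zonal normalization folded in; ``t`` is
    filled with the clamped direction cosines for reuse in the backward pass.
    """
    C, K, _ = q.shape
    N = u.shape[0]
    J = degrees.shape[0]
    lmax = degrees[J - 1]
    for c in range(C):
        for n in range(N):
            ux, uy, uz = u[n, 0], u[n, 1], u[n, 2]
            for k in range(K):
                tt = ux * q[c, k, 0] + uy * q[c, k, 1] + uz * q[c, k, 2]
                if tt > 1.0:
                    tt = 1.0
                elif tt < -1.0:
                    tt = -1.0
                acc = 0.0
                j = 0
                p_prev = 1.0  # P_0
                if degrees[0] == 0:
                    acc += cs[n, 0]
                    j = 1
                p_curr = tt  # P_1
                for l in range(2, lmax + 1):
                    p_next = ((2 * l - 1) * tt * p_curr - (l - 1) * p_prev) / l
                    p_prev = p_curr
                    p_curr = p_next
                    if j < J and degrees[j] == l:
                        acc += cs[n, j] * p_curr
                        j += 1
                t[c, n, k] = tt
                A[c, n, k] = acc


@njit(fastmath=True, cache=False)
def zonal_backward(u, du_th, du_ph, cs, norms, degrees, q, G, A, t,
                   g_coeffs, g_theta, g_phi, want_coeffs, want_angles):
    """Accumulate data-term gradients from the backprojected residual G.

    F = 2 G A is the sensitivity of the misfit to the per-voxel amplitude;
    coefficients receive F norm_j P_{l_j}(t) and the zenith angles
    F (dA/dt) (du/dangle . q).
    """
    C, K, _ = q.shape
    N = u.shape[0]
    J = degrees.shape[0]
    lmax = degrees[J - 1]
    for c in range(C):
        for n in range(N):
            for k in range(K):
                F = 2.0 * G[c, n, k] * A[c, n, k]
                if F == 0.0:
                    continue
                tt = t[c, n, k]
                dAdt = 0.0
                j = 0
                p_prev = 1.0  # P_0
                dp_prev = 0.0
                if degrees[0] == 0:
                    if want_coeffs:
                        g_coeffs[n, 0] += F * norms[0]
                    j = 1
                p_curr = tt
                dp_curr = 1.0
                for l in range(2, lmax + 1):
                    p_next = ((2 * l - 1) * tt * p_curr - (l - 1) * p_prev) / l
                    dp_next = dp_prev + (2 * l - 1) * p_curr
                    p_prev, p_curr = p_curr, p_next
                    dp_prev, dp_curr = dp_curr, dp_next
                    if j < J and degrees[j] == l:
                        if want_coeffs:
                            g_coeffs[n, j] += F * norms[j] * p_curr
                        if want_angles:
                            dAdt += cs[n, j] * dp_curr
                        j += 1
                if want_angles and dAdt != 0.0:
                    qx, qy, qz = q[c, k, 0], q[c, k, 1], q[c, k, 2]
                    g_theta[n] += F * dAdt * (
                        du_th[n, 0] * qx + du_th[n, 1] * qy + du_th[n, 2] * qz
                    )
                    g_phi[n] += F * dAdt * (
                        du_ph[n, 0] * qx + du_ph[n, 1] * qy + du_ph[n, 2] * qz
                    )


def warmup() -> None:
    """Trigger JIT compilation on a tiny problem (a few seconds, once)."""
    if not HAVE_NUMBA:
        return
    u = np.array([[0.0, 0.0, 1.0]])
    cs = np.array([[1.0, 0.1]])
    degrees = np.array([0, 2], dtype=np.int64)
    q = np.zeros((1, 2, 3))
    q[0, :, 0] = 1.0
    A = np.zeros((1, 1, 2))
    t = np.zeros((1, 1, 2))
    zonal_forward(u, cs, degrees, q, A, t)
    zonal_backward(u, u, u, cs, np.array([1.0, 1.0]), degrees, q, A.copy(), A, t,
                   np.zeros((1, 2)), np.zeros(1), np.zeros(1), True, True)
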