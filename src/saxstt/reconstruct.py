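"""Four-step reconstruction schedule over a nonlinear conjugate-gradient core.

The optimization runs in four steps to accelerate convergence:

1. isotropic term only, against azimuthally averaged data (gives a first
   estimate of a00 and, by thresholding it, the binary support mask);
2. zenith angles only, with the anisotropic coefficients frozen at fixed
   ratios s_l of the local a00;
3. all coefficients, angles frozen;
4. everything jointly.

The core is Polak-Ribiere nonlinear CG with periodic restarts and an Armijo
backtracking line search; analytic gradients come from the gradients module
and may be sieve-smoothed per iteration.  The L-curve sweep for the
orientation-regularization strength mu reports the maximum-curvature corner
but leaves the final choice to the user (visual inspection may override).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .forward_model import (
    DetectorGeometry,
    TensorVolume,
    batched_ray_operators,
    _convolve_segments,
)
from .gradients import GradientSet, TTProblem, sieve_smooth
from .harmonics import SHBasisSpec
from .objective import (
    ObjectiveValue,
    coeff_penalty,
    normalize_stack,
    orientation_regularizer,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "cg_minimize",
    "step1_isotropic",
    "make_support",
    "step2_angles",
    "step3_coeffs",
    "step4_joint",
    "reconstruct_full",
    "l_curve",
]

_FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tunable settings of the four-step reconstruction.

    ``step_ratios`` maps degree l > 0 to the factor s_l fixing a_l0 = s_l a00
    during the angle-only step; the defaults give an equatorial-band map
    typical of fibril scattering and should be treated as tunable (re-running
    with different constants guards against local minima).  ``max_iter`` and
    ``tol`` are per-step CG controls; ``support_threshold`` is the a00
    fraction used to build the support mask after step 1.
    """

    basis: SHBasisSpec = field(default_factory=SHBasisSpec)
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)
    step_ratios: dict = field(default_factory=lambda: {2: -0.3, 4: 0.1, 6: -0.05})
    sieve_window: int | None = 3
    mu: float = 0.0
    lam: float = 0.0
    bounds_spec: dict | None = None
    residual_mode: str = "amplitude"
    max_iter: dict = field(default_factory=lambda: {1: 40, 2: 40, 3: 40, 4: 60})
    tol: float = 1e-7
    restart: int = 20
    support_threshold: float = 0.05
    support_closing: bool = False
    seed: int = 0
    voxel_size: float = 1.0


@dataclass
class ReconstructionResult:
    volume: TensorVolume
    objective_trace: list
    step_boundaries: list
    statuses: list
    config: ReconstructionConfig


# ---------------------------------------------------------------------------
# conjugate-gradient core

def cg_minimize(fun, grad, x0: np.ndarray, max_iter: int, tol: float,
                restart: int = 20, callback=None):
    """Polak-Ribiere nonlinear CG with Armijo backtracking.

    ``fun(x) -> float``; ``grad(x) -> array``.  Restarts to steepest descent
    every ``restart`` iterations or whenever the conjugate direction stops
    being a descent direction.  Stops on relative objective change below
    ``tol``, on max_iter, or with status "stalled" when no decrease can be
    found along steepest descent at the minimal step.
    """
    c1 = 1e-4
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    g = grad(x)
    d = -g
    alpha_prev = None
    status = "max_iter"
    for it in range(max_iter):
        if np.linalg.norm(g) == 0.0:
            status = "converged"
            break
        if it > 0 and it % restart == 0:
            d = -g
        slope = float(g @ d)
        if slope >= 0.0:
            d = -g
            slope = float(g @ d)
            if slope >= 0.0:
                status = "converged"
                break
        # expected-decrease initial step, warm-started from the last accepted one
        alpha = alpha_prev * 2.0 if alpha_prev else min(1.0, 2.0 * max(f, 1e-30) / -slope)
        accepted = False
        for _ in range(40):
            f_new = fun(x + alpha * d)
            denom = 2.0 * (f_new - f - slope * alpha)
            alpha_q = -slope * alpha * alpha / denom if denom > 0 else None
            if f_new <= f + c1 * alpha * slope:
                # one interpolation refinement toward the 1D minimizer (makes
                # the search near-exact on locally quadratic objectives)
                if alpha_q is not None and abs(alpha_q - alpha) > 1e-3 * alpha:
                    f_q = fun(x + alpha_q * d)
                    if f_q < f_new and f_q <= f + c1 * alpha_q * slope:
                        alpha, f_new = alpha_q, f_q
                accepted = True
                break
            # interpolated backtracking, safeguarded into [0.1, 0.5] alpha
            alpha = min(max(alpha_q, 0.1 * alpha), 0.5 * alpha) if alpha_q else 0.5 * alpha
        if not accepted:
            if not np.array_equal(d, -g):
                d = -g
                alpha_prev = None
                continue
            status = "stalled"
            break
        x = x + alpha * d
        alpha_prev = alpha
        g_new = grad(x)
        beta = max(0.0, float(g_new @ (g_new - g)) / max(float(g @ g), 1e-300))
        d = -g_new + beta * d
        rel_drop = (f - f_new) / max(abs(f), 1e-30)
        f, g = f_new, g_new
        if callback is not None:
            callback(x, f)
        if rel_drop < tol:
            status = "converged"
            break
    return x, f, status


# ---------------------------------------------------------------------------
# parameter packing

class _ParamView:
    """Maps the active parameter block of a volume to/from a flat vector."""

    def __init__(self, volume: TensorVolume, coeff_cols, angles: bool):
        self.volume = volume
        self.coeff_cols = list(coeff_cols)
        self.angles = angles
        self.idx = np.flatnonzero(volume.support.ravel())
        self.n_sup = self.idx.size
        self.n_c = self.n_sup * len(self.coeff_cols)

    def pack(self) -> np.ndarray:
        v = self.volume
        parts = []
        if self.coeff_cols:
            parts.append(v.coeffs.reshape(-1, v.basis.size)[self.idx][:, self.coeff_cols].ravel())
        if self.angles:
            parts.append(v.theta.reshape(-1)[self.idx])
            parts.append(v.phi.reshape(-1)[self.idx])
        return np.concatenate(parts) if parts else np.zeros(0)

    def unpack(self, x: np.ndarray) -> None:
        v = self.volume
        if self.coeff_cols:
            block = x[: self.n_c].reshape(self.n_sup, len(self.coeff_cols))
            flat = v.coeffs.reshape(-1, v.basis.size)
            for k, j in enumerate(self.coeff_cols):
                flat[self.idx, j] = block[:, k]
        if self.angles:
            v.theta.reshape(-1)[self.idx] = x[self.n_c: self.n_c + self.n_sup]
            v.phi.reshape(-1)[self.idx] = x[self.n_c + self.n_sup:]

    def pack_grad(self, grads: GradientSet) -> np.ndarray:
        parts = []
        if self.coeff_cols:
            parts.append(
                grads.d_coeffs.reshape(-1, self.volume.basis.size)[self.idx][:, self.coeff_cols].ravel()
            )
        if self.angles:
            parts.append(grads.d_theta.reshape(-1)[self.idx])
            parts.append(grads.d_phi.reshape(-1)[self.idx])
        return np.concatenate(parts) if parts else np.zeros(0)


def _run_block(problem: TTProblem, volume: TensorVolume, coeff_cols, angles: bool,
               which: str, config: ReconstructionConfig, step: int, trace: list):
    """Run one CG block on the selected parameters of ``volume`` in place."""
    view = _ParamView(volume, coeff_cols, angles)
    smooth_coeffs = bool(coeff_cols) and config.sieve_window not in (None, "none")

    def fun(x):
        view.unpack(x)
        return problem.value(volume).total

    def grad(x):
        view.unpack(x)
        _, grads = problem.value_and_grad(volume, which=which)
        if smooth_coeffs:
            grads = sieve_smooth(grads, config.sieve_window, volume.support)
        return view.pack_grad(grads)

    def cb(x, f):
        # recover the parts from the (cheap) regularizer values; the data
        # term follows from the accepted total without a second forward pass
        view.unpack(x)
        ru = orientation_regularizer(volume)
        pen = coeff_penalty(volume, problem.bounds_spec)
        trace.append(
            ObjectiveValue(
                data_term=f - problem.mu * ru - problem.lam * pen,
                orientation_term=ru,
                coeff_penalty=pen,
                mu=problem.mu,
                lam=problem.lam,
            )
        )

    x0 = view.pack()
    x, _, status = cg_minimize(
        fun, grad, x0,
        max_iter=config.max_iter.get(step, 40),
        tol=config.tol,
        restart=config.restart,
        callback=cb,
    )
    view.unpack(x)
    return status


# ---------------------------------------------------------------------------
# step 1: isotropic component against azimuthally averaged data

class _IsotropicProblem:
    """Misfit of an isotropic (a00-only) model against phi-averaged data."""

    def __init__(self, data, det: DetectorGeometry, mode: str):
        self.mode = mode
        normalized, _ = normalize_stack(data)
        self.entries = []
        for d_norm, w, orient in normalized:
            nvalid = w.sum(axis=-1)
            avg = np.where(nvalid > 0, (d_norm * w).sum(axis=-1) / np.maximum(nvalid, 1), 0.0)
            self.entries.append(
                {
                    "orientation": orient,
                    "avg": avg,
                    "sqrt_avg": np.sqrt(np.maximum(avg, 0.0)),
                    "mask": nvalid > 0,
                }
            )
        self._batches_key = None

    def mean_data(self) -> float:
        vals = [e["avg"][e["mask"]] for e in self.entries]
        allv = np.concatenate([v for v in vals if v.size])
        return float(allv.mean()) if allv.size else 0.0

    def _batches(self, shape):
        if self._batches_key == shape:
            return self._batch_list
        ops = batched_ray_operators(shape, [e["orientation"] for e in self.entries])
        out = []
        for op in ops:
            chunk = self.entries[op["sl"]]
            out.append(
                {
                    "B": op["B"],
                    "BT": op["BT"],
                    "npix": op["npix"],
                    "C": len(chunk),
                    "avg": np.stack([e["avg"] for e in chunk]),
                    "sqrt_avg": np.stack([e["sqrt_avg"] for e in chunk]),
                    "mask": np.stack([e["mask"] for e in chunk]),
                }
            )
        self._batch_list = out
        self._batches_key = shape
        return out

    def value_and_grad(self, a00: np.ndarray, want_grad: bool = True):
        shape = a00.shape
        n = a00.size
        iso = (a00 * a00).reshape(-1) / _FOUR_PI
        value = 0.0
        g = np.zeros(n) if want_grad else None
        for b in self._batches(shape):
            C, npix = b["C"], b["npix"]
            img = (b["B"] @ np.tile(iso, C)).reshape(C, npix, npix, 1)
            img = _convolve_segments(img)[..., 0]
            w = b["mask"]
            if self.mode == "amplitude":
                sq = np.sqrt(np.maximum(img, 1e-30))
                r = np.where(w, sq - b["sqrt_avg"], 0.0)
                value += float(np.sum(r * r))
                dres = r / sq
            else:
                r = np.where(w, img - b["avg"], 0.0)
                value += float(np.sum(r * r))
                dres = 2.0 * r
            if want_grad:
                back = b["BT"] @ _convolve_segments(dres[..., None]).reshape(-1)
                g += back.reshape(C, n).sum(axis=0)
        if want_grad:
            g = g * (2.0 * a00.reshape(-1) / _FOUR_PI)
            return value, g.reshape(shape)
        return value, None


def step1_isotropic(data, config: ReconstructionConfig, shape) -> np.ndarray:
    """Per-voxel isotropic amplitude a00 fitted to phi-averaged data.

    The a00 gradient is sieve-smoothed like any other coefficient gradient:
    the anti-aliasing kernel nulls transverse-Nyquist intensity patterns, so
    without the sieve the quasi-invisible voxel-scale modes fill with noise.
    """
    prob = _IsotropicProblem(data, config.detector, config.residual_mode)
    mean_d = max(prob.mean_data(), 1e-12)
    # data-scaled positive start (zero is a stationary point of A^2 models)
    a0 = np.full(shape, np.sqrt(_FOUR_PI * mean_d / max(shape)))
    window = None
    if config.sieve_window not in (None, "none"):
        from .gradients import hamming_window_3d

        window = hamming_window_3d(int(config.sieve_window))

    def fun(x):
        v, _ = prob.value_and_grad(x.reshape(shape), want_grad=False)
        return v

    def grad(x):
        _, g = prob.value_and_grad(x.reshape(shape))
        if window is not None:
            g = ndimage.convolve(g, window, mode="constant", cval=0.0)
        return g.reshape(-1)

    x, _, status = cg_minimize(
        fun, grad, a0.reshape(-1),
        max_iter=config.max_iter.get(1, 50), tol=config.tol, restart=config.restart,
    )
    logger.info("step 1 finished (%s)", status)
    return x.reshape(shape)


def make_support(a00_volume: np.ndarray, threshold_fraction: float,
                 closing: bool = False) -> np.ndarray:
    """Binary support mask from a thresholded isotropic component."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    peak = float(np.max(a00_volume))
    if peak <= 0.0:
        logger.warning("all-zero isotropic component; support mask is empty")
        return np.zeros(np.shape(a00_volume), dtype=bool)
    mask = np.asarray(a00_volume) > threshold_fraction * peak
    if closing:
        mask = ndimage.binary_closing(mask)
    return mask


# ---------------------------------------------------------------------------
# steps 2-4

def _freeze_ratio_coeffs(volume: TensorVolume, step_ratios: dict) -> None:
    """Set a_l0 = s_l a00 for l > 0 (zero for any m != 0 members)."""
    basis = volume.basis
    a00 = volume.coeffs[..., basis.index_of(0, 0)]
    for j, (l, m) in enumerate(basis.lm_pairs):
        if l == 0:
            continue
        if m == 0:
            volume.coeffs[..., j] = step_ratios.get(l, 0.0) * a00
        else:
            volume.coeffs[..., j] = 0.0


def _make_problem(data, config: ReconstructionConfig) -> TTProblem:
    return TTProblem(
        data, config.detector, mu=config.mu, lam=config.lam,
        mode=config.residual_mode, bounds_spec=config.bounds_spec,
    )


def step2_angles(volume: TensorVolume, data, config: ReconstructionConfig,
                 trace: list | None = None) -> TensorVolume:
    """Freeze a_l0 = s_l a00 and optimize the zenith angles only."""
    volume = volume.copy()
    _freeze_ratio_coeffs(volume, config.step_ratios)
    trace = trace if trace is not None else []
    _run_block(_make_problem(data, config), volume, coeff_cols=[], angles=True,
               which="angles", config=config, step=2, trace=trace)
    return volume

def step3_coeffs(volume: TensorVolume, data, config: ReconstructionConfig,
                 trace: list | None = None) -> TensorVolume:
    """Optimize all coefficients with the zenith angles frozen."""
    volume = volume.copy()
    trace = trace if trace is not None else []
    _run_block(_make_problem(data, config), volume,
               coeff_cols=list(range(volume.basis.size)), angles=False,
               which="coeffs", config=config, step=3, trace=trace)
    return volume


def step4_joint(volume: TensorVolume, data, config: ReconstructionConfig,
                trace: list | None = None) -> TensorVolume:
    """Optimize all coefficients and both zenith angles simultaneously."""
    volume = volume.copy()
    trace = trace if trace is not None else []
    _run_block(_make_problem(data, config), volume,
               coeff_cols=list(range(volume.basis.size)), angles=True,
               which="both", config=config, step=4, trace=trace)
    return volume


def _init_angles(volume: TensorVolume, seed: int) -> None:
    """Deterministic uniform-hemisphere zenith initialization."""
    rng = np.random.default_rng(seed)
    n = volume.n_voxels
    z = rng.uniform(0.0, 1.0, n)  # cos(theta) on the upper hemisphere
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    volume.theta[...] = np.arccos(z).reshape(volume.shape)
    volume.phi[...] = phi.reshape(volume.shape)


def reconstruct_full(data, config: ReconstructionConfig, shape=None) -> ReconstructionResult:
    """Run the full four-step schedule on a measured stack.

    The volume shape defaults to a cube inferred from the raster size.
    Deterministic for a fixed config (the seed only drives the zenith
    initialization before step 2).
    """
    if shape is None:
        npix = data[0].intensities.shape[0]
        n = int(np.floor((npix - 4) / np.sqrt(3.0)))
        shape = (n, n, n)
    statuses = []
    trace: list = []
    boundaries = []

    a00 = step1_isotropic(data, config, shape)
    support = make_support(a00, config.support_threshold, config.support_closing)
    statuses.append("step1 done")
    boundaries.append(len(trace))

    volume = TensorVolume.zeros(shape, config.basis, voxel_size=config.voxel_size)
    volume.support = support
    # vacuum outside the support: those parameters are frozen, so any
    # leftover step-1 amplitude there would project as an un-correctable
    # background; inside, smooth the start (a support-normalized Hamming
    # average) so the weakly-determined voxel-scale modes start clean
    from .gradients import hamming_window_3d

    w3 = hamming_window_3d(3)
    num = ndimage.convolve(np.where(support, a00, 0.0), w3, mode="constant")
    den = ndimage.convolve(support.astype(float), w3, mode="constant")
    a00_smooth = np.where(support, num / np.maximum(den, 1e-12), 0.0)
    volume.coeffs[..., config.basis.index_of(0, 0)] = a00_smooth
    _init_angles(volume, config.seed)

    volume = step2_angles(volume, data, config, trace)
    boundaries.append(len(trace))
    volume = step3_coeffs(volume, data, config, trace)
    boundaries.append(len(trace))
    volume = step4_joint(volume, data, config, trace)
    boundaries.append(len(trace))
    return ReconstructionResult(
        volume=volume,
        objective_trace=trace,
        step_boundaries=boundaries,
        statuses=statuses,
        config=config,
    )


# ---------------------------------------------------------------------------
# L-curve

@dataclass
class LCurveResult:
    points: list  # (mu, data_term, orientation_term)
    selected_mu: float | None
    results: list


def l_curve(data, config: ReconstructionConfig, mu_list,
            warm_start: bool = True) -> LCurveResult:
    """Sweep the orientation-regularization strength and locate the corner.

    One reconstruction per mu, warm-started from the previous solution (a
    joint refinement step) by default; ``warm_start=False`` runs each mu
    from scratch, which spends more time but makes the per-mu solutions
    equally converged (useful when comparing the two error terms across the
    sweep).  The corner is the maximum-curvature point of the log-log curve
    (data error vs orientation penalty); it is reported, not silently
    applied -- visual inspection of the solutions may override it.
    """
    mu_list = [float(m) for m in mu_list]
    if any(b < a for a, b in zip(mu_list, mu_list[1:])):
        raise ValueError("mu_list must be ascending")
    points = []
    results = []
    volume = None
    for mu in mu_list:
        cfg = replace(config, mu=mu)
        if volume is None or not warm_start:
            res = reconstruct_full(data, cfg)
            volume = res.volume
        else:
            trace: list = []
            volume = step4_joint(volume, data, cfg, trace)
            res = ReconstructionResult(volume, trace, [len(trace)], ["warm"], cfg)
        problem = _make_problem(data, replace(cfg, mu=0.0))
        val = problem.value(volume)
        points.append((mu, val.data_term, val.orientation_term))
        results.append(res)

    selected = None
    if len(points) >= 4:
        x = np.log(np.maximum([p[1] for p in points], 1e-300))
        y = np.log(np.maximum([p[2] for p in points], 1e-300))
        dx, dy = np.gradient(x), np.gradient(y)
        ddx, ddy = np.gradient(dx), np.gradient(dy)
        kappa = (dx * ddy - dy * ddx) / np.maximum((dx * dx + dy * dy) ** 1.5, 1e-300)
        selected = mu_list[int(np.argmax(kappa[1:-1])) + 1]
    else:
        logger.warning("fewer than 4 mu values; corner not estimated")
    return LCurveResult(points=points, selected_mu=selected, results=results)
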