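"""Acquisition geometry for two-axis scanning-SAXS tomography.

A sample orientation is described by a tomographic rotation ``alpha`` about the
object y axis followed by a tilt ``beta`` of that rotation axis about the lab x
axis.  Both rotations are active, right-handed, and map object coordinates to
laboratory coordinates (the beam travels along lab z).  Angles are degrees at
every public interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleOrientation",
    "OrientationGrid",
    "rotation_matrix",
    "beam_direction_object",
    "orientation_grid",
    "subset_grid",
]

_EPS = 1e-9


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"angle {name!r} must be finite, got {value}")
    return value


def _rot_y(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_matrix(alpha: float, beta: float) -> np.ndarray:
    """Object-to-lab rotation: R = R_x(beta) @ R_y(alpha), angles in degrees.

    ``p_lab = R @ p_obj``.  ``rotation_matrix(90, 0)`` maps the object z axis
    onto the lab x axis.
    """
    alpha = _check_finite("alpha", alpha)
    beta = _check_finite("beta", beta)
    return _rot_x(np.deg2rad(beta)) @ _rot_y(np.deg2rad(alpha))


@dataclass(frozen=True)
class SampleOrientation:
    """One (alpha, beta) sample orientation with its rotation matrix."""

    alpha: float
    beta: float
    R: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.R is None:
            object.__setattr__(self, "R", rotation_matrix(self.alpha, self.beta))
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("R is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("R is not a proper rotation")


def beam_direction_object(orientation: SampleOrientation) -> np.ndarray:
    """Unit beam direction (lab z) expressed in object coordinates, R^T z."""
    b = orientation.R.T @ np.array([0.0, 0.0, 1.0])
    return b / np.linalg.norm(b)


def _axis_values(start: float, stop: float, step: float, include_stop: bool) -> np.ndarray:
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    span = stop - start
    if span < 0:
        raise ValueError("empty range")
    n = int(np.floor(span / step + _EPS))
    values = start + step * np.arange(n + 1)
    if not include_stop:
        values = values[values < stop - _EPS * max(1.0, abs(stop))]
    return values


@dataclass(frozen=True)
class OrientationGrid:
    """Ordered Cartesian product of alpha and beta values (beta-major)."""

    orientations: tuple
    alpha_values: tuple
    beta_values: tuple
    alpha_step: float
    beta_step: float

    def __len__(self) -> int:
        return len(self.orientations)

    def __iter__(self):
        return iter(self.orientations)

    def __getitem__(self, i):
        return self.orientations[i]


def _build_grid(alpha_values, beta_values, alpha_step, beta_step) -> OrientationGrid:
    pairs = set()
    orientations = []
    for b in beta_values:
        for a in alpha_values:
            key = (round(float(a), 9), round(float(b), 9))
            if key in pairs:
                raise ValueError(f"duplicate orientation {key}")
            pairs.add(key)
            orientations.append(SampleOrientation(float(a), float(b)))
    return OrientationGrid(
        orientations=tuple(orientations),
        alpha_values=tuple(float(a) for a in alpha_values),
        beta_values=tuple(float(b) for b in beta_values),
        alpha_step=float(alpha_step),
        beta_step=float(beta_step),
    )


def orientation_grid(
    alpha_step: float = 4.5,
    alpha_range: tuple = (0.0, 180.0),
    beta_step: float = 15.0,
    beta_range: tuple = (-30.0, 45.0),
) -> OrientationGrid:
    """Two-axis acquisition grid.

    alpha is sampled on the half-open interval [start, stop): an even-degree
    reciprocal-space map is point symmetric, so alpha and alpha + 180 deg are
    redundant.  beta is sampled on the closed interval, including the stop
    value when the step divides the span.  The default settings give the
    240-orientation grid (40 alpha x 6 beta).
    """
    alphas = _axis_values(alpha_range[0], alpha_range[1], alpha_step, include_stop=False)
    betas = _axis_values(beta_range[0], beta_range[1], beta_step, include_stop=True)
    if len(alphas) == 0 or len(betas) == 0:
        raise ValueError("empty orientation grid")
    return _build_grid(alphas, betas, alpha_step, beta_step)


def subset_grid(
    grid: OrientationGrid,
    alpha_keep_step: float | None = None,
    beta_keep_step: float | None = None,
    beta_values: tuple | None = None,
) -> OrientationGrid:
    """Decimate an acquisition grid for sampling studies.

    Keep-steps must be integer multiples of the native steps.  alpha decimation
    is anchored at the smallest alpha; beta decimation is anchored at beta = 0
    when present (so dbeta = 30 on the [-30, 45] grid keeps {-30, 0, 30}).
    ``beta_values`` selects an explicit beta subset instead, e.g. ``(0.0,)``
    for single-axis tomography.
    """

    def _decimate(values, native_step, keep_step, anchor):
        if keep_step is None:
            return values, native_step
        ratio = keep_step / native_step
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"keep step {keep_step} is not an integer multiple of native step {native_step}"
            )
        kept = [v for v in values if abs((v - anchor) / keep_step - round((v - anchor) / keep_step)) < 1e-9]
        return tuple(kept), float(keep_step)

    alphas = grid.alpha_values
    betas = grid.beta_values
    alpha_anchor = min(alphas)
    beta_anchor = 0.0 if any(abs(b) < 1e-9 for b in betas) else min(betas)

    alphas, alpha_step = _decimate(alphas, grid.alpha_step, alpha_keep_step, alpha_anchor)
    if beta_values is not None:
        requested = []
        for bv in beta_values:
            matches = [b for b in betas if abs(b - bv) < 1e-9]
            if not matches:
                raise ValueError(f"beta value {bv} not in grid")
            requested.append(matches[0])
        betas, beta_step = tuple(requested), grid.beta_step
    else:
        betas, beta_step = _decimate(betas, grid.beta_step, beta_keep_step, beta_anchor)

    if len(alphas) == 0 or len(betas) == 0:
        raise ValueError("subset grid is empty")
    return _build_grid(alphas, betas, alpha_step, beta_step)
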