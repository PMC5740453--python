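"""Masked, absorption-normalized data misfit and regularization terms.

The default data term compares square roots of modelled and measured
intensities, a first-order approximation to the Poisson maximum-likelihood
metric for photon counting; a plain intensity-residual mode is kept as a
documented alternative.  Measured intensities are divided by the transmitted
intensity to compensate for sample absorption before comparison.  Two
regularizers can be added: a neighbor-orientation penalty based on the
absolute dot product between adjacent zeniths (compatible with the u -> -u
point-symmetry ambiguity) weighted by mu, and an optional smooth hinge
penalty on coefficient bounds weighted by lambda (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import DetectorGeometry, ProjectionImage, TensorVolume, project
from .geometry import SampleOrientation

__all__ = [
    "MeasuredProjection",
    "ObjectiveValue",
    "absorption_normalize",
    "normalize_stack",
    "data_misfit",
    "orientation_regularizer",
    "orientation_pair_count",
    "coeff_penalty",
    "total_objective",
]

_SQRT_FLOOR = 1e-30  # guards sqrt(0) in the amplitude residual


@dataclass
class MeasuredProjection:
    """Measured (or simulated) scanning-SAXS raster for one orientation."""

    intensities: np.ndarray  # (nx, ny, K), photon-count scale
    transmission: np.ndarray  # (nx, ny), in (0, 1]
    mask: np.ndarray  # (nx, ny, K), binary validity mask W
    orientation: SampleOrientation

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape mismatch")
        if self.transmission.shape != self.intensities.shape[:2]:
            raise ValueError("transmission shape mismatch")


@dataclass
class ObjectiveValue:
    """Unweighted objective terms; the total is combined on read."""

    data_term: float
    orientation_term: float
    coeff_penalty: float
    mu: float
    lam: float

    @property
    def total(self) -> float:
        return self.data_term + self.mu * self.orientation_term + self.lam * self.coeff_penalty


# ---------------------------------------------------------------------------
# data term

def absorption_normalize(raw: np.ndarray, transmission: np.ndarray) -> np.ndarray:
    """Divide measured intensities by the transmitted intensity, per pixel."""
    raw = np.asarray(raw, dtype=float)
    transmission = np.asarray(transmission, dtype=float)
    return raw / transmission[..., None]


def normalize_stack(projections) -> tuple:
    """Absorption-normalize a stack; non-positive-T pixels are masked out.

    Returns (list of (normalized intensities, mask, orientation), n_bad_pixels).
    """
    out = []
    n_bad = 0
    for p in projections:
        mask = p.mask.copy()
        bad = (p.transmission <= 0) & mask.any(axis=-1)
        n_bad += int(bad.sum())
        mask[bad, :] = False
        T = np.where(p.transmission > 0, p.transmission, 1.0)
        out.append((absorption_normalize(p.intensities, T), mask, p.orientation))
    return out, n_bad


def data_misfit(model, data, mode: str = "amplitude") -> float:
    """Masked misfit between modelled and absorption-normalized measured stacks.

    mode "amplitude": sum of W (sqrt(I_model) - sqrt(I_data))^2 (Poisson-ML
    first-order form); mode "intensity": sum of W (I_model - I_data)^2.
    """
    if mode not in ("amplitude", "intensity"):
        raise ValueError(f"unknown residual mode {mode!r}")
    normalized, _ = normalize_stack(data)
    total = 0.0
    for m, (d, w, orient) in zip(model, normalized, strict=True):
        mi = m.intensities if isinstance(m, ProjectionImage) else np.asarray(m, dtype=float)
        if mi.shape != d.shape:
            raise ValueError("model/data shape mismatch")
        if isinstance(m, ProjectionImage) and (
            m.orientation.alpha != orient.alpha or m.orientation.beta != orient.beta
        ):
            raise ValueError("model/data orientation mismatch")
        if np.any(d[w] < 0):
            raise ValueError("negative masked-in measured intensity")
        if mode == "amplitude":
            r = np.sqrt(np.maximum(mi[w], _SQRT_FLOOR)) - np.sqrt(d[w])
        else:
            r = mi[w] - d[w]
        total += float(np.dot(r, r))
    return total


# ---------------------------------------------------------------------------
# regularization terms

def _neighbor_dots(u: np.ndarray, support: np.ndarray):
    """Yield (|dot|, pair_mask, axis) for forward neighbors along x, y, z."""
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        dot = np.einsum("...i,...i->...", u[sl_a], u[sl_b])
        pair = support[sl_a] & support[sl_b]
        yield dot, pair, axis, sl_a, sl_b


def orientation_regularizer(volume: TensorVolume) -> float:
    """Neighbor-orientation roughness sum of (1 - |u . u'|) over support pairs."""
    u = volume.u_field
    total = 0.0
    for dot, pair, _, _, _ in _neighbor_dots(u, volume.support):
        total += float(np.sum((1.0 - np.abs(dot))[pair]))
    return total


def orientation_pair_count(volume: TensorVolume) -> int:
    """Number of in-support forward neighbor pairs (for normalized roughness)."""
    n = 0
    for _, pair, _, _, _ in _neighbor_dots(volume.u_field, volume.support):
        n += int(pair.sum())
    return n


def coeff_penalty(volume: TensorVolume, bounds_spec: dict | None) -> float:
    """Smooth (quadratic hinge) penalty on coefficients outside per-(l,m) bounds.

    bounds_spec maps (l, m) to (lo, hi); either side may be None.  Returns 0
    when disabled (None) or when every coefficient satisfies its bounds.
    """
    if not bounds_spec:
        return 0.0
    total = 0.0
    sup = volume.support
    for (l, m), (lo, hi) in bounds_spec.items():
        j = volume.basis.index_of(l, m)
        a = volume.coeffs[..., j][sup]
        if hi is not None:
            total += float(np.sum(np.maximum(a - hi, 0.0) ** 2))
        if lo is not None:
            total += float(np.sum(np.maximum(lo - a, 0.0) ** 2))
    return total


def total_objective(volume: TensorVolume, data, det: DetectorGeometry,
                    mu: float = 0.0, lam: float = 0.0,
                    mode: str = "amplitude",
                    bounds_spec: dict | None = None) -> ObjectiveValue:
    """Data term plus weighted regularizers for a measured stack."""
    model = [project(volume, p.orientation, det) for p in data]
    return ObjectiveValue(
        data_term=data_misfit(model, data, mode=mode),
        orientation_term=orientation_regularizer(volume),
        coeff_penalty=coeff_penalty(volume, bounds_spec),
        mu=float(mu),
        lam=float(lam),
    )
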