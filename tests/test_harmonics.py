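import logging

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import saxstt as st
from saxstt.harmonics import (
    SHBasisSpec,
    VoxelSH,
    legendre_even,
    legendre_even_deriv,
    local_polar,
)

SQ4PI = 2.0 * np.sqrt(np.pi)


def _legendre_recurrence(l, m, t):
    """Independent unphased associated-Legendre oracle (upward recurrence)."""
    t = np.asarray(t, dtype=float)
    pmm = np.ones_like(t)
    if m > 0:
        somx2 = np.sqrt(np.maximum(0.0, 1.0 - t * t))
        fact = 1.0
        for _ in range(m):
            pmm = pmm * fact * somx2
            fact += 2.0
    if l == m:
        return pmm
    pmmp1 = t * (2 * m + 1) * pmm
    if l == m + 1:
        return pmmp1
    for ll in range(m + 2, l + 1):
        pll = (t * (2 * ll - 1) * pmmp1 - (ll + m - 1) * pmm) / (ll - m)
        pmm, pmmp1 = pmmp1, pll
    return pmmp1


def _real_sh_oracle(l, m, theta, phi):
    from math import factorial

    am = abs(m)
    n = np.sqrt((2 * l + 1) / (4 * np.pi) * factorial(l - am) / factorial(l + am))
    p = _legendre_recurrence(l, am, np.cos(theta))
    if m > 0:
        return n * p * np.sqrt(2) * np.cos(m * phi)
    if m < 0:
        return n * p * np.sqrt(2) * np.sin(am * phi)
    return n * p


class TestBasisSpec:
    def test_defaults(self, zonal_basis):
        assert zonal_basis.lm_pairs == ((0, 0), (2, 0), (4, 0), (6, 0))
        assert zonal_basis.is_zonal

    def test_odd_degree_rejected(self):
        with pytest.raises(ValueError):
            SHBasisSpec((0, 3))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            SHBasisSpec((2,), {2: (3,)})

    def test_truncation(self, zonal_basis):
        assert zonal_basis.truncated(4).degrees == (0, 2, 4)


class TestRealSphHarm:
    def test_isotropic_constant(self):
        assert np.isclose(st.real_sph_harm(0, 0, 1.1, 2.2), 1.0 / SQ4PI)

    def test_l2_pole_value(self):
        assert np.isclose(st.real_sph_harm(2, 0, 0.0, 0.0), np.sqrt(5 / (4 * np.pi)))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            st.real_sph_harm(2, 3, 0.1, 0.1)

    def test_orthonormality_quadrature(self):
        # Gauss-Legendre in cos(theta) x uniform azimuth: exact for this band
        nodes, weights = np.polynomial.legendre.leggauss(60)
        phi = np.linspace(0, 2 * np.pi, 241)[:-1]
        dphi = phi[1] - phi[0]
        T, P = np.meshgrid(np.arccos(nodes), phi, indexing="ij")
        pairs = [(0, 0), (2, 0), (2, 1), (2, -2), (4, 0), (4, 3), (6, 0), (6, -5)]
        for i, (l1, m1) in enumerate(pairs):
            y1 = st.real_sph_harm(l1, m1, T, P)
            for l2, m2 in pairs[i:]:
                y2 = st.real_sph_harm(l2, m2, T, P)
                integral = np.sum(weights[:, None] * y1 * y2) * dphi
                expected = 1.0 if (l1, m1) == (l2, m2) else 0.0
                assert abs(integral - expected) < 1e-6

    @pytest.mark.parametrize("l,m", [(2, 0), (4, 2), (6, -4), (6, 6)])
    def test_matches_independent_recurrence_oracle(self, l, m):
        rng = np.random.default_rng(5)
        theta = rng.uniform(0.01, np.pi - 0.01, 50)
        phi = rng.uniform(-np.pi, np.pi, 50)
        assert np.allclose(
            st.real_sph_harm(l, m, theta, phi), _real_sh_oracle(l, m, theta, phi),
            atol=1e-12,
        )


class TestLegendreFastPath:
    """The Horner tables used on the hot path agree with the generic forms."""

    @pytest.mark.parametrize("l", [0, 2, 4, 6, 8])
    def test_values_and_derivatives(self, l):
        t = np.linspace(-1, 1, 1001)
        from scipy.special import eval_legendre

        assert np.allclose(legendre_even(l, t), eval_legendre(l, t), atol=1e-12)
        c = np.zeros(l + 1)
        c[l] = 1.0
        dref = np.polynomial.legendre.legval(t, np.polynomial.legendre.legder(c))
        assert np.allclose(legendre_even_deriv(l, t), dref, atol=1e-10)


class TestLocalPolar:
    def test_aligned_and_perpendicular(self):
        u = np.array([0.0, 1.0, 0.0])
        tp, _ = local_polar(u, u)
        assert tp == 0.0
        tp, _ = local_polar(np.array([0.0, 0.0, 1.0]), u)
        assert np.isclose(tp, np.pi / 2)

    def test_theta_rotation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            q = rng.normal(size=3)
            q /= np.linalg.norm(q)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            R = Rotation.random(random_state=rng).as_matrix()
            t1, _ = local_polar(q, u)
            t2, _ = local_polar(R @ q, R @ u)
            assert abs(t1 - t2) < 1e-10

    def test_pole_fallback_is_logged(self, caplog):
        u = np.array([0.0, 0.0, 1.0])
        q = np.array([1.0, 0.0, 0.0])
        with caplog.at_level(logging.INFO, logger="saxstt.harmonics"):
            tp, pp = local_polar(q, u)
        assert np.isclose(tp, np.pi / 2)
        assert any("falling back" in r.message for r in caplog.records)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            local_polar(np.array([2.0, 0, 0]), np.array([0.0, 0, 1.0]))


class TestAmplitudeAndIntensity:
    def test_isotropic_amplitude(self, zonal_basis):
        vox = VoxelSH(coeffs=[3.0, 0, 0, 0], theta_op=0.7, phi_op=1.0)
        q = np.array([0.2, 0.3, np.sqrt(1 - 0.13)])
        assert np.isclose(st.rs_amplitude(vox, zonal_basis, q), 3.0 / SQ4PI)

    def test_point_symmetry(self, zonal_basis):
        rng = np.random.default_rng(9)
        vox = VoxelSH(coeffs=rng.normal(size=4), theta_op=1.0, phi_op=0.5)
        for _ in range(20):
            q = rng.normal(size=3)
            q /= np.linalg.norm(q)
            a1 = st.rs_amplitude(vox, zonal_basis, q)
            a2 = st.rs_amplitude(vox, zonal_basis, -q)
            assert np.isclose(a1 * a1, a2 * a2, rtol=1e-12)

    def test_matches_termwise_recurrence_oracle(self, zonal_basis):
        rng = np.random.default_rng(11)
        coeffs = rng.normal(size=4)
        vox = VoxelSH(coeffs=coeffs, theta_op=1.2, phi_op=-0.4)
        u = vox.u
        for _ in range(50):
            q = rng.normal(size=3)
            q /= np.linalg.norm(q)
            t = np.dot(q, u)
            expected = sum(
                c * np.sqrt((2 * l + 1) / (4 * np.pi)) * _legendre_recurrence(l, 0, t)
                for c, l in zip(coeffs, (0, 2, 4, 6))
            )
            assert np.isclose(st.rs_amplitude(vox, zonal_basis, q), expected, atol=1e-10)

    def test_intensity_map_nonnegative_and_zonal_symmetry(self, zonal_basis):
        vox = VoxelSH(coeffs=[1.0, -0.8, 0.2, 0.0], theta_op=0.9, phi_op=2.0)
        grid = st.fibonacci_sphere(400)
        I = st.rs_intensity_map(vox, zonal_basis, grid)
        assert np.all(I >= 0)
        # zonal maps depend on direction only through the angle to the zenith:
        # directions on a cone around u must share one intensity
        u = vox.u
        e1 = np.cross(u, [0.0, 0.0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        for theta_p in (0.3, 1.1, 2.4):
            ring = [
                np.cos(theta_p) * u + np.sin(theta_p) * (np.cos(a) * e1 + np.sin(a) * e2)
                for a in np.linspace(0, 2 * np.pi, 9)
            ]
            Ir = st.rs_intensity_map(vox, zonal_basis, np.array(ring))
            assert np.allclose(Ir, Ir[0], atol=1e-10)

    def test_squared_sum_touches_zero_but_not_negative(self):
        basis = SHBasisSpec((0, 2))
        # choose a20 so the amplitude changes sign over the sphere
        vox = VoxelSH(coeffs=[1.0, 1.5], theta_op=0.0, phi_op=0.0)
        I = st.rs_intensity_map(vox, basis, st.fibonacci_sphere(2000))
        assert I.min() >= 0.0
        assert I.min() < 1e-4 * I.max()

    def test_constant_map_for_isotropic_voxel(self, zonal_basis):
        vox = VoxelSH(coeffs=[2.0, 0, 0, 0])
        I = st.rs_intensity_map(vox, zonal_basis, st.fibonacci_sphere(100))
        assert np.allclose(I, 4.0 / (4 * np.pi))


class TestCanonicalization:
    def test_hemisphere_and_idempotence(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        c = st.canonicalize_zenith(u)
        assert np.all(c[:, 2] >= 0)
        assert np.allclose(np.abs(np.einsum("ij,ij->i", c, u)), 1.0, atol=1e-12)
        assert np.allclose(st.canonicalize_zenith(c), c)
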