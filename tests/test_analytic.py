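"""Analytic phase-shifting solver: closed form, lattice phases, full-device sums."""

import numpy as np
import pytest
from scipy import integrate

from dmdsim import (
    AngularGrid,
    DMDGeometry,
    TiltPattern,
    analytic_dmd_field,
    angles_to_direction,
    envelope_centre,
    grating_factor,
    lattice_phase,
    make_pattern,
    rotation_matrix,
    single_mirror_field,
)


def _random_case(rng, w_um=7.56):
    a = angles_to_direction(rng.uniform(-60, 60), rng.uniform(-60, 60))
    b = angles_to_direction(rng.uniform(-60, 60), rng.uniform(-60, 60))
    gamma = rng.uniform(-15, 15)
    lam = rng.uniform(0.4, 0.7)
    return a, b, gamma, w_um, lam


def _gauss_legendre_oracle(a, b, gamma, w, lam, order=200):
    """Tensor-product quadrature of the raw 2-D mirror integral.

    Exact to machine precision at this order for the <= ~60 rad phase sweeps
    involved; makes no use of the closed form's separable structure.
    """
    x, wts = np.polynomial.legendre.leggauss(order)
    s = 0.5 * w * (x + 1.0)
    k0 = 2.0 * np.pi / lam
    rot = rotation_matrix(gamma)
    delta = a + b
    qx = k0 * (rot[:, 0] @ delta)
    qy = k0 * (rot[:, 1] @ delta)
    ints = ((0.5 * w * wts) * np.exp(1j * qx * s)).sum() * (
        (0.5 * w * wts) * np.exp(1j * qy * s)
    ).sum()
    # assemble as a genuine 2-D sum for a handful of nodes? full tensor product:
    phase = qx * s[:, None] + qy * s[None, :]
    tensor = np.einsum("i,j,ij->", 0.5 * w * wts, 0.5 * w * wts, np.exp(1j * phase))
    assert abs(tensor - ints) < 1e-9 * w**2  # sanity: same rule, two evaluations
    return tensor


class TestSingleMirrorClosedForm:
    def test_matches_quadrature_on_200_random_cases(self, rng):
        w = 7.56
        worst = 0.0
        for _ in range(200):
            a, b, gamma, w, lam = _random_case(rng)
            closed = single_mirror_field(a, b, gamma, w, lam)
            oracle = _gauss_legendre_oracle(a, b, gamma, w, lam)
            worst = max(worst, abs(closed - oracle) / w**2)
        assert worst < 1e-8

    def test_matches_adaptive_dblquad_spot_checks(self, rng):
        for _ in range(3):
            a, b, gamma, w, lam = _random_case(rng)
            k0 = 2 * np.pi / lam
            rot = rotation_matrix(gamma)

            def integrand(t, s, part):
                d = rot @ np.array([s, t, 0.0])
                val = np.exp(1j * k0 * d @ (a + b))
                return val.real if part == "re" else val.imag

            re, _ = integrate.dblquad(integrand, 0, w, 0, w, args=("re",),
                                      epsabs=1e-10, epsrel=1e-10)
            im, _ = integrate.dblquad(integrand, 0, w, 0, w, args=("im",),
                                      epsabs=1e-10, epsrel=1e-10)
            closed = single_mirror_field(a, b, gamma, w, lam)
            assert abs(closed - (re + 1j * im)) / w**2 < 1e-7

    @pytest.mark.parametrize("gamma", [-12.0, 0.0, 12.0])
    def test_specular_direction_gives_full_modulus(self, gamma):
        # zero path difference across the facet <=> b is the specular reflection
        a = angles_to_direction(-21.0, 21.0)
        b = envelope_centre(a, gamma)
        val = single_mirror_field(a, b, gamma, 7.56, 0.532)
        assert abs(val) == pytest.approx(7.56**2, rel=1e-12)

    def test_first_sinc_null(self):
        # gamma = 0, normal incidence: null where qx * w / 2 = pi, i.e. bx = lam / w
        w, lam = 7.56, 0.532
        bx = lam / w
        b = np.array([bx, 0.0, np.sqrt(1 - bx**2)])
        val = single_mirror_field(np.array([0.0, 0.0, 1.0]), b, 0.0, w, lam)
        assert abs(val) < 1e-10 * w**2

    def test_modulus_bounded_by_mirror_area(self, rng):
        for _ in range(50):
            a, b, gamma, w, lam = _random_case(rng)
            assert abs(single_mirror_field(a, b, gamma, w, lam)) <= w**2 * (1 + 1e-12)


class TestLatticePhase:
    def test_reference_mirror_is_unity(self, rng):
        a, b, *_ = _random_case(rng)
        assert lattice_phase(0, 0, a, b, 7.56, 0.532) == pytest.approx(1.0)

    def test_specular_direction_unity_for_all_mirrors(self):
        a = angles_to_direction(-13.0, 8.0)
        b = np.array([-a[0], -a[1], a[2]])  # transverse part of a + b vanishes
        vals = lattice_phase(np.arange(5), np.arange(5), a, b, 7.56, 0.532)
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_phase_additivity(self, rng):
        a, b, *_ = _random_case(rng)
        one = lattice_phase(1, 0, a, b, 7.56, 0.532)
        two = lattice_phase(2, 0, a, b, 7.56, 0.532)
        assert two == pytest.approx(one**2, abs=1e-12)

    def test_unit_modulus(self, rng):
        a, b, *_ = _random_case(rng)
        vals = lattice_phase(np.arange(10), np.arange(10)[::-1], a, b, 7.56, 0.532)
        np.testing.assert_allclose(np.abs(vals), 1.0, atol=1e-12)


class TestDeviceField:
    def test_single_mirror_device_reduces_to_closed_form(self):
        geom = DMDGeometry(nx=1, ny=1)
        grid = AngularGrid.linspace(-10, 10, 21)
        fmap = analytic_dmd_field(geom, TiltPattern.uniform(geom, "minus"),
                                  (-21.0, 21.0), grid, 0.532)
        a = angles_to_direction(-21.0, 21.0)
        expected = single_mirror_field(a, grid.directions(), -12.0, 7.56, 0.532)
        np.testing.assert_allclose(fmap.field, expected, rtol=1e-12)

    @pytest.mark.parametrize("tilt_sign,gamma", [("minus", -12.0), ("plus", 12.0)])
    def test_uniform_tilt_factorizes_into_grating_form(self, geom, tilt_sign, gamma):
        grid = AngularGrid.linspace(-15, 15, 41)
        fmap = analytic_dmd_field(geom, TiltPattern.uniform(geom, tilt_sign),
                                  (-21.0, 21.0), grid, 0.532)
        a = angles_to_direction(-21.0, 21.0)
        b = grid.directions()
        expected = single_mirror_field(a, b, gamma, geom.mirror_um, 0.532) * grating_factor(
            geom, a, b, 0.532
        )
        scale = np.abs(expected).max()
        np.testing.assert_allclose(fmap.field / scale, expected / scale, atol=1e-10)

    def test_field_bounded_by_total_mirror_area(self, geom):
        grid = AngularGrid.linspace(-15, 15, 31)
        pattern = make_pattern("checkerboard", geom.nx, geom.ny, period=3)
        fmap = analytic_dmd_field(geom, pattern, (-21.0, 21.0), grid, 0.532)
        assert np.abs(fmap.field).max() <= geom.nx * geom.ny * geom.mirror_um**2 * (1 + 1e-12)

    def test_striped_pattern_produces_satellite_orders(self, geom):
        """Lines of period p mirrors add satellites lambda/(p*m) from each order.

        Horizontal lines (varying along y) displace satellites along theta_b.
        """
        lam, p = 0.532, 4
        pattern = make_pattern("h_lines", geom.nx, geom.ny, period=p, duty=0.5)
        a = angles_to_direction(-21.0, 21.0)
        b0 = envelope_centre(a, -12.0)  # blazed: brightest order sits here
        phi0, theta0 = np.degrees(np.arctan2(b0[0], b0[2])), np.degrees(
            np.arctan2(b0[1], b0[2])
        )
        grid = AngularGrid.linspace(phi0 - 0.05, phi0 + 0.05, 3,
                                    theta0 - 3.0, theta0 + 3.0, 1201)
        inten = analytic_dmd_field(geom, pattern, (-21.0, 21.0), grid, lam).intensity
        profile = inten[:, 1]
        sines = np.sin(np.deg2rad(grid.theta_deg))
        main = profile.argmax()
        # duty-0.5 stripes: strong odd satellites at sin(theta) -+ k*lambda/(p*m)
        for k in (-1, +1):
            target = sines[main] + k * lam / (p * geom.pitch_um)
            j = int(np.abs(sines - target).argmin())
            window = profile[j - 3 : j + 4]
            assert window.max() > 0.05 * profile[main]  # satellite present
            jloc = j - 3 + window.argmax()
            assert profile[jloc] >= profile[jloc - 1] and profile[jloc] >= profile[jloc + 1]

    def test_mirror_symmetry_under_axis_swap(self):
        """Swapping x<->y maps the device to itself with negated tilts.

        Reflecting the device across the diagonal turns the tilt pattern into
        its transposed complement; fields must then be reflections of each
        other in the (phi_b, theta_b) plane with incidence angles swapped.
        """
        geom = DMDGeometry(nx=8, ny=8)
        grid = AngularGrid.linspace(-12, 12, 41)
        states = make_pattern("h_lines", 8, 8, period=4).states
        inten1 = analytic_dmd_field(geom, TiltPattern(states), (-21.0, 13.0), grid,
                                    0.532).intensity
        inten2 = analytic_dmd_field(geom, TiltPattern(1 - states.T), (13.0, -21.0), grid,
                                    0.532).intensity
        np.testing.assert_allclose(inten1, inten2.T, rtol=1e-9, atol=1e-9)

    def test_dimension_mismatch_rejected(self, geom):
        grid = AngularGrid.linspace(-5, 5, 5)
        with pytest.raises(ValueError):
            analytic_dmd_field(geom, TiltPattern(np.zeros((3, 3))), (0.0, 0.0), grid, 0.532)
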