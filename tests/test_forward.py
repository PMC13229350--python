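"""Four-sphere EEG forward solution.

The primary correctness oracle: with all four conductivities equal, the
model must reduce to the closed-form surface potential of a current dipole
inside a homogeneous conducting sphere with insulating exterior.  The
closed forms below are derived independently from the Legendre generating
function (radial: sum (2n+1) f^{n+1} P_n; tangential: sum (2n+1)/n f^{n+1}
P_n^1), both with the monopole (n=0) term removed so the potentials are
zero-mean over the sphere.
"""

import dataclasses

import numpy as np
import pytest

from pfceeg.forward import FourSphereModel, four_sphere_potential, neuron_dipole


def homogeneous_sphere_potential(p_vec, b_m, R_m, sigma, theta, phi):
    """Surface potential (V) of dipole p (A*m) at z=b inside a homogeneous
    sphere of radius R with insulating exterior; electrode at (theta, phi).

    Radial part: (p_r/(4 pi s b^2)) * [f (2f(x-f)/d^3 + 1/d) - f]
    Tangential:  (p_t cos(phi) sqrt(1-x^2) f/(4 pi s b^2)) *
                 [2f/d^3 + (f-x)/((1-x^2) d) + x/(1-x^2)]
    with f = b/R, x = cos(theta), d = sqrt(1 - 2 f x + f^2).
    """

    f = b_m / R_m
    x = np.cos(theta)
    d = np.sqrt(1 - 2 * f * x + f * f)
    pref = 1.0 / (4 * np.pi * sigma * b_m**2)
    p_r, p_t = p_vec[2], p_vec[0]
    phi_r = pref * p_r * (f * (2 * f * (x - f) / d**3 + 1 / d) - f)
    if abs(x) < 1 - 1e-12:
        ang = 2 * f / d**3 + (f - x) / ((1 - x * x) * d) + x / (1 - x * x)
        phi_t = pref * p_t * np.cos(phi) * np.sqrt(1 - x * x) * f * ang
    else:
        phi_t = 0.0
    return phi_r + phi_t


def make_equal_conductivity_model(theta, phi=0.0, rz=70.0):
    R = 90.0
    electrode = R * np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return FourSphereModel(
        conductivities=(0.3, 0.3, 0.3, 0.3),
        dipole_position_mm=(0.0, 0.0, rz),
        electrode_position_mm=tuple(electrode),
        n_terms=200,
    )


class TestHomogeneousSphereOracle:
    @pytest.mark.parametrize("theta_deg", np.linspace(5, 175, 10))
    def test_radial_dipole_20_positions(self, theta_deg):
        theta = np.radians(theta_deg)
        for rz in (60.0, 75.0):
            model = make_equal_conductivity_model(theta, rz=rz)
            got = model.potential_nV(np.array([0.0, 0.0, 1.0]))
            want = homogeneous_sphere_potential(
                np.array([0.0, 0.0, 1e-15]), rz * 1e-3, 0.09, 0.3, theta, 0.0
            ) * 1e9
            assert got == pytest.approx(want, rel=0.01)

    @pytest.mark.parametrize("theta_deg", [30, 60, 90, 120, 150])
    def test_tangential_dipole(self, theta_deg):
        theta = np.radians(theta_deg)
        model = make_equal_conductivity_model(theta, rz=70.0)
        got = model.potential_nV(np.array([1.0, 0.0, 0.0]))
        want = homogeneous_sphere_potential(
            np.array([1e-15, 0.0, 0.0]), 70e-3, 0.09, 0.3, theta, 0.0
        ) * 1e9
        assert got == pytest.approx(want, rel=0.01)

    def test_oblique_moment_superposes(self):
        theta = np.radians(50)
        model = make_equal_conductivity_model(theta)
        p = np.array([0.6, 0.0, 0.8])
        got = model.potential_nV(p)
        want = 0.6 * model.potential_nV(np.array([1.0, 0, 0])) + 0.8 * model.potential_nV(
            np.array([0, 0, 1.0])
        )
        assert got == pytest.approx(want, rel=1e-12)


class TestFourSphereProperties:
    def test_linearity_negation(self):
        model = FourSphereModel()
        p = np.array([0.0, 0.0, 3.7])
        assert four_sphere_potential(model, -p) == pytest.approx(
            -four_sphere_potential(model, p), rel=1e-12
        )

    def test_attenuation_with_depth(self):
        # fixed radial moment, vertex electrode: deeper dipole -> smaller |phi|
        depths = [78.0, 70.0, 55.0, 35.0]
        mags = []
        for rz in depths:
            model = FourSphereModel(dipole_position_mm=(0.0, 0.0, rz))
            mags.append(abs(model.potential_nV(np.array([0, 0, 1.0]))))
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_series_convergence_beyond_default_order(self):
        # dipole >= 1 mm below the brain surface: doubling the order changes
        # the potential by < 0.1%
        base = FourSphereModel(dipole_position_mm=(0, 0, 78.0), n_terms=60,
                               tail_rtol=1e-12, max_terms=60)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v60 = base.potential_nV(np.array([0, 0, 1.0]))
            high = FourSphereModel(dipole_position_mm=(0, 0, 78.0), n_terms=240,
                                   tail_rtol=1e-12, max_terms=240)
            v240 = high.potential_nV(np.array([0, 0, 1.0]))
        assert abs(v60 - v240) / abs(v240) < 1e-3

    def test_default_geometry_as_configured(self):
        model = FourSphereModel()
        assert model.radii_mm == (79.0, 80.0, 85.0, 90.0)
        assert model.conductivities == (0.47, 1.71, 0.02, 0.41)

    def test_dipole_outside_brain_rejected(self):
        with pytest.raises(ValueError):
            FourSphereModel(dipole_position_mm=(0, 0, 82.0))

    def test_electrode_off_scalp_rejected(self):
        with pytest.raises(ValueError):
            FourSphereModel(electrode_position_mm=(0, 0, 70.0))

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            FourSphereModel(radii_mm=(79, 85, 80, 90))


class TestNeuronDipole:
    def test_zero_current_zero_dipole(self):
        p = neuron_dipole(np.zeros(10), 400.0, [0, 0, 1.0])
        assert np.all(p == 0)

    def test_magnitude_definition(self):
        p = neuron_dipole(np.array([1.0]), 400.0, [0, 0, 1.0])
        assert np.linalg.norm(p[0]) == pytest.approx(400.0)

    def test_antiparallel_cancellation(self):
        i = np.array([0.3, -1.2, 0.9])
        up = neuron_dipole(i, 400.0, [0, 0, 1.0])
        down = neuron_dipole(i, 400.0, [0, 0, -1.0])
        np.testing.assert_allclose(up + down, 0.0, atol=1e-12)

    def test_bad_separation(self):
        with pytest.raises(ValueError):
            neuron_dipole(np.ones(3), 0.0, [0, 0, 1])
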