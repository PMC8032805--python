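"""Form factors, size averaging, the Percus-Yevick structure factor, and
intensity assembly, checked against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, trapezoid
from scipy.optimize import brentq

from saxsmw.models import (
    ParticleModel,
    StructureFactorSpec,
    UnsupportedModelError,
    assemble_intensity,
    form_factor_amplitude,
    mean_volume,
    polydisperse_intensity,
    py_structure_factor,
    sphere_intensity_zero,
    sphere_volume,
)


class TestSphereIntensityZero:
    def test_working_scale_value(self):
        # ((4/3) pi R^3 * contrast)^2 for the fitted PS/H2O sphere
        assert sphere_intensity_zero(90.71, 1.176e-7) == pytest.approx(0.1352, rel=1e-3)

    def test_zero_contrast(self):
        assert sphere_intensity_zero(90.0, 0.0) == 0.0

    def test_direct_arithmetic(self):
        V = 4.0 / 3.0 * np.pi * 90.0**3
        assert sphere_intensity_zero(90.0, 1.0) == pytest.approx(V**2, rel=1e-12)
        assert V == pytest.approx(3.054e6, rel=1e-3)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_intensity_zero(-1.0, 1.0)


class TestAmplitudes:
    @pytest.mark.parametrize("model,F0", [
        (ParticleModel("sphere", 90.0, contrast=2.0), 2.0 * sphere_volume(90.0)),
        (ParticleModel("spheroid", 90.0, contrast=1.0, axis_ratio=1.05),
         1.05 * sphere_volume(90.0)),
        (ParticleModel("core_shell_sphere", 60.0, shell_thickness=16.5,
                       sld_core=8.0592e-6, sld_shell=10.44e-6, sld_solvent=9.4691e-6),
         sphere_volume(60.0) * (8.0592e-6 - 10.44e-6)
         + sphere_volume(76.5) * (10.44e-6 - 9.4691e-6)),
    ])
    def test_long_wavelength_limit(self, model, F0):
        assert form_factor_amplitude(model, 0.0)[0] == pytest.approx(F0, rel=1e-10)

    def test_sphere_first_zero(self):
        # oracle: first positive root of tan(x) = x
        x0 = brentq(lambda x: np.tan(x) - x, np.pi, 1.5 * np.pi - 1e-9)
        assert x0 == pytest.approx(4.4934, abs=1e-3)
        R = 90.0
        model = ParticleModel("sphere", R)
        q0 = brentq(lambda q: form_factor_amplitude(model, q)[0], 0.03, 0.06)
        assert q0 == pytest.approx(x0 / R, rel=1e-6)

    def test_degenerate_shell_equals_sphere(self):
        sld = 2.5e-6
        cs = ParticleModel("core_shell_sphere", 50.0, shell_thickness=25.0,
                           sld_core=sld, sld_shell=sld, sld_solvent=0.0)
        sph = ParticleModel("sphere", 75.0, contrast=sld)
        q = np.linspace(0.0, 0.3, 50)
        np.testing.assert_allclose(form_factor_amplitude(cs, q),
                                   form_factor_amplitude(sph, q), rtol=1e-10)

    def test_unknown_family_rejected(self):
        with pytest.raises(UnsupportedModelError):
            ParticleModel("cylinder", 90.0)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            form_factor_amplitude(ParticleModel("sphere", 90.0), -0.1)


class TestPolydispersity:
    def test_zero_width_is_monodisperse(self):
        q = np.geomspace(0.002, 0.35, 100)
        mono = ParticleModel("sphere", 90.0, contrast=1e-6)
        assert mono.pd_kind == "none"
        np.testing.assert_array_equal(
            polydisperse_intensity(mono, q),
            form_factor_amplitude(mono, q) ** 2)

    @pytest.mark.parametrize("kind", ["gaussian", "schulz_zimm"])
    def test_minima_filled_and_nonnegative(self, kind):
        q = np.geomspace(0.002, 0.35, 400)
        mono = ParticleModel("sphere", 90.0, contrast=1e-6)
        poly = ParticleModel("sphere", 90.0, contrast=1e-6, pd_kind=kind, pd_ratio=0.05)
        I_m = polydisperse_intensity(mono, q)
        I_p = polydisperse_intensity(poly, q)
        assert np.all(I_p >= 0)
        # at the monodisperse minimum the averaged curve is far above it
        i_min = np.argmin(np.abs(q - 4.4934 / 90.0))
        assert I_p[i_min] > 10 * I_m[i_min]

    @pytest.mark.parametrize("kind,ratio", [("gaussian", 0.05), ("gaussian", 0.15),
                                            ("schulz_zimm", 0.10)])
    def test_forward_intensity_vs_monte_carlo(self, kind, ratio):
        # brute-force <F(0)^2> = contrast^2 <V^2> over 2e6 sampled radii
        model = ParticleModel("sphere", 90.0, contrast=1.0, pd_kind=kind, pd_ratio=ratio)
        rng = np.random.default_rng(1234)
        n = 2_000_000
        if kind == "gaussian":
            r = rng.normal(90.0, ratio * 90.0, n)
            r = r[r > 0]
        else:
            z = 1.0 / ratio**2 - 1.0
            r = rng.gamma(z + 1.0, 90.0 / (z + 1.0), n)
        mc = np.mean(sphere_volume(r) ** 2)
        quadr = polydisperse_intensity(model, np.array([0.0]))[0]
        assert quadr == pytest.approx(mc, rel=1e-3)

    def test_excessive_width_rejected(self):
        with pytest.raises(ValueError):
            ParticleModel("sphere", 90.0, pd_kind="gaussian", pd_ratio=0.5)


class TestPercusYevick:
    def test_ideal_gas_limit(self):
        q = np.geomspace(1e-4, 1.0, 50)
        S = py_structure_factor(q, StructureFactorSpec("hard_sphere_py", 90.0, 0.0))
        np.testing.assert_array_equal(S, 1.0)

    @pytest.mark.parametrize("phi", [0.05, 0.1, 0.2, 0.3, 0.4])
    def test_compressibility_limit(self, phi):
        S0 = py_structure_factor(np.array([0.0]),
                                 StructureFactorSpec("hard_sphere_py", 90.0, phi))[0]
        assert S0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2, abs=1e-9)

    def test_against_direct_correlation_quadrature(self):
        # independent oracle: S(q) = 1 / (1 - rho c^(q)) with the PY c(r)
        # Fourier-transformed numerically
        phi, R = 0.2, 90.0
        sigma = 2.0 * R
        denom = (1 - phi) ** 4
        alpha = (1 + 2 * phi) ** 2 / denom
        beta = -6 * phi * (1 + phi / 2) ** 2 / denom
        gamma = 0.5 * phi * alpha
        rho = 6.0 * phi / (np.pi * sigma**3)

        def S_oracle(q):
            def integrand(r):
                x = r / sigma
                return -(alpha + beta * x + gamma * x**3) * r**2 * np.sinc(q * r / np.pi)
            chat = 4.0 * np.pi * quad(integrand, 0.0, sigma, limit=200)[0]
            return 1.0 / (1.0 - rho * chat)

        q = np.array([0.002, 0.004, 0.01, 0.02, 0.05, 0.1, 0.3])
        S = py_structure_factor(q, StructureFactorSpec("hard_sphere_py", R, phi))
        oracle = np.array([S_oracle(x) for x in q])
        np.testing.assert_allclose(S, oracle, atol=1e-6)

    def test_oscillations_decay_beyond_peak(self):
        q = np.linspace(0.001, 1.0, 4000)
        S = py_structure_factor(q, StructureFactorSpec("hard_sphere_py", 90.0, 0.2))
        i_peak = np.argmax(S)
        dev = np.abs(1.0 - S[i_peak:])
        # envelope of |1 - S| decays: window maxima decrease monotonically
        win = np.array_split(dev, 8)
        maxima = [w.max() for w in win]
        assert all(a > b for a, b in zip(maxima, maxima[1:]))

    def test_bad_volume_fraction_rejected(self):
        with pytest.raises(ValueError):
            StructureFactorSpec("hard_sphere_py", 90.0, 0.8)


class TestAssembly:
    def test_absolute_scale_forward_intensity(self):
        # PS/H2O: I(0) = phi V drho^2 * 1e8 ~ 0.132 1/cm
        m = ParticleModel("sphere", 90.0, contrast=4.65e-8)
        I0 = assemble_intensity(m, StructureFactorSpec("none"), 0.2, np.array([1e-8]))[0]
        assert I0 == pytest.approx(0.2 * sphere_volume(90.0) * (4.65e-8) ** 2 * 1e8,
                                   rel=1e-6)
        assert I0 == pytest.approx(0.132, rel=5e-3)

    def test_contrast_and_dilution_scaling(self):
        q = np.geomspace(0.002, 0.3, 50)
        sf = StructureFactorSpec("none")
        m1 = ParticleModel("sphere", 90.0, contrast=1e-6)
        m3 = ParticleModel("sphere", 90.0, contrast=3e-6)
        I1 = assemble_intensity(m1, sf, 0.1, q)
        np.testing.assert_allclose(assemble_intensity(m3, sf, 0.1, q), 9.0 * I1, rtol=1e-12)
        np.testing.assert_allclose(assemble_intensity(m1, sf, 0.05, q), 0.5 * I1, rtol=1e-12)
        assert np.all(assemble_intensity(m1, sf, 0.0, q) == 0.0)

    def test_dilute_invariant_identity(self):
        # integral I q^2 dq / (2 pi^2) -> phi drho^2 * 1e8 for S = 1 spheres
        drho, phi = 1e-6, 0.01
        m = ParticleModel("sphere", 90.0, contrast=drho)
        q = np.geomspace(1e-4, 5.0, 20000)
        I = assemble_intensity(m, StructureFactorSpec("none"), phi, q)
        Q = trapezoid(I * q**2, q) / (2 * np.pi**2)
        assert Q == pytest.approx(phi * drho**2 * 1e8, rel=0.01)

    def test_hard_sphere_invariant_identity(self):
        # with the PY structure factor the invariant picks up the (1 - phi)
        # occupancy factor of the two-phase mean-square fluctuation
        drho, phi = 4.65e-8, 0.2
        m = ParticleModel("sphere", 90.0, contrast=drho, pd_kind="gaussian", pd_ratio=0.05)
        q = np.geomspace(0.002, 0.35, 400)
        I = assemble_intensity(m, StructureFactorSpec("hard_sphere_py", 90.0, phi), phi, q)
        Q = trapezoid(I * q**2, q)
        Q += np.median((I * q**4)[q > q[-1] / 10**0.5]) / q[-1]  # Porod tail
        assert Q / (2 * np.pi**2) == pytest.approx(phi * (1 - phi) * drho**2 * 1e8,
                                                   rel=0.05)
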