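"""Form factors, analytic structure factors, and the combined model."""

import numpy as np
import pytest

from micellekit.saxs.models import (
    CombinedModel,
    CoreShellParams,
    GaussianChainParams,
    HayterPenfoldParams,
    PowerLawParams,
    SphereParams,
    combined_intensity,
    core_shell_amplitude,
    core_shell_form_factor,
    gaussian_chain_intensity,
    hard_sphere_py_sf,
    hayter_penfold_sf,
    kappa_from_counterions,
    power_law_intensity,
    sphere_form_factor,
)

from oracles import core_shell_amplitude_quadrature


class TestSphereFormFactor:
    def test_forward_limit_is_unity(self):
        q = np.array([1e-8, 1e-5, 1e-3])
        P = sphere_form_factor(q, SphereParams(radius=2.0))
        assert np.allclose(P, 1.0, atol=1e-9)

    def test_first_zero_at_qr_4p4934(self):
        # first root of 3(sin x - x cos x)/x^3 is x = 4.4934094579...
        R = 2.45
        x0 = 4.4934094579
        P = sphere_form_factor(np.array([x0 / R]), SphereParams(radius=R))
        assert P[0] < 1e-15  # squared amplitude vanishes at the node
        flank = sphere_form_factor(np.array([(x0 - 0.1) / R, (x0 + 0.1) / R]),
                                   SphereParams(radius=R))
        assert np.all(flank > P[0])

    def test_series_matches_direct_kernel_across_switch(self):
        # the small-x series must join the closed form smoothly (below
        # x ~ 1e-4 the closed form itself loses digits to cancellation)
        R = 1.0
        q = np.geomspace(1e-3, 1.0, 50)
        P = sphere_form_factor(q, SphereParams(radius=R))
        x = q * R
        direct = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        assert np.allclose(P, direct, rtol=1e-6)
        near_switch = sphere_form_factor(np.array([0.9e-4, 1.1e-4]),
                                         SphereParams(radius=R))
        # the closed form itself carries ~1e-7 cancellation error here
        assert abs(near_switch[1] - near_switch[0]) < 1e-6

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            SphereParams(radius=-1.0)


class TestCoreShell:
    def test_amplitude_matches_radial_quadrature_oracle(self):
        q = np.linspace(0.05, 5.0, 40)
        p = CoreShellParams(core_radius=1.5, outer_radius=2.45,
                            rho_core=0.29, rho_shell=0.40, rho_solvent=0.333)
        impl = core_shell_amplitude(q, p)
        oracle = core_shell_amplitude_quadrature(q, 1.5, 2.45, 0.29, 0.40, 0.333)
        assert np.max(np.abs(impl - oracle)) / np.max(np.abs(oracle)) < 1e-8

    def test_degenerate_shell_reduces_to_sphere(self):
        # rho_shell == rho_solvent: only the core scatters
        q = np.linspace(0.05, 5.0, 40)
        p = CoreShellParams(core_radius=1.5, outer_radius=2.45,
                            rho_core=0.29, rho_shell=0.333, rho_solvent=0.333)
        P = core_shell_form_factor(q, p)
        assert np.allclose(P, sphere_form_factor(q, SphereParams(radius=1.5)),
                           rtol=1e-9)

    def test_normalized_form_factor_is_unity_forward(self):
        p = CoreShellParams(core_radius=1.5, outer_radius=2.45,
                            rho_core=0.29, rho_shell=0.40, rho_solvent=0.333)
        P = core_shell_form_factor(np.array([1e-8]), p)
        assert P[0] == pytest.approx(1.0, abs=1e-9)

    def test_core_must_fit_inside_outer_radius(self):
        with pytest.raises(ValueError):
            CoreShellParams(core_radius=3.0, outer_radius=2.0,
                            rho_core=0.29, rho_shell=0.40, rho_solvent=0.333)


class TestGaussianChain:
    def test_debye_value_at_unit_reduced_q(self):
        # x = (qRg)^2 = 1: I/i0 = 2(e^-1 + 1 - 1)/1 = 2/e
        rg = 1.8
        q = np.array([1.0 / rg])
        I = gaussian_chain_intensity(q, GaussianChainParams(rg=rg, i0=1.0))
        assert I[0] == pytest.approx(2.0 / np.e, rel=1e-10)

    def test_forward_intensity_and_low_q_series(self):
        p = GaussianChainParams(rg=1.8, i0=0.0025)
        q = np.array([1e-8, 1e-7, 1e-4, 1e-3])
        I = gaussian_chain_intensity(q, p)
        assert I[0] == pytest.approx(0.0025, rel=1e-12)
        assert np.all(np.diff(I) <= 0)

    def test_high_q_limit_2_over_x(self):
        p = GaussianChainParams(rg=1.8, i0=1.0)
        q = np.array([50.0])
        x = (q[0] * p.rg) ** 2
        I = gaussian_chain_intensity(q, p)
        assert I[0] == pytest.approx(2.0 * (x - 1.0) / x**2, rel=1e-6)


class TestPowerLaw:
    def test_exact_power_law_decay(self):
        p = PowerLawParams(amplitude=1e-4, alpha=2.6)
        q = np.array([0.1, 1.0])
        I = power_law_intensity(q, p)
        assert I[1] / I[0] == pytest.approx(10.0 ** (-2.6), rel=1e-12)
        assert I[1] == pytest.approx(1e-4, rel=1e-12)


class TestPercusYevick:
    def test_zero_q_compressibility_value(self):
        # S(0) = (1-phi)^4 / (1+2 phi)^2 ; phi = 0.2 -> 0.2089962...
        S = hard_sphere_py_sf(np.array([1e-9]), 2.45, 0.2)
        expected = 0.8**4 / 1.4**2
        assert S[0] == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(0.20898, abs=5e-6)

    def test_dilute_and_high_q_limits_approach_unity(self):
        S_dilute = hard_sphere_py_sf(np.linspace(0.05, 5, 30), 2.45, 1e-6)
        assert np.allclose(S_dilute, 1.0, atol=1e-4)
        S_highq = hard_sphere_py_sf(np.array([500.0]), 2.45, 0.3)
        assert S_highq[0] == pytest.approx(1.0, abs=5e-3)

    def test_structure_suppresses_forward_scattering(self):
        q = np.linspace(0.01, 5, 100)
        S = hard_sphere_py_sf(q, 2.45, 0.3)
        assert S[0] < 0.1  # strong forward suppression at phi = 0.3
        assert np.max(S) > 1.0  # nearest-neighbour peak


class TestHayterPenfold:
    def test_uncharged_limit_equals_percus_yevick(self):
        q = np.linspace(0.05, 5.0, 60)
        for phi in (0.05, 0.2):
            hp = HayterPenfoldParams(hs_radius=2.45, volume_fraction=phi, z_eff=0.0,
                                     inv_screening_length=1.0)
            S_hp = hayter_penfold_sf(q, hp)
            S_py = hard_sphere_py_sf(q, 2.45, phi)
            assert np.max(np.abs(S_hp - S_py)) < 1e-3

    def test_charge_deepens_forward_suppression(self):
        q = np.linspace(0.05, 5.0, 60)
        base = dict(hs_radius=2.45, volume_fraction=0.0117)
        S0 = hayter_penfold_sf(q, HayterPenfoldParams(z_eff=0.0,
                                                      inv_screening_length=0.14, **base))
        S10 = hayter_penfold_sf(q, HayterPenfoldParams(z_eff=10.8, **base))
        assert S10[0] < S0[0]  # Coulomb repulsion orders the solution

    def test_interference_peak_position_for_one_percent_sample(self):
        # 1 wt % study condition: peak in the 0.4-0.5 nm^-1 band
        q = np.linspace(0.1, 2.0, 400)
        hp = HayterPenfoldParams(hs_radius=2.45, volume_fraction=0.0117, z_eff=10.8)
        S = hayter_penfold_sf(q, hp)
        q_peak = q[np.argmax(S)]
        assert 0.4 <= q_peak <= 0.5

    def test_counterion_screening_length(self):
        # kappa^2 = 4 pi lambda_B z_eff n  (monovalent counterions only)
        hp = HayterPenfoldParams(hs_radius=2.45, volume_fraction=0.0117, z_eff=10.8)
        kappa = kappa_from_counterions(hp.number_density, hp.z_eff)
        assert kappa == pytest.approx(hp.kappa(), rel=1e-12)
        lam_b = 1.6021766e-19**2 / (4 * np.pi * 8.8541878e-12 * 78.5
                                    * 1.380649e-23 * 298.0) * 1e9
        assert kappa == pytest.approx(
            np.sqrt(4 * np.pi * lam_b * 10.8 * hp.number_density), rel=1e-4)


class TestCombinedModel:
    def test_product_combination(self):
        q = np.linspace(0.05, 5, 50)
        core = CoreShellParams(core_radius=1.5, outer_radius=2.45,
                               rho_core=0.29, rho_shell=0.40, rho_solvent=0.333)
        hp = HayterPenfoldParams(hs_radius=2.45, volume_fraction=0.0117, z_eff=10.8)
        model = CombinedModel(form="core_shell", structure="hayter_penfold",
                              scale=0.4, background=1e-4)
        I = combined_intensity(q, model, core, hp)
        expected = (0.4 * core_shell_form_factor(q, core)
                    * hayter_penfold_sf(q, hp) + 1e-4)
        assert np.allclose(I, expected, rtol=1e-10)

    def test_chain_model_carries_absolute_intensity(self):
        q = np.linspace(0.05, 5, 50)
        gp = GaussianChainParams(rg=1.8, i0=0.0025)
        model = CombinedModel(form="gaussian_chain", structure="none",
                              scale=1.0, background=0.0)
        I = combined_intensity(q, model, gp)
        assert np.allclose(I, gaussian_chain_intensity(q, gp), rtol=1e-12)

    def test_structure_factor_refused_for_fractal_form(self):
        with pytest.raises(ValueError):
            CombinedModel(form="power_law", structure="hayter_penfold",
                          scale=1.0, background=0.0)
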