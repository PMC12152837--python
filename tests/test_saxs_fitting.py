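"""Model fitting, forward-intensity, power-law and breakpoint estimators."""

import numpy as np
import pytest

from micellekit.datatypes import NoiseSpec, ScatteringCurve
from micellekit.saxs.fitting import (
    BreakpointFitter,
    GuinierForwardIntensity,
    InsufficientDataError,
    PowerLawExponentFitter,
    SAXSModelFitter,
    breakpoint_fit,
    detect_interference_peak,
    fit_model,
    forward_intensity,
    powerlaw_exponent,
)
from micellekit.saxs.models import (
    CombinedModel,
    SphereParams,
    sphere_form_factor,
)
from micellekit.synthetic import make_titration, preset_curve


class TestSAXSModelFitter:
    def test_gaussian_chain_recovery_from_noisy_dilute_curve(self):
        curve, truth = preset_curve("aged_0.1wt", seed=42, relative_sd=0.01)
        fitter = SAXSModelFitter(family="gaussian_chain", n_starts=4, seed=3)
        fitter.fit(curve)
        assert fitter.converged_
        assert fitter.params_["rg"] == pytest.approx(truth["rg"], rel=0.05)
        assert fitter.params_["i0"] == pytest.approx(truth["i0"], rel=0.05)
        assert 0.3 < fitter.chi2_reduced_ < 3.0

    def test_sphere_radius_recovery(self):
        q = np.geomspace(0.05, 5.0, 150)
        R = 2.2
        ideal = 0.05 * sphere_form_factor(q, SphereParams(radius=R)) + 1e-4
        sigma = 0.01 * ideal + 1e-6
        rng = np.random.default_rng(5)
        curve = ScatteringCurve(q=q, intensity=ideal + sigma * rng.standard_normal(q.shape),
                                sigma=sigma)
        # the sphere form factor is oscillatory, so start from a rough
        # size estimate as a Guinier pre-analysis would supply
        fitter = SAXSModelFitter(family="sphere", n_starts=6, seed=1,
                                 init={"radius": 2.0, "scale": 0.05,
                                       "background": 1e-4}).fit(curve)
        assert fitter.params_["radius"] == pytest.approx(R, rel=0.02)

    def test_predict_reproduces_fitted_model(self):
        curve, _ = preset_curve("aged_0.1wt", seed=42, relative_sd=0.01)
        fitter = SAXSModelFitter(family="gaussian_chain", n_starts=2, seed=3).fit(curve)
        pred = fitter.predict(curve.q)
        chi2 = np.mean(((pred - curve.intensity) / curve.sigma) ** 2)
        assert chi2 < 3.0

    def test_uncertainties_are_nonnegative_and_finite(self):
        curve, _ = preset_curve("aged_0.1wt", seed=42, relative_sd=0.01)
        fitter = SAXSModelFitter(family="gaussian_chain", n_starts=2, seed=3).fit(curve)
        for err in fitter.uncertainties_.values():
            assert np.isfinite(err) and err >= 0.0

    def test_deterministic_for_fixed_seed(self):
        curve, _ = preset_curve("aged_0.1wt", seed=42, relative_sd=0.01)
        a = SAXSModelFitter(family="gaussian_chain", n_starts=4, seed=9).fit(curve)
        b = SAXSModelFitter(family="gaussian_chain", n_starts=4, seed=9).fit(curve)
        assert a.params_ == b.params_

    def test_too_few_points_rejected(self):
        curve = ScatteringCurve(q=np.linspace(0.1, 1, 5),
                                intensity=np.ones(5), sigma=np.ones(5))
        with pytest.raises(InsufficientDataError):
            SAXSModelFitter(family="gaussian_chain").fit(curve)

    def test_unknown_family_rejected(self):
        curve, _ = preset_curve("aged_0.1wt", seed=0, relative_sd=0.0)
        with pytest.raises(ValueError):
            SAXSModelFitter(family="lamellar").fit(curve)

    def test_fit_model_accepts_combined_model_declaration(self):
        curve, truth = preset_curve("aged_0.1wt", seed=42, relative_sd=0.01)
        model = CombinedModel(form="gaussian_chain", structure="none",
                              scale=1.0, background=0.0)
        res = fit_model(curve, model, n_starts=2, seed=3)
        assert res.converged
        assert res.best_params["rg"] == pytest.approx(truth["rg"], rel=0.05)


class TestInterferencePeak:
    def test_concentrated_micellar_curve_shows_peak(self):
        curve, _ = preset_curve("aged_1wt", seed=4, relative_sd=0.02)
        assert detect_interference_peak(curve)

    def test_dilute_oligomer_curve_has_no_peak(self):
        curve, _ = preset_curve("aged_0.1wt", seed=4, relative_sd=0.02)
        assert not detect_interference_peak(curve)


class TestForwardIntensity:
    def test_guinier_recovers_forward_intensity_and_rg(self):
        curve, truth = preset_curve("aged_0.1wt", seed=21, relative_sd=0.01)
        est = GuinierForwardIntensity(method="guinier").fit(curve)
        assert est.i0_ == pytest.approx(truth["i0"], rel=0.05)
        assert est.rg_ == pytest.approx(truth["rg"], rel=0.10)

    def test_plateau_estimate_agrees_with_guinier(self):
        curve, truth = preset_curve("aged_0.1wt", seed=21, relative_sd=0.01)
        i0_p, _ = forward_intensity(curve, method="plateau")
        assert i0_p == pytest.approx(truth["i0"], rel=0.05)

    def test_plateau_invariant_under_uniform_sigma_rescaling(self):
        curve, _ = preset_curve("aged_0.1wt", seed=21, relative_sd=0.01)
        scaled = ScatteringCurve(q=curve.q, intensity=curve.intensity,
                                 sigma=curve.sigma * 7.3)
        i0_a, _ = forward_intensity(curve, method="plateau")
        i0_b, _ = forward_intensity(scaled, method="plateau")
        assert i0_a == pytest.approx(i0_b, rel=1e-12)


class TestPowerLawExponent:
    def test_fractal_exponent_recovery(self):
        curve, truth = preset_curve("fresh_0.1wt", seed=13, relative_sd=0.01)
        est = PowerLawExponentFitter().fit(curve)
        assert est.alpha_ == pytest.approx(truth["alpha"], abs=0.05)
        assert est.alpha_stderr_ < 0.05

    def test_q_range_restriction(self):
        curve, truth = preset_curve("fresh_0.1wt", seed=13, relative_sd=0.01)
        alpha, _ = powerlaw_exponent(curve, q_range=(0.05, 1.0))
        assert alpha == pytest.approx(truth["alpha"], abs=0.08)

    def test_nonpositive_intensity_rejected(self):
        q = np.linspace(0.1, 1, 20)
        I = np.linspace(1.0, -0.1, 20)
        with pytest.raises(ValueError):
            PowerLawExponentFitter().fit(ScatteringCurve(q=q, intensity=I))


class TestBreakpoint:
    def test_cmc_recovery_from_noisy_titration(self):
        conc, resp = make_titration(cmc=0.06, n_points=20, relative_sd=0.03, seed=8)
        res = breakpoint_fit(conc, resp)
        assert res.significant
        assert res.breakpoint == pytest.approx(0.06, abs=0.005)

    def test_noiseless_titration_is_exactly_segmented(self):
        conc, resp = make_titration(cmc=0.06, n_points=14, relative_sd=0.0)
        fitter = BreakpointFitter().fit(conc, resp)
        assert fitter.significant_
        assert fitter.breakpoint_ == pytest.approx(0.06, rel=1e-4)
        assert fitter.slope_left_ == pytest.approx(0.05, abs=1e-6)
        assert fitter.slope_right_ == pytest.approx(1.0, abs=1e-6)

    def test_straight_line_is_not_significant(self):
        x = np.geomspace(0.01, 1.0, 15)
        rng = np.random.default_rng(3)
        y = 2.0 + 0.5 * np.log10(x) + 1e-3 * rng.standard_normal(15)
        fitter = BreakpointFitter().fit(x, y)
        assert not fitter.significant_

    def test_breakpoint_stays_inside_data_range(self):
        conc, resp = make_titration(cmc=0.06, n_points=20, relative_sd=0.05, seed=99)
        res = breakpoint_fit(conc, resp)
        assert conc.min() <= res.breakpoint <= conc.max()

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            breakpoint_fit(np.array([0.1, 0.2, 0.3]), np.array([1.0, 2.0, 3.0]))
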