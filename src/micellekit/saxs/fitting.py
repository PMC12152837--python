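"""Weighted nonlinear SAXS fitting, forward-intensity and exponent
estimation, and breakpoint (CMC) estimation.

The fit-shaped operations are sklearn-style estimators
(:class:`SAXSModelFitter`, :class:`GuinierForwardIntensity`,
:class:`PowerLawExponentFitter`, :class:`BreakpointFitter`) with
``fit``/``predict`` and trailing-underscore fitted attributes; the
module-level functions (:func:`fit_model`, :func:`forward_intensity`,
:func:`powerlaw_exponent`, :func:`breakpoint_fit`,
:func:`compare_structure_factors`) are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from ..datatypes import BreakpointResult, FitResult, ScatteringCurve
from .models import (
    CombinedModel,
    CoreShellParams,
    GaussianChainParams,
    HayterPenfoldParams,
    PowerLawParams,
    SphereParams,
    combined_intensity,
    gaussian_chain_intensity,
    hard_sphere_py_sf,
    power_law_intensity,
    sphere_form_factor,
    core_shell_form_factor,
)
from .oz import OZConvergenceError, RescaledMSACache

DEFAULT_SEED = 20250512


class InsufficientDataError(ValueError):
    """Raised when too few usable points are available for an estimate."""


# ---------------------------------------------------------------------------
# model families: parameter names, default bounds, intensity builders
# ---------------------------------------------------------------------------

@dataclass
class _Family:
    param_names: tuple
    default_bounds: dict
    builder: Callable  # (q, params_dict, fixed_dict, cache) -> intensity


def _build_gaussian_chain(q, p, fixed, cache):
    return gaussian_chain_intensity(q, GaussianChainParams(rg=p["rg"], i0=p["i0"])) + p["background"]


def _build_power_law(q, p, fixed, cache):
    return power_law_intensity(q, PowerLawParams(amplitude=p["amplitude"], alpha=p["alpha"])) + p["background"]


def _build_sphere(q, p, fixed, cache):
    return p["scale"] * sphere_form_factor(q, SphereParams(radius=p["radius"])) + p["background"]


def _core_shell_from(p, fixed):
    return CoreShellParams(
        core_radius=p["core_radius"], outer_radius=p["outer_radius"],
        rho_core=fixed.get("rho_core", 0.29),
        rho_shell=fixed.get("rho_shell", 0.40),
        rho_solvent=fixed.get("rho_solvent", 0.333),
    )


def _build_core_shell(q, p, fixed, cache):
    cs = _core_shell_from(p, fixed)
    return p["scale"] * core_shell_form_factor(q, cs) + p["background"]


def _build_core_shell_py(q, p, fixed, cache):
    cs = _core_shell_from(p, fixed)
    sq = hard_sphere_py_sf(q, p["hs_radius"], p["volume_fraction"])
    return p["scale"] * core_shell_form_factor(q, cs) * sq + p["background"]


def _build_core_shell_hp(q, p, fixed, cache):
    cs = _core_shell_from(p, fixed)
    hp = HayterPenfoldParams(
        hs_radius=p.get("hs_radius", p["outer_radius"]),
        volume_fraction=p["volume_fraction"],
        z_eff=p["z_eff"],
        inv_screening_length=fixed.get("inv_screening_length"),
        temperature=fixed.get("temperature", 298.0),
        dielectric_const=fixed.get("dielectric_const", 78.5),
    )
    from .models import hayter_penfold_sf

    # fitting defaults trade a little solver tolerance for speed; the
    # resulting S(q) error (~1e-4) is far below the data noise
    sq = hayter_penfold_sf(q, hp, cache=cache,
                           n_grid=int(fixed.get("n_grid", 4096)),
                           tol=float(fixed.get("oz_tol", 1e-8)),
                           s_tol=float(fixed.get("oz_s_tol", 1e-4)))
    return p["scale"] * core_shell_form_factor(q, cs) * sq + p["background"]


_FAMILIES = {
    "gaussian_chain": _Family(
        ("rg", "i0", "background"),
        {"rg": (0.2, 20.0), "i0": (1e-6, 10.0), "background": (0.0, 0.1)},
        _build_gaussian_chain,
    ),
    "power_law": _Family(
        ("amplitude", "alpha", "background"),
        {"amplitude": (1e-8, 100.0), "alpha": (0.0, 5.0), "background": (0.0, 0.1)},
        _build_power_law,
    ),
    "sphere": _Family(
        ("radius", "scale", "background"),
        {"radius": (0.3, 50.0), "scale": (1e-8, 100.0), "background": (0.0, 0.1)},
        _build_sphere,
    ),
    "core_shell": _Family(
        ("core_radius", "outer_radius", "scale", "background"),
        {"core_radius": (0.3, 10.0), "outer_radius": (0.5, 20.0),
         "scale": (1e-8, 100.0), "background": (0.0, 0.1)},
        _build_core_shell,
    ),
    "core_shell_py": _Family(
        ("core_radius", "outer_radius", "hs_radius", "volume_fraction", "scale", "background"),
        {"core_radius": (0.3, 10.0), "outer_radius": (0.5, 20.0),
         "hs_radius": (0.5, 20.0), "volume_fraction": (1e-4, 0.5),
         "scale": (1e-8, 100.0), "background": (0.0, 0.1)},
        _build_core_shell_py,
    ),
    "core_shell_hp": _Family(
        ("core_radius", "outer_radius", "z_eff", "volume_fraction", "scale", "background"),
        {"core_radius": (0.5, 5.0), "outer_radius": (1.0, 8.0),
         "z_eff": (0.5, 40.0), "volume_fraction": (1e-3, 0.2),
         "scale": (1e-8, 100.0), "background": (0.0, 0.1)},
        _build_core_shell_hp,
    ),
}


def model_to_family(model: CombinedModel) -> str:
    """Map a :class:`CombinedModel` declaration to a fit-family name."""
    if model.structure == "none":
        return model.form
    if model.form != "core_shell":
        raise ValueError("structure factors are fitted with the core_shell form only")
    return {"hard_sphere_PY": "core_shell_py", "hayter_penfold": "core_shell_hp"}[model.structure]


def _as_curve(q, intensity, sigma) -> ScatteringCurve:
    if isinstance(q, ScatteringCurve):
        return q
    return ScatteringCurve(q=np.asarray(q, float).ravel(), intensity=intensity, sigma=sigma)


# ---------------------------------------------------------------------------
# main model fitter
# ---------------------------------------------------------------------------

class SAXSModelFitter(BaseEstimator):
    """Weighted least-squares fit of a SAXS model family to a curve.

    Minimizes Σ[(I_obs − I_model)/σ]² with seeded Latin-hypercube
    multi-start (charged-sphere fits are multi-modal in (φ, z_eff));
    deterministic for a fixed ``seed``.

    Parameters
    ----------
    family : str
        One of ``gaussian_chain, power_law, sphere, core_shell,
        core_shell_py, core_shell_hp``.
    init : dict, optional
        Starting values for (a subset of) the family's parameters; used
        as the first start.
    bounds : dict, optional
        ``{name: (lo, hi)}`` overrides of the family defaults.
    fixed : dict, optional
        Non-varied quantities (electron densities, screening length,
        temperature); also accepts parameter names to freeze at their
        ``init`` value via ``vary``.
    vary : sequence of str, optional
        Names of parameters to vary; others are frozen at ``init``.
    n_starts : int
        Number of multi-start initializations (default 8).
    seed : int
        Seed for the quasi-random starts.

    Attributes
    ----------
    params_, uncertainties_ : dict
    chi2_reduced_ : float
    converged_ : bool
    result_ : FitResult
    """

    def __init__(self, family: str = "gaussian_chain", init: Optional[dict] = None,
                 bounds: Optional[dict] = None, fixed: Optional[dict] = None,
                 vary: Optional[Sequence[str]] = None, n_starts: int = 8,
                 seed: int = DEFAULT_SEED):
        self.family = family
        self.init = init
        self.bounds = bounds
        self.fixed = fixed
        self.vary = vary
        self.n_starts = n_starts
        self.seed = seed

    # -- internals -----------------------------------------------------
    def _setup(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {sorted(_FAMILIES)}")
        fam = _FAMILIES[self.family]
        bounds = dict(fam.default_bounds)
        if self.bounds:
            bounds.update(self.bounds)
        init = dict(self.init or {})
        vary = list(self.vary) if self.vary is not None else list(fam.param_names)
        for name in vary:
            if name not in fam.param_names:
                raise ValueError(f"{name!r} is not a parameter of family {self.family!r}")
        frozen = {n: init[n] for n in fam.param_names if n not in vary}
        missing = [n for n in fam.param_names if n not in vary and n not in init]
        if missing:
            raise ValueError(f"frozen parameters need init values: {missing}")
        return fam, bounds, init, vary, frozen

    def fit(self, q, intensity=None, sigma=None):
        """Fit the model; ``q`` may be a :class:`ScatteringCurve`."""
        curve = _as_curve(q, intensity, sigma)
        if len(curve) < 10:
            raise InsufficientDataError("need at least 10 data points for a model fit")
        if not np.all(np.isfinite(curve.intensity)):
            raise ValueError("NaN/inf in intensity data")
        fam, bounds, init, vary, frozen = self._setup()

        if curve.sigma is not None:
            weights = 1.0 / curve.sigma
        else:
            warnings.warn("curve has no uncertainties; performing unweighted fit",
                          stacklevel=2)
            weights = np.ones_like(curve.intensity)

        lo = np.array([bounds[n][0] for n in vary])
        hi = np.array([bounds[n][1] for n in vary])
        fixed = dict(self.fixed or {})

        # start points: user/default init first, then Latin hypercube
        starts = []
        x0 = np.array([np.clip(init.get(n, 0.5 * (bounds[n][0] + bounds[n][1])),
                               bounds[n][0], bounds[n][1]) for n in vary])
        starts.append(x0)
        if self.n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(vary), seed=self.seed)
            unit = sampler.random(self.n_starts - 1)
            # log-spaced sampling for scale-like positive parameters
            for row in unit:
                pt = lo + row * (hi - lo)
                starts.append(pt)

        cache = RescaledMSACache()

        def residuals(x):
            params = dict(zip(vary, x))
            params.update(frozen)
            try:
                model_i = fam.builder(curve.q, params, fixed, cache)
            except (ValueError, OZConvergenceError):
                # infeasible geometry (e.g. core outside the shell) or a
                # non-converging structure-factor state: a large residual
                # plateau steers the optimizer back instead of aborting
                return np.full(len(curve), 1e8)
            return (model_i - curve.intensity) * weights

        best = None
        n_failed = 0
        for x_start in starts:
            try:
                res = least_squares(residuals, x_start, bounds=(lo, hi),
                                    method="trf", x_scale="jac", ftol=1e-12,
                                    xtol=1e-12, gtol=1e-12, max_nfev=400)
            except (OZConvergenceError, ValueError, FloatingPointError):
                n_failed += 1
                continue
            if not np.all(np.isfinite(res.fun)):
                n_failed += 1
                continue
            if best is None or res.cost < best.cost:
                best = res

        names_all = list(fam.param_names)
        if best is None:
            self.converged_ = False
            self.params_ = {}
            self.uncertainties_ = {}
            self.chi2_reduced_ = float("nan")
            self.result_ = FitResult(
                best_params={}, param_uncertainties={}, chi2_reduced=float("nan"),
                n_points=len(curve), converged=False, model_id=self.family,
                message=f"no start converged ({n_failed} failures)",
            )
            return self

        dof = max(len(curve) - len(vary), 1)
        chi2_red = float(2.0 * best.cost / dof)
        # covariance from the Jacobian at the optimum
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * chi2_red
            perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            perr = np.full(len(vary), np.nan)

        params = dict(zip(vary, (float(v) for v in best.x)))
        params.update(frozen)
        errs = dict(zip(vary, (float(e) for e in perr)))
        errs.update({n: 0.0 for n in frozen})

        self.params_ = {n: params[n] for n in names_all}
        self.uncertainties_ = {n: errs[n] for n in names_all}
        self.chi2_reduced_ = chi2_red
        self.converged_ = bool(best.status > 0)
        self.n_failed_starts_ = n_failed
        self.result_ = FitResult(
            best_params=self.params_, param_uncertainties=self.uncertainties_,
            chi2_reduced=chi2_red, n_points=len(curve), converged=self.converged_,
            model_id=self.family,
        )
        self._fixed_used_ = fixed
        return self

    def predict(self, q) -> np.ndarray:
        """Model intensity at ``q`` for the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        fam = _FAMILIES[self.family]
        return fam.builder(np.asarray(q, float), self.params_,
                           dict(self._fixed_used_), RescaledMSACache())


def fit_model(curve: ScatteringCurve, model, init: Optional[dict] = None,
              bounds: Optional[dict] = None, n_starts: int = 8,
              seed: int = DEFAULT_SEED, fixed: Optional[dict] = None,
              vary: Optional[Sequence[str]] = None) -> FitResult:
    """Fit ``curve`` with a model family (name or :class:`CombinedModel`)."""
    family = model_to_family(model) if isinstance(model, CombinedModel) else model
    est = SAXSModelFitter(family=family, init=init, bounds=bounds, fixed=fixed,
                          vary=vary, n_starts=n_starts, seed=seed)
    est.fit(curve)
    return est.result_


# ---------------------------------------------------------------------------
# structure-factor model comparison
# ---------------------------------------------------------------------------

def detect_interference_peak(curve: ScatteringCurve, *, min_prominence: float = 0.02) -> bool:
    """Heuristic: does the curve show an interior interference maximum?

    Looks for a local maximum of a smoothed I(q) away from both ends
    whose prominence exceeds both ``min_prominence`` of the local
    intensity and (when uncertainties are available) several times the
    smoothed noise level, so counting noise does not register as a peak.
    """
    from scipy.signal import find_peaks
    from scipy.ndimage import uniform_filter1d

    window = max(3, len(curve) // 20)
    y = uniform_filter1d(curve.intensity, size=window)
    peaks, props = find_peaks(y, prominence=0.0)
    for idx, prom in zip(peaks, props["prominences"]):
        if not (2 <= idx <= len(curve) - 3):
            continue
        threshold = min_prominence * y[idx]
        if curve.sigma is not None:
            threshold = max(threshold,
                            5.0 * float(curve.sigma[idx]) / np.sqrt(window))
        if prom > threshold:
            return True
    return False


def compare_structure_factors(curve: ScatteringCurve, base_form_params: dict,
                              *, init: Optional[dict] = None,
                              bounds: Optional[dict] = None,
                              n_starts: int = 8, seed: int = DEFAULT_SEED,
                              fixed: Optional[dict] = None) -> dict:
    """Fit the interference peak with PY hard-sphere vs charged-sphere S(q).

    ``base_form_params`` carries the core–shell starting values shared by
    both fits.  Returns both :class:`FitResult`\\ s and their reduced-χ²
    ratio; when no peak is resolvable the fits are flagged instead.
    """
    peak = detect_interference_peak(curve)
    report = {"peak_detected": peak}
    common = dict(init or {})
    common.update(base_form_params)
    if not peak:
        flagged = FitResult(best_params={}, param_uncertainties={},
                            chi2_reduced=float("nan"), n_points=len(curve),
                            converged=False, model_id="peakless",
                            message="no resolvable interference peak")
        report["py"] = flagged
        report["hp"] = flagged
        report["chi2_ratio_hp_over_py"] = float("nan")
        return report

    py_init = dict(common)
    py_init.setdefault("hs_radius", common.get("outer_radius", 2.5))
    report["py"] = fit_model(curve, "core_shell_py", init=py_init, bounds=bounds,
                             n_starts=n_starts, seed=seed, fixed=fixed)
    report["hp"] = fit_model(curve, "core_shell_hp", init=common, bounds=bounds,
                             n_starts=n_starts, seed=seed, fixed=fixed)
    report["chi2_ratio_hp_over_py"] = (
        report["hp"].chi2_reduced / report["py"].chi2_reduced
        if report["py"].chi2_reduced else float("nan")
    )
    return report


# ---------------------------------------------------------------------------
# forward intensity I(0)
# ---------------------------------------------------------------------------

class GuinierForwardIntensity(BaseEstimator):
    """Model-independent forward-scattering I(0) estimator.

    ``method='guinier'`` fits ln I vs q² over a window iterated to
    q·Rg ≤ qrg_max (default 1.3, standard practice); ``method='plateau'``
    takes the uncertainty-weighted mean of the lowest-q decade.

    Attributes: ``i0_``, ``i0_stderr_``, ``rg_`` (guinier only), ``n_used_``.
    """

    def __init__(self, method: str = "guinier", qrg_max: float = 1.3,
                 min_points: int = 5):
        self.method = method
        self.qrg_max = qrg_max
        self.min_points = min_points

    def fit(self, q, intensity=None, sigma=None):
        curve = _as_curve(q, intensity, sigma)
        if self.method == "plateau":
            self._fit_plateau(curve)
        elif self.method == "guinier":
            self._fit_guinier(curve)
        else:
            raise ValueError("method must be 'guinier' or 'plateau'")
        return self

    def _fit_plateau(self, curve: ScatteringCurve) -> None:
        qmin = curve.q[0]
        mask = curve.q <= 10.0 * qmin
        if mask.sum() < self.min_points:
            raise InsufficientDataError(
                f"plateau needs >= {self.min_points} points in the lowest-q decade")
        y = curve.intensity[mask]
        if curve.sigma is not None:
            w = 1.0 / curve.sigma[mask] ** 2
            i0 = float(np.sum(w * y) / np.sum(w))
            se = float(np.sqrt(1.0 / np.sum(w)))
        else:
            i0 = float(np.mean(y))
            se = float(np.std(y, ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0
        self.i0_, self.i0_stderr_ = i0, se
        self.rg_ = float("nan")
        self.n_used_ = int(mask.sum())

    def _fit_guinier(self, curve: ScatteringCurve) -> None:
        pos = curve.intensity > 0
        q, I = curve.q[pos], curve.intensity[pos]
        sig = curve.sigma[pos] if curve.sigma is not None else None
        if q.size < self.min_points:
            raise InsufficientDataError("too few positive-intensity points")

        def wls(mask):
            x = q[mask] ** 2
            y = np.log(I[mask])
            w = (I[mask] / sig[mask]) ** 2 if sig is not None else np.ones(x.size)
            W = np.sum(w)
            xm, ym = np.sum(w * x) / W, np.sum(w * y) / W
            sxx = np.sum(w * (x - xm) ** 2)
            slope = np.sum(w * (x - xm) * (y - ym)) / sxx
            inter = ym - slope * xm
            resid = y - (inter + slope * x)
            dof = max(mask.sum() - 2, 1)
            s2 = np.sum(w * resid**2) / dof
            se_inter = np.sqrt(s2 * (1.0 / W + xm**2 / sxx))
            return slope, inter, se_inter

        # pass 0: lowest quarter of the grid (at least min_points)
        n0 = max(self.min_points, q.size // 4)
        mask = np.zeros(q.size, bool)
        mask[:n0] = True
        for _ in range(3):  # two-pass iteration of the q·Rg window
            slope, inter, se_inter = wls(mask)
            rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
            if rg == 0.0:
                break
            new_mask = q * rg <= self.qrg_max
            if new_mask.sum() < self.min_points:
                new_mask = np.zeros(q.size, bool)
                new_mask[: self.min_points] = True
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        if mask.sum() < self.min_points:
            raise InsufficientDataError("fewer than min_points usable low-q points")
        slope, inter, se_inter = wls(mask)
        i0 = float(np.exp(inter))
        self.i0_ = i0
        self.i0_stderr_ = float(i0 * se_inter)
        self.rg_ = float(np.sqrt(max(-3.0 * slope, 0.0)))
        self.n_used_ = int(mask.sum())


def forward_intensity(curve: ScatteringCurve, method: str = "guinier"):
    """I(0) in cm⁻¹ with standard error, by Guinier or low-q plateau."""
    est = GuinierForwardIntensity(method=method).fit(curve)
    return est.i0_, est.i0_stderr_


# ---------------------------------------------------------------------------
# power-law exponent
# ---------------------------------------------------------------------------

class PowerLawExponentFitter(BaseEstimator):
    """Weighted log–log regression; ``alpha_`` is the decay exponent of
    I(q) ∼ q^(−alpha) over ``q_range``."""

    def __init__(self, q_range: Optional[tuple] = None, min_points: int = 5):
        self.q_range = q_range
        self.min_points = min_points

    def fit(self, q, intensity=None, sigma=None):
        curve = _as_curve(q, intensity, sigma)
        q_lo, q_hi = self.q_range if self.q_range else (curve.q[0], curve.q[-1])
        mask = (curve.q >= q_lo) & (curve.q <= q_hi)
        if mask.sum() < self.min_points:
            raise InsufficientDataError(
                f"need >= {self.min_points} points in the q range")
        I = curve.intensity[mask]
        if np.any(I <= 0):
            raise ValueError("nonpositive intensities in the fit range")
        x = np.log(curve.q[mask])
        y = np.log(I)
        if curve.sigma is not None:
            w = (I / curve.sigma[mask]) ** 2
        else:
            w = np.ones(x.size)
        W = np.sum(w)
        xm, ym = np.sum(w * x) / W, np.sum(w * y) / W
        sxx = np.sum(w * (x - xm) ** 2)
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        resid = y - (ym + slope * (x - xm))
        dof = max(mask.sum() - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        self.alpha_ = float(-slope)
        self.alpha_stderr_ = float(np.sqrt(s2 / sxx))
        self.n_used_ = int(mask.sum())
        return self


def powerlaw_exponent(curve: ScatteringCurve, q_range: Optional[tuple] = None):
    """Decay exponent alpha (I ∼ q^−alpha) with standard error."""
    est = PowerLawExponentFitter(q_range=q_range).fit(curve)
    return est.alpha_, est.alpha_stderr_


# ---------------------------------------------------------------------------
# breakpoint (CMC) estimation
# ---------------------------------------------------------------------------

class BreakpointFitter(BaseEstimator):
    """Continuous two-segment piecewise-linear fit in log₁₀(x).

    The knot is located by grid search over interior positions followed
    by bounded refinement; significance against a single straight line is
    an F-test at ``alpha`` (default 0.05).

    Attributes: ``breakpoint_`` (linear units), ``slope_left_``,
    ``slope_right_``, ``breakpoint_stderr_``, ``significant_``,
    ``p_value_``, ``result_``.
    """

    def __init__(self, alpha: float = 0.05, n_grid: int = 201, log_x: bool = True):
        self.alpha = alpha
        self.n_grid = n_grid
        self.log_x = log_x

    @staticmethod
    def _rss(u, y, t):
        X = np.column_stack([np.ones_like(u), u - t, np.clip(u - t, 0.0, None)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid), coef

    def fit(self, x, y):
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 6:
            raise InsufficientDataError("breakpoint fit needs at least 6 points")
        order = np.argsort(x)
        x, y = x[order], y[order]
        if self.log_x:
            if np.any(x <= 0):
                raise ValueError("log-domain breakpoint fit needs x > 0")
            u = np.log10(x)
        else:
            u = x.copy()

        n = u.size
        # single-line reference
        X1 = np.column_stack([np.ones(n), u])
        coef1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(np.sum((y - X1 @ coef1) ** 2))

        t_lo, t_hi = u[1], u[-2]
        grid = np.linspace(t_lo, t_hi, self.n_grid)
        rss_grid = np.array([self._rss(u, y, t)[0] for t in grid])
        i_best = int(np.argmin(rss_grid))
        lo = grid[max(i_best - 1, 0)]
        hi = grid[min(i_best + 1, self.n_grid - 1)]
        opt = minimize_scalar(lambda t: self._rss(u, y, t)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        t_hat = float(opt.x)
        rss2, coef = self._rss(u, y, t_hat)

        # F-test: 2 extra parameters (knot + slope change) vs one line
        dof2 = n - 4
        if dof2 <= 0 or rss1 <= 0:
            significant = False
            p_value = float("nan")
        elif rss2 < 1e-12 * max(rss1, 1.0):
            # essentially exact two-segment fit
            significant = rss1 > 1e-10 * float(y @ y + 1.0)
            p_value = 0.0 if significant else float("nan")
        else:
            F = ((rss1 - rss2) / 2.0) / (rss2 / dof2)
            p_value = float(stats.f.sf(F, 2, dof2))
            significant = p_value < self.alpha

        slope_left = float(coef[1])
        slope_right = float(coef[1] + coef[2])

        # knot uncertainty from the curvature of the RSS profile
        s2 = rss2 / max(dof2, 1)
        dt = max((t_hi - t_lo) / (self.n_grid - 1), 1e-6)
        rp = self._rss(u, y, min(t_hat + dt, t_hi))[0]
        rm = self._rss(u, y, max(t_hat - dt, t_lo))[0]
        curv = (rp - 2.0 * rss2 + rm) / dt**2
        t_se = float(np.sqrt(2.0 * s2 / curv)) if curv > 0 else float("nan")

        if self.log_x:
            bp = 10.0**t_hat
            bp_se = bp * np.log(10.0) * t_se  # delta method
        else:
            bp, bp_se = t_hat, t_se

        if not significant and abs(coef[2]) < 1e-12 * (abs(coef[1]) + 1.0):
            bp = float("nan")  # collinear data: breakpoint undefined

        self.breakpoint_ = float(bp)
        self.breakpoint_stderr_ = float(bp_se)
        self.slope_left_ = slope_left
        self.slope_right_ = slope_right
        self.significant_ = bool(significant)
        self.p_value_ = p_value
        self.result_ = BreakpointResult(
            breakpoint=self.breakpoint_, slope_left=slope_left,
            slope_right=slope_right, breakpoint_uncertainty=self.breakpoint_stderr_,
            significant=self.significant_, p_value=p_value,
        )
        return self


def breakpoint_fit(x, y, *, alpha: float = 0.05, log_x: bool = True) -> BreakpointResult:
    """Two-segment breakpoint (e.g. CMC) estimate; see :class:`BreakpointFitter`."""
    return BreakpointFitter(alpha=alpha, log_x=log_x).fit(x, y).result_
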