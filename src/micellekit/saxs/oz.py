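"""Ornstein–Zernike solver with the mean-spherical-approximation closure.

This is the numerical engine behind the charged-sphere (Hayter–Penfold
type) structure factor: hard spheres of diameter ``d`` interacting through
a repulsive tail ``βu(r)`` (a screened-Coulomb/Yukawa potential in the
charged-micelle application).  The MSA closure is

    h(r) = -1            for r < d        (hard core)
    c(r) = -βu(r)        for r > d

and the OZ relation in Fourier space, ĥ = ĉ / (1 - ρ ĉ), links the two.
The solver iterates on the indirect correlation γ = h - c with Picard
mixing, using fast sine transforms for the 3-D radial Fourier pair.

For dilute charged systems the plain MSA yields the well-known unphysical
negative contact value g(d⁺) < 0; :func:`solve_rescaled_msa` then applies
the Hansen–Hayter rescaling: the hard-core diameter is inflated to
s·d (the tail potential left unchanged) with s chosen so that
g(s·d⁺) = 0, which is the standard low-volume-fraction fix for the
rescaled MSA of charged colloids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.fft import dst
from scipy.optimize import brentq


class OZConvergenceError(RuntimeError):
    """Raised when the OZ/MSA iteration or the rescaling root search fails."""


@dataclass
class OZSolution:
    """Converged OZ/MSA solution on the solver's internal grids."""

    r: np.ndarray          # nm, uniform, r_j = j*dr
    h: np.ndarray          # total correlation on r
    c: np.ndarray          # direct correlation on r
    q: np.ndarray          # nm^-1, uniform, q_k = pi*k/(n*dr)
    s_of_q: np.ndarray     # structure factor on q
    g_contact: float       # extrapolated g(d+)
    diameter: float        # (possibly rescaled) hard-core diameter, nm
    rescale_factor: float  # s such that diameter = s * d_input
    n_iterations: int

    def structure_factor(self, q_out: np.ndarray) -> np.ndarray:
        """Interpolate S(q) onto an arbitrary grid; S→1 beyond the grid."""
        from scipy.interpolate import CubicSpline

        spl = CubicSpline(self.q, self.s_of_q)
        q_out = np.asarray(q_out, dtype=float)
        out = np.ones_like(q_out)
        inside = q_out <= self.q[-1]
        out[inside] = spl(q_out[inside])
        return out


def _radial_ft(f: np.ndarray, r: np.ndarray, q: np.ndarray, dr: float) -> np.ndarray:
    # f̂(q) = 4π/q ∫ r f(r) sin(qr) dr on the uniform grid (DST-I quadrature)
    return (4.0 * np.pi * dr / q) * 0.5 * dst(r * f, type=1)


def _radial_ift(fhat: np.ndarray, r: np.ndarray, q: np.ndarray, dq: float) -> np.ndarray:
    # f(r) = 1/(2π² r) ∫ q f̂(q) sin(qr) dq
    return (dq / (2.0 * np.pi**2) / r) * 0.5 * dst(q * fhat, type=1)


def solve_msa(
    diameter: float,
    number_density: float,
    beta_u_tail: Optional[Callable[[np.ndarray], np.ndarray]],
    *,
    n_grid: int = 8192,
    dr: Optional[float] = None,
    tol: float = 1e-10,
    max_iter: int = 20000,
    mixing: float = 0.5,
    gamma_init: Optional[np.ndarray] = None,
) -> OZSolution:
    """Solve the OZ equation with the MSA closure for one component.

    Parameters
    ----------
    diameter : float
        Hard-core diameter d, nm.
    number_density : float
        Particle number density ρ, nm⁻³.
    beta_u_tail : callable or None
        Dimensionless tail potential βu(r) for r > d; ``None`` means pure
        hard spheres (then MSA coincides with the Percus–Yevick closure).
    n_grid, dr
        Radial grid: r_j = j·dr, j = 1..n_grid-1.  Default dr = d/60.
    tol, max_iter, mixing
        Picard iteration controls; the mixing parameter is halved
        adaptively when the residual grows.
    gamma_init : array, optional
        Warm-start for γ = h - c (must match the grid).

    Raises
    ------
    OZConvergenceError
        If the iteration does not reach ``tol`` or 1 - ρĉ crosses zero.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if number_density < 0:
        raise ValueError("number_density must be >= 0")
    if dr is None:
        dr = diameter / 60.0
    m = n_grid - 1
    j = np.arange(1, n_grid)
    r = j * dr
    dq = np.pi / (n_grid * dr)
    q = j * dq

    # fractional-cell weight of the hard core in each cell [r_j ± dr/2];
    # smoothing the closure across the discontinuity keeps the quadrature
    # second-order accurate in dr
    w_core = np.clip((diameter - (r - dr / 2.0)) / dr, 0.0, 1.0)
    core = w_core >= 1.0
    tail_pot = np.zeros(m)
    if beta_u_tail is not None:
        outside = w_core < 1.0
        tail_pot[outside] = beta_u_tail(r[outside])

    gamma = np.zeros(m) if gamma_init is None else np.array(gamma_init, dtype=float)
    if gamma.shape != r.shape:
        raise ValueError("gamma_init does not match the grid")

    rho = number_density
    mix = mixing
    prev_res = np.inf
    for it in range(1, max_iter + 1):
        c = w_core * (-1.0 - gamma) + (1.0 - w_core) * (-tail_pot)
        chat = _radial_ft(c, r, q, dr)
        denom = 1.0 - rho * chat
        if np.any(denom <= 0):
            raise OZConvergenceError(
                "1 - rho*c_hat(q) lost positivity: no physical MSA solution "
                f"at eta={rho * np.pi * diameter**3 / 6:.4g}"
            )
        gamma_hat = rho * chat**2 / denom
        gamma_new = _radial_ift(gamma_hat, r, q, dq)
        res = float(np.max(np.abs(gamma_new - gamma)))
        if res > prev_res * 1.5 and mix > 0.02:
            mix *= 0.5
        prev_res = res
        gamma = (1.0 - mix) * gamma + mix * gamma_new
        if res < tol:
            break
    else:
        raise OZConvergenceError(f"OZ/MSA iteration did not converge (residual {res:.3g})")

    c = w_core * (-1.0 - gamma) + (1.0 - w_core) * (-tail_pot)
    h = gamma + c
    chat = _radial_ft(c, r, q, dr)
    s_of_q = 1.0 / (1.0 - rho * chat)

    # contact value g(d+): quadratic extrapolation from the first points
    # fully outside the (smoothed) core boundary
    out_idx = np.nonzero(w_core <= 0.0)[0][:4]
    if out_idx.size >= 3:
        coeffs = np.polyfit(r[out_idx], h[out_idx], 2)
        g_contact = float(np.polyval(coeffs, diameter) + 1.0)
    else:
        g_contact = float(h[out_idx[0]] + 1.0) if out_idx.size else np.nan

    return OZSolution(r=r, h=h, c=c, q=q, s_of_q=s_of_q, g_contact=g_contact,
                      diameter=diameter, rescale_factor=1.0, n_iterations=it)


def solve_rescaled_msa(
    diameter: float,
    number_density: float,
    beta_u_tail: Optional[Callable[[np.ndarray], np.ndarray]],
    *,
    eta_max: float = 0.64,
    s_tol: float = 1e-5,
    warm_start: Optional["RescaledMSACache"] = None,
    **solver_kwargs,
) -> OZSolution:
    """MSA with the Hansen–Hayter low-volume-fraction rescaling.

    If the plain MSA solution already has g(d⁺) ≥ 0 it is returned as-is.
    Otherwise the hard-core diameter is inflated to s·d (tail unchanged)
    and s is found by root-bracketing on g(s·d⁺) = 0.
    """
    cache = warm_start
    eta = number_density * np.pi * diameter**3 / 6.0
    # keep one grid across all rescaled solves so warm starts line up
    solver_kwargs.setdefault("dr", diameter / 60.0)

    def solve_at(s: float) -> OZSolution:
        init = None
        if cache is not None and cache.gamma is not None:
            init = cache.gamma
        sol = solve_msa(diameter * s, number_density, beta_u_tail,
                        gamma_init=init, **solver_kwargs)
        if cache is not None:
            cache.gamma = sol.h - sol.c
        return sol

    s_max = (eta_max / eta) ** (1.0 / 3.0) if eta > 0 else 4.0

    # warm path: previous rescale factor usually brackets the new root tightly
    if (beta_u_tail is not None and cache is not None and cache.s is not None
            and 1.0 < cache.s < s_max):
        lo = max(1.0, cache.s * 0.97)
        hi = min(s_max, cache.s * 1.03)
        g_lo = solve_at(lo).g_contact
        g_hi = solve_at(hi).g_contact
        if g_lo < 0.0 < g_hi:
            s_root = brentq(lambda s: solve_at(s).g_contact, lo, hi, xtol=s_tol)
            sol = solve_at(s_root)
            sol.rescale_factor = s_root
            cache.s = s_root
            return sol

    sol1 = solve_at(1.0)
    if beta_u_tail is None or sol1.g_contact >= 0.0:
        if cache is not None:
            cache.s = None
        return sol1

    if s_max <= 1.0:
        raise OZConvergenceError("cannot rescale: volume fraction already at the cap")

    # g(s d+) grows with s; bracket the root
    lo, g_lo = 1.0, sol1.g_contact
    hi = min(1.3, s_max)
    g_hi = solve_at(hi).g_contact
    while g_hi < 0.0 and hi < s_max * 0.999:
        lo, g_lo = hi, g_hi
        hi = min(hi * 1.3, s_max)
        g_hi = solve_at(hi).g_contact
    if g_hi < 0.0:
        raise OZConvergenceError(
            "Hansen–Hayter rescaling found no g(contact)=0 root below the "
            f"packing cap (eta_rescaled max {eta_max})"
        )

    s_root = brentq(lambda s: solve_at(s).g_contact, lo, hi, xtol=s_tol)
    sol = solve_at(s_root)
    sol.rescale_factor = s_root
    if cache is not None:
        cache.s = s_root
    return sol


@dataclass
class RescaledMSACache:
    """Warm-start store for repeated nearby rescaled-MSA solves (fitting)."""

    gamma: Optional[np.ndarray] = None
    s: Optional[float] = None
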