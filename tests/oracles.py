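"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation's code paths: the OZ/MSA
solver here works in real space with bipolar-coordinate quadrature (no
fast sine transforms), the SASA oracle samples random points instead of
a Fibonacci set, and the core–shell oracle integrates the radial
density profile directly.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# real-space OZ solver with the MSA closure
# ---------------------------------------------------------------------------

class RealSpaceOZ:
    """OZ + MSA by direct real-space iteration.

    Unknowns are c(r) inside the hard core and h(r) outside; the radial
    convolution uses the bipolar identity
    (c*h)(r) = (2π/r) ∫ s c(s) [H(r+s) − H(|r−s|)] ds with H the
    cumulative of t·h(t), evaluated by trapezoid quadrature on a uniform
    grid with precomputed interpolation indices.
    """

    def __init__(self, diameter, number_density, beta_u_tail=None,
                 n_core=40, l_over_d=30.0):
        self.d = float(diameter)
        self.rho = float(number_density)
        self.tail = beta_u_tail
        # midpoint grid commensurate with the core so the hard-core
        # discontinuity falls exactly on a cell edge (keeps the midpoint
        # quadrature second order across the jump)
        self.h_step = self.d / n_core
        self.n = int(round(l_over_d * n_core))
        self.r = (np.arange(self.n) + 0.5) * self.h_step
        # precompute gather indices for H(r_i + s_j) and H(|r_i - s_j|)
        rp = self.r[:, None] + self.r[None, :]
        rm = np.abs(self.r[:, None] - self.r[None, :])
        self._idx_p, self._w_p = self._interp_setup(rp)
        self._idx_m, self._w_m = self._interp_setup(rm)
        self.inside = self.r < self.d
        self.bu = np.zeros(self.n)
        if beta_u_tail is not None:
            self.bu[~self.inside] = beta_u_tail(self.r[~self.inside])

    def _interp_setup(self, x):
        # linear interpolation on the midpoint-rule cumulative, which is
        # defined at cell edges k*h, k = 0..n
        pos = x / self.h_step
        idx = np.clip(pos.astype(int), 0, self.n - 1)
        w = np.clip(pos - idx, 0.0, 1.0)
        return idx, w

    def _convolve(self, c, h):
        # cum[k] = midpoint-rule ∫_0^{kh} t h(t) dt
        cum = np.concatenate([[0.0], np.cumsum(self.r * h)]) * self.h_step
        Hp = cum[self._idx_p] + self._w_p * (cum[self._idx_p + 1] - cum[self._idx_p])
        Hm = cum[self._idx_m] + self._w_m * (cum[self._idx_m + 1] - cum[self._idx_m])
        integrand = self.r[None, :] * c[None, :] * (Hp - Hm)
        return (2.0 * np.pi / self.r) * integrand.sum(axis=1) * self.h_step

    def _closure(self, gamma):
        # MSA: h = -1 in the core, c = -βu outside
        return np.where(self.inside, -1.0 - gamma, -self.bu)

    def solve(self, tol=1e-9, max_iter=20000, mixing=0.3):
        gamma = np.zeros(self.n)
        prev_res = np.inf
        for _ in range(max_iter):
            c = self._closure(gamma)
            gamma_new = self.rho * self._convolve(c, c + gamma)
            res = np.max(np.abs(gamma_new - gamma))
            if res < tol:
                gamma = gamma_new
                break
            if res > prev_res * 1.5:
                mixing = max(mixing * 0.5, 0.01)
            prev_res = res
            gamma = (1 - mixing) * gamma + mixing * gamma_new
        else:
            raise RuntimeError("real-space OZ iteration did not converge")
        self.c = self._closure(gamma)
        self.h = self.c + gamma
        return self

    def g_contact(self):
        out = np.nonzero(~self.inside)[0][:4]
        coeffs = np.polyfit(self.r[out], self.h[out], 2)
        return float(np.polyval(coeffs, self.d) + 1.0)

    def structure_factor(self, q):
        q = np.atleast_1d(np.asarray(q, float))
        hq = np.array([
            4.0 * np.pi / qi * np.sum(self.r * self.h * np.sin(qi * self.r)) * self.h_step
            for qi in q
        ])
        return 1.0 + self.rho * hq


def oz_msa_structure_factor(q, diameter, number_density, beta_u_tail=None,
                            rescale=True, n_core=40, l_over_d=30.0):
    """Rescaled-MSA S(q) by the real-space solver.

    Applies the same physical criterion as the implementation under
    test — inflate the core until g(contact) = 0 — but with its own
    machinery throughout.
    """
    def solved(dia):
        return RealSpaceOZ(dia, number_density, beta_u_tail, n_core=n_core,
                           l_over_d=l_over_d * diameter / dia).solve()

    sol = solved(diameter)
    if rescale and beta_u_tail is not None and sol.g_contact() < 0.0:
        eta = number_density * np.pi * diameter**3 / 6.0
        s_hi = min(1.3, (0.64 / eta) ** (1 / 3))
        while solved(s_hi * diameter).g_contact() < 0 and s_hi < (0.64 / eta) ** (1 / 3) * 0.99:
            s_hi = min(s_hi * 1.3, (0.64 / eta) ** (1 / 3))
        s_root = brentq(lambda s: solved(s * diameter).g_contact(), 1.0, s_hi,
                        xtol=1e-4)
        sol = solved(s_root * diameter)
    return sol.structure_factor(q)


# ---------------------------------------------------------------------------
# core–shell amplitude by radial quadrature
# ---------------------------------------------------------------------------

def core_shell_amplitude_quadrature(q, core_radius, outer_radius, rho_core,
                                    rho_shell, rho_solvent):
    """F(q) = 4π ∫ Δρ(r) r² sinc(qr) dr, densities e Å⁻³, radii nm.

    Direct adaptive quadrature of the excess radial density profile.
    """
    def dr_profile(r):
        if r < core_radius:
            return (rho_core - rho_solvent) * 1e3
        if r < outer_radius:
            return (rho_shell - rho_solvent) * 1e3
        return 0.0

    out = []
    for qi in np.atleast_1d(q):
        val, _ = quad(lambda r: dr_profile(r) * r**2 * np.sinc(qi * r / np.pi),
                      0.0, outer_radius, points=[core_radius], limit=200)
        out.append(4.0 * np.pi * val)
    return np.array(out)


# ---------------------------------------------------------------------------
# SASA by random-direction sampling
# ---------------------------------------------------------------------------

def sasa_random_oracle(positions, radii, probe=0.14, n_points=20000, seed=1234):
    """Shrake–Rupley area with a seeded random point set (not Fibonacci)."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    positions = np.asarray(positions, float)
    ext = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(positions)):
        sample = positions[i] + ext[i] * pts
        exposed = np.ones(n_points, bool)
        for j in range(len(positions)):
            if j == i:
                continue
            d2 = ((sample - positions[j]) ** 2).sum(axis=1)
            exposed &= d2 >= ext[j] ** 2
        total += 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
    return total
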