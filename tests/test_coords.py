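"""Radial density profiles, SASA, and aggregation propensity."""

import numpy as np
import pytest

from micellekit.coords import (
    aggregation_propensity,
    average_density_profile,
    fibonacci_sphere,
    radial_electron_density,
    sasa,
)
from micellekit.datatypes import CoordinateSet

from oracles import sasa_random_oracle


def _simple_set(positions, radius=0.17):
    n = len(positions)
    return CoordinateSet(positions=np.asarray(positions, float),
                         elements=np.array(["C"] * n, dtype=object),
                         electrons=np.full(n, 6.0),
                         radii=np.full(n, radius))


def _rotation(angles=(0.3, 1.1, -0.7)):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("zyx", angles).as_matrix()


class TestRadialDensity:
    def test_uniform_ball_profile_is_flat(self, uniform_ball):
        R = 2.0
        prof = radial_electron_density(uniform_ball, bin_width=0.4, r_max=2.4)
        expected = len(uniform_ball) / (4.0 / 3.0 * np.pi * R**3) / 1e3  # e/A^3
        mask = prof.bin_centers < 0.8 * R
        assert np.max(np.abs(prof.electron_density[mask] / expected - 1.0)) < 0.02

    def test_electron_conservation(self, uniform_ball):
        prof = radial_electron_density(uniform_ball, bin_width=0.05)
        edges = np.arange(prof.bin_centers.size + 1) * prof.bin_width
        shell_vol_a3 = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3) * 1e3
        total = float(np.sum(prof.electron_density * shell_vol_a3))
        assert total == pytest.approx(float(uniform_ball.electrons.sum()), rel=1e-9)

    def test_rotation_and_translation_invariance(self, packed_micelle):
        prof = radial_electron_density(packed_micelle, bin_width=0.1)
        moved = CoordinateSet(
            positions=packed_micelle.positions @ _rotation().T + np.array([3.0, -1.0, 8.0]),
            elements=packed_micelle.elements, electrons=packed_micelle.electrons,
            radii=packed_micelle.radii)
        prof2 = radial_electron_density(moved, bin_width=0.1)
        assert np.allclose(prof.electron_density, prof2.electron_density, rtol=1e-6)

    def test_frame_averaging_is_plain_mean(self, packed_micelle):
        from micellekit.synthetic import make_micelle_coordinates

        other = make_micelle_coordinates(30, seed=12)
        avg = average_density_profile([packed_micelle, other], bin_width=0.1)
        r_max = avg.bin_centers[-1] + avg.bin_width / 2
        p1 = radial_electron_density(packed_micelle, bin_width=0.1, r_max=r_max)
        p2 = radial_electron_density(other, bin_width=0.1, r_max=r_max)
        assert np.allclose(avg.electron_density,
                           (p1.electron_density + p2.electron_density) / 2,
                           rtol=1e-12)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            radial_electron_density(_simple_set(np.zeros((3, 3))))


class TestSasa:
    def test_single_sphere_analytic_area(self):
        cs = _simple_set([[0.0, 0.0, 0.0]], radius=0.2)
        total, per_atom = sasa(cs, probe_radius=0.14, n_points=960)
        exact = 4.0 * np.pi * (0.2 + 0.14) ** 2
        assert total == pytest.approx(exact, rel=0.01)
        assert per_atom[0] == pytest.approx(total)

    def test_distant_atoms_are_additive(self):
        cs = _simple_set([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], radius=0.2)
        total, _ = sasa(cs)
        assert total == pytest.approx(2 * 4.0 * np.pi * 0.34**2, rel=0.01)

    def test_overlapping_pair_matches_random_point_oracle(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.25, 0.0, 0.0]])
        cs = _simple_set(pos)
        total, _ = sasa(cs)
        oracle = sasa_random_oracle(pos, cs.radii, n_points=50000)
        assert total == pytest.approx(oracle, rel=0.02)

    def test_area_decreases_monotonically_with_approach(self):
        separations = [2.0, 0.6, 0.4, 0.3, 0.2, 0.1]
        areas = []
        for d in separations:
            cs = _simple_set([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            areas.append(sasa(cs)[0])
        assert all(b < a + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_rigid_motion_invariance(self, packed_micelle):
        base, _ = sasa(packed_micelle)
        moved = CoordinateSet(
            positions=packed_micelle.positions @ _rotation().T + np.array([5.0, -3.0, 2.0]),
            elements=packed_micelle.elements, electrons=packed_micelle.electrons,
            radii=packed_micelle.radii)
        rotated, _ = sasa(moved)
        assert abs(rotated - base) / base < 1e-6

    def test_fibonacci_points_lie_on_unit_sphere(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # near-uniform: mean nearest-neighbour distance close to the ideal
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].std() / d[:, 1].mean() < 0.25

    def test_too_few_points_rejected(self, packed_micelle):
        with pytest.raises(ValueError):
            sasa(packed_micelle, n_points=16)


class TestAggregationPropensity:
    def test_identical_configurations_give_unity(self, packed_micelle):
        assert aggregation_propensity(packed_micelle, packed_micelle) == 1.0

    def test_dispersed_chains_have_larger_area_than_micelle(
            self, packed_micelle, dispersed_chains):
        ap = aggregation_propensity(dispersed_chains, packed_micelle)
        assert ap > 1.3

    def test_invariant_under_uniform_scaling(self, packed_micelle, dispersed_chains):
        def scaled(cs, s):
            return CoordinateSet(positions=cs.positions * s, elements=cs.elements,
                                 electrons=cs.electrons, radii=cs.radii * s)

        ap = aggregation_propensity(dispersed_chains, packed_micelle,
                                    probe_radius=0.14)
        ap_half = aggregation_propensity(scaled(dispersed_chains, 0.5),
                                         scaled(packed_micelle, 0.5),
                                         probe_radius=0.07)
        assert ap_half == pytest.approx(ap, rel=1e-9)

    def test_partially_expanded_micelle_reproduces_paper_scale_ap(self, packed_micelle):
        """A 30-chain system built so the true area ratio is 1.36.

        Each rigid chain of the packed micelle is translated radially
        outward by 0.555 nm; the independent random-point oracle pins the
        true initial/final area ratio at 1.36 for this construction.
        """
        per = len(packed_micelle.positions) // 30
        chains = packed_micelle.positions.reshape(30, per, 3)
        dirs = chains.mean(axis=1)
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        expanded = CoordinateSet(
            positions=(chains + 0.555 * dirs[:, None, :]).reshape(-1, 3),
            elements=packed_micelle.elements, electrons=packed_micelle.electrons,
            radii=packed_micelle.radii)

        oracle_ratio = (sasa_random_oracle(expanded.positions, expanded.radii,
                                           n_points=5000)
                        / sasa_random_oracle(packed_micelle.positions,
                                             packed_micelle.radii, n_points=5000))
        assert oracle_ratio == pytest.approx(1.36, abs=0.01)

        ap = aggregation_propensity(expanded, packed_micelle)
        assert ap == pytest.approx(1.36, abs=0.03)
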