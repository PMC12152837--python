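import numpy as np
import pytest

from micellekit.datatypes import CoordinateSet


def uniform_ball_coordinates(radius=2.0, spacing=0.04, seed=7) -> CoordinateSet:
    """Uniform-density ball of unit-electron point atoms.

    A jittered lattice: each cell contributes exactly one point uniformly
    distributed within it, so the density is exactly uniform in
    expectation and the shell-count variance is confined to cells cut by
    the ball surface.
    """
    rng = np.random.default_rng(seed)
    g = np.arange(-radius, radius + spacing, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts + rng.uniform(-spacing / 2, spacing / 2, pts.shape)
    pts = pts[np.linalg.norm(pts, axis=1) < radius]
    n = len(pts)
    return CoordinateSet(
        positions=pts,
        elements=np.array(["C"] * n, dtype=object),
        electrons=np.ones(n),
        radii=np.full(n, 0.17),
    )


@pytest.fixture(scope="session")
def uniform_ball() -> CoordinateSet:
    return uniform_ball_coordinates()


@pytest.fixture(scope="session")
def packed_micelle():
    from micellekit.synthetic import make_micelle_coordinates

    return make_micelle_coordinates(30, seed=11)


@pytest.fixture(scope="session")
def dispersed_chains():
    from micellekit.synthetic import make_micelle_coordinates

    return make_micelle_coordinates(30, seed=11, arrangement="dispersed")
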