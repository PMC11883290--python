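import numpy as np
import pytest

from endocast import phantom as ph

#: 4 vertices of the unit right tetrahedron (legs along the axes)
UNIT_RIGHT_TET = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                           [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture
def unit_right_tet():
    return UNIT_RIGHT_TET.copy()


def random_cloud(seed: int, n: int = 30, scale: float = 1.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return scale * rng.normal(size=(n, 3))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Default-geometry phantom with exact markers (shared; treat read-only)."""
    spec = ph.PhantomSpec(marker_noise_sd=0.0)
    return ph.phantom_pose_series(spec)


@pytest.fixture(scope="session")
def default_scene():
    """Phantom at the full default study conditions (noisy markers)."""
    return ph.phantom_pose_series(ph.PhantomSpec())


def sphere_fit_circumradius(tet: np.ndarray) -> float:
    """Independent circumradius oracle: sphere through four points via the
    general-sphere linear system x^2+y^2+z^2 + Dx + Ey + Fz + G = 0."""
    A = np.column_stack([tet, np.ones(4)])
    b = -np.sum(tet**2, axis=1)
    try:
        D, E, F, G = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    if abs(np.linalg.det(A)) < 1e-12:
        return np.inf
    center = -0.5 * np.array([D, E, F])
    r2 = float(center @ center - G)
    return np.sqrt(r2) if r2 > 0 else np.inf
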