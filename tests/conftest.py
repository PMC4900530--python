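import numpy as np
import pytest

from aperturekit import HelicospiralSpec, generate_shell, reference_shell_set

#: circular helix r=2, c=1: kappa = 2/5, tau = 1/5 exactly
HELIX_SPEC = HelicospiralSpec(
    r0=2.0,
    k=0.0,
    pitch=1.0,
    n_whorls=3.0,
    n_apertures=400,
    ring_size=16,
    aperture_axes=(0.3, 0.25),
    aperture_growth=1.0,
    shell_id="helix",
)


@pytest.fixture(scope="session")
def helix():
    """400-aperture circular-helix shell with its analytic truth."""
    return generate_shell(HELIX_SPEC)


@pytest.fixture(scope="session")
def helix_shell(helix):
    return helix[0]


@pytest.fixture(scope="session")
def reference_set():
    """The eight-shell synthetic study set (bases + transforms + composite)."""
    return reference_shell_set(seed=0)


@pytest.fixture(scope="session")
def toy_grid():
    """Minimal valid 3-ring x 4-vertex square tube."""
    from aperturekit import RetopologisedShellMesh

    sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    verts = np.vstack([sq + [0, 0, z] for z in (0.0, 0.5, 1.0)])
    return RetopologisedShellMesh("toy", verts, 3, 4)


def tilted_circle(n=200, radius=2.0, seed=3):
    """Points on a circle of given radius in a randomly tilted plane."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)]
    )
    R = Rotation.random(rng=rng).as_matrix()
    return pts @ R.T + rng.normal(size=3)
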