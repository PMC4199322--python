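import numpy as np
import pytest

from hgmap import SimConfig, TriangleMesh, make_mesh_and_leadfield, simulate_session


@pytest.fixture(scope="session")
def small_mesh_lf():
    return make_mesh_and_leadfield(60, 16, seed=7)


@pytest.fixture(scope="session")
def tiny_session(small_mesh_lf):
    mesh, lf = small_mesh_lf
    cfg = SimConfig(n_trials_per_hand=6, n_channels=16, artifact_rate=0.0, seed=11)
    ts, emg, eog, truth = simulate_session(cfg, mesh, lf)
    return cfg, ts, emg, eog, truth


def flat_grid_mesh(nx: int = 10, ny: int = 10, spacing: float = 5.0) -> TriangleMesh:
    """Planar triangulated grid with known coordinates (mm), for geometry tests."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    vertices = np.c_[xs.ravel(), ys.ravel(), np.zeros(nx * ny)]
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return TriangleMesh(vertices, np.asarray(faces))


@pytest.fixture(scope="session")
def grid_mesh():
    return flat_grid_mesh()
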