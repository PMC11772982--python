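import numpy as np
import pytest

from sulcalvar.config import FeatureWeights, SimulationConfig
from sulcalvar.sulcal_graph import SurfaceMesh


def make_grid_mesh(nx: int, ny: int, depth_fn, spacing: float = 1.0,
                   region: str = "hemisphere") -> SurfaceMesh:
    """Regular triangulated grid in the z=0 plane with a depth function."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    vertices = np.column_stack([
        xs.ravel() * spacing, ys.ravel() * spacing,
        np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = i * ny + j + 1
            d = (i + 1) * ny + j + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    depth = np.array([depth_fn(v[0], v[1]) for v in vertices])
    return SurfaceMesh(vertices=vertices, faces=np.array(faces),
                       depth=depth, region=region)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    return SimulationConfig(
        seed=7, n_case=10, n_control=12, n_annotations=70,
        variants_per_participant_mean=10.0,
        effect_annotation_count=10, planted_module_sizes=(25, 25),
        n_template_nodes=8,
    )


@pytest.fixture
def default_weights():
    return FeatureWeights()
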