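import itertools

import numpy as np
import pytest

from projdense.axon_quant import skeleton_graph_from_voxels


def brute_force_skeleton_length_mm(voxels: np.ndarray, spacing_um) -> float:
    """Independent oracle: sum anisotropic distances over every ordered pair
    of 26-adjacent foreground voxels, divided by two."""
    coords = np.argwhere(voxels)
    spacing = np.asarray(spacing_um, dtype=float)
    total = 0.0
    for a, b in itertools.product(coords, repeat=2):
        d = a - b
        if np.any(d) and np.all(np.abs(d) <= 1):
            total += float(np.sqrt(((d * spacing) ** 2).sum()))
    return total / 2.0 / 1000.0


@pytest.fixture
def random_voxel_cloud():
    """Sparse random boolean volumes for graph-length oracle checks."""
    def make(seed, shape=(6, 7, 8), density=0.15):
        rng = np.random.default_rng(seed)
        return rng.random(shape) < density

    return make
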