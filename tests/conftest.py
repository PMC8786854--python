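import numpy as np
import pytest

from axonseg import imgen
from axonseg.core import InstanceMap


@pytest.fixture(scope="session")
def fiber_fixture():
    """Small synthetic image/mask pair shared across tests."""
    cfg = imgen.FixtureConfig(
        image_height=256, image_width=256, n_fibers=20, seed=2
    )
    return imgen.generate_fiber_field(cfg)


@pytest.fixture(scope="session")
def clumped_fixture():
    cfg = imgen.FixtureConfig(
        image_height=256, image_width=256, n_fibers=30, clump_fraction=0.9, seed=5
    )
    return imgen.generate_fiber_field(cfg)


def random_instance_pair(seed: int, shape=(64, 64), n_seeds: int = 20):
    """Correlated random instance maps for matching tests.

    Ground truth is a nearest-seed (Voronoi) labeling with some cells
    dropped to background; the prediction is the same labeling shifted by
    up to 2 px with independent cell drops, so IoUs span the whole range
    around the 0.5 matching threshold.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    seeds = rng.uniform(0, [h, w], size=(n_seeds, 2))
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    cells = d2.argmin(axis=-1).astype(np.int32) + 1

    def variant(labels, drop_p, dy, dx):
        out = np.roll(np.roll(labels, dy, axis=0), dx, axis=1)
        out = out.copy()
        for lab in range(1, n_seeds + 1):
            if rng.random() < drop_p:
                out[out == lab] = 0
        return out

    gt = variant(cells, 0.2, 0, 0)
    pred = variant(cells, 0.2, int(rng.integers(-2, 3)), int(rng.integers(-2, 3)))
    return InstanceMap(pred), InstanceMap(gt)
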