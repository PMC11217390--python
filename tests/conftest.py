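import numpy as np
import pytest

from sansml.dataset import ImageCollection
from sansml.instrument import N_COLS, N_ROWS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_collection(images, labels):
    """Wrap raw image stacks into an ImageCollection with minimal metadata."""
    import pandas as pd

    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    meta = pd.DataFrame(
        {
            "model": [f"m{int(t)}" for t in labels],
            "label": labels,
            "config_id": 0,
            "wavelength_A": 6.0,
            "collimation_m": 8.0,
            "sdd_m": 8.0,
            "slit_id": 0,
            "holder_mm": 1.0,
            "absorption": 0.0,
            "seed": np.arange(len(labels)),
            "ok": True,
        }
    )
    return ImageCollection(images=images, targets=labels.astype(np.int64), meta=meta)


@pytest.fixture
def tiny_collection():
    """60 random non-negative detector images over 5 labels."""
    g = np.random.default_rng(7)
    imgs = g.random((60, N_ROWS, N_COLS)).astype(np.float32)
    labels = np.repeat(np.arange(5), 12)
    return make_collection(imgs, labels)
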