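import numpy as np
import pandas as pd
import pytest

from metabocontrast.containers import FeatureMatrix
from metabocontrast.simulate import SimConfig


def make_matrix(values, samples=None, features=None, below_lod=None):
    """Small FeatureMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"s{i+1}" for i in range(n)]
    features = features or [f"f{j+1}" for j in range(p)]
    frame = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"),
                         columns=features)
    lod = None
    if below_lod is not None:
        lod = pd.DataFrame(np.asarray(below_lod, dtype=bool),
                           index=frame.index, columns=frame.columns)
        frame = frame.mask(lod)
    return FeatureMatrix(frame, lod)


@pytest.fixture
def small_config():
    """Reduced-size study configuration for fast tests."""
    return SimConfig(
        n_per_cohort={"LLS": 400, "RS": 400},
        n_mz_pairs=120,
        n_dz_pairs=80,
        seed=11,
    )


@pytest.fixture
def tiny_twin_config():
    return SimConfig(n_per_cohort={"LLS": 50}, n_mz_pairs=60, n_dz_pairs=40, seed=5)
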