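import numpy as np
import pandas as pd
import pytest

import chromage as c


@pytest.fixture(scope="session")
def small_image_fixture():
    spec = c.ImageFixtureSpec(n_nuclei=6, field_shape=(160, 160), seed=11)
    return spec, c.make_image_fixture(spec)


@pytest.fixture(scope="session")
def drift_table():
    """Feature table with mean drift along the first coordinate."""
    spec = c.TableFixtureSpec(n_animals_per_group=3, cells_per_animal=400,
                              n_features=20, noise_sd=1.0, seed=7)
    return spec, c.make_feature_fixture(spec)


@pytest.fixture(scope="session")
def small_pipeline_result(drift_table):
    _, table = drift_table
    cfg = c.RunConfig(bootstrap=c.BootstrapConfig(100, 60, seed=5),
                      split=c.SplitConfig(n_iterations=5, seed=6))
    return c.run_axis_pipeline(table, cfg)


def brute_force_tas(binary: np.ndarray) -> np.ndarray:
    """Independent O(n * 3^d) per-pixel neighbor scan."""
    b = np.asarray(binary, dtype=bool)
    n_bins = 3**b.ndim
    fg = np.argwhere(b)
    if len(fg) == 0:
        return np.zeros(n_bins)
    counts = np.zeros(n_bins)
    offsets = [d for d in np.ndindex(*(3,) * b.ndim) if d != (1,) * b.ndim]
    for coord in fg:
        k = 0
        for off in offsets:
            nb = coord + np.array(off) - 1
            if np.all(nb >= 0) and np.all(nb < b.shape) and b[tuple(nb)]:
                k += 1
        counts[k] += 1
    return counts / len(fg)
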