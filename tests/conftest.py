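import numpy as np
import pandas as pd
import pytest

import ramanbone as rb
from ramanbone import preprocess as pp
from ramanbone import synth


@pytest.fixture(scope="session")
def small_config():
    """One subject per week: 4 x (35 + 60) = 380 spectra."""
    return rb.default_config(subjects_per_week=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Simulated small study with its clean (noise-free peak) signals."""
    sset, profile, truth, clean = synth.simulate_study(
        small_config, seed=101, return_clean=True
    )
    return sset, profile, truth, clean


@pytest.fixture(scope="session")
def small_preprocessed(small_study):
    sset, profile, _, _ = small_study
    out, log = pp.preprocess_pipeline(sset, profile)
    return out, log


@pytest.fixture(scope="session")
def small_metrics(small_preprocessed):
    from ramanbone import bands

    out, _ = small_preprocessed
    return bands.metrics_table(out)


@pytest.fixture()
def tiny_set():
    """Two handmade spectra on a short axis, for I/O round trips."""
    axis = np.arange(900.0, 1701.0, 2.0)
    rng = np.random.default_rng(7)
    intensities = rng.uniform(1.0, 10.0, (2, axis.size))
    meta = pd.DataFrame(
        {
            "spectrum_id": ["a1", "a2"],
            "subject_id": ["m1", "m1"],
            "week": [0, 2],
            "bone": ["femur", "spine"],
            "site": [4, "L5"],
            "replicate": [1, 2],
            "stage": ["raw", "raw"],
        }
    )
    return rb.SpectrumSet(axis=axis, intensities=intensities, meta=meta)
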