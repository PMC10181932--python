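import numpy as np
import pytest

from tfdose import SimulationConfig, generate_dose_series, tmm_normalize


@pytest.fixture(scope="session")
def six_by_seven_dosages():
    """Per-sample dosages of the default 6-level x 7-replicate design."""
    return np.repeat([100.0, 72.0, 51.0, 36.0, 18.0, 4.0], 7)


@pytest.fixture(scope="session")
def small_series():
    """A small simulated titration with hill/linear/null features and a
    null background, TMM-normalized."""
    cfg = SimulationConfig(
        n_features_down=20, n_features_up=20, n_features_linear=10,
        n_features_null=200, seed=42,
    )
    counts, meta, truth = generate_dose_series(cfg)
    cpm = tmm_normalize(counts, meta)
    return cfg, counts, meta, truth, cpm
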