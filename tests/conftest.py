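import numpy as np
import pytest

import eegpathlab as epl


@pytest.fixture(scope="session")
def tiny_dataset():
    """Strongly separated 6-channel dataset small enough for fast end-to-end
    runs: 9 recordings per class, 100 s at 250 Hz.  Nine per class keeps six
    per class in a 70/30 training split, the smallest group size at which a
    two-group rank test can reach p < 0.01."""
    spec = epl.separable_spec(n_channels=6, duration_s=100.0, n_per_class=9, seed=3)
    return epl.generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_cfg():
    return epl.PipelineConfig(
        montage=epl.CANONICAL_MONTAGE[:6],
        max_segments=20,
        n_csp=4,
        classifier=epl.ClassifierConfig(backend="xgboost", n_estimators=150),
        seed=3,
    )


@pytest.fixture(scope="session")
def edf_dir(tmp_path_factory, tiny_dataset):
    """Two fixture recordings written as EDF with a labels.csv sidecar."""
    d = tmp_path_factory.mktemp("edf")
    epl.write_fixture_edf([tiny_dataset[0], tiny_dataset[-1]], d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
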