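import numpy as np
import pandas as pd
import pytest

from megstrat.bands import BAND_MAP
from megstrat.cohort import CohortConfig
from megstrat.features import FeatureMatrix

ALPHA = BAND_MAP["alpha"]


def make_feature_matrix(X: np.ndarray, labels, prefix: str = "pow_alpha_"
                        ) -> FeatureMatrix:
    """Wrap a plain array + labels into a FeatureMatrix with power-style names."""
    n, m = X.shape
    ids = [f"s{i:03d}" for i in range(n)]
    cols = [f"{prefix}{k}" for k in range(m)]
    values = pd.DataFrame(X, index=ids, columns=cols)
    lab = pd.Series(list(labels), index=ids, name="group")
    meta = pd.DataFrame([{"type": "power", "band": "alpha", "roi": k,
                          "i": -1, "j": -1} for k in range(m)], index=cols)
    return FeatureMatrix(values, lab, meta)


@pytest.fixture
def fm_factory():
    return make_feature_matrix


@pytest.fixture
def tiny_config():
    """A minimal, fast cohort configuration: alpha band only, 64 Hz, clean
    (no between-subject jitter), used for construction-level checks."""
    return CohortConfig(
        n_per_group={"PTSD": 3, "TC": 3, "mTBI": 3, "NTC": 3},
        n_regions=5, fs=64.0, epoch_len=10.0, n_epochs=3,
        base_band_amplitudes={"alpha": 0.7}, bands=(ALPHA,),
        amp_jitter_subject=0.0, amp_jitter_region=0.0,
        coupling_jitter=0.0, global_coupling=0.0, seed=11)


@pytest.fixture
def gaussian_groups():
    """Four-group Gaussian feature data with two informative features."""
    rng = np.random.default_rng(42)
    n_per = 15
    labels = np.repeat(["PTSD", "TC", "mTBI", "NTC"], n_per)
    X = rng.standard_normal((4 * n_per, 20))
    X[labels == "PTSD", 0] += 3.0
    X[labels == "mTBI", 1] += 3.0
    return X, labels
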