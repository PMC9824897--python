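import numpy as np
import pytest

import hybridseek as hs


@pytest.fixture(scope="session")
def short_record():
    """A 20 s, 2-channel synthetic record with one seizure at [12, 15) s."""
    cfg = hs.SynthRecordConfig(
        duration_s=20.0,
        n_channels=2,
        seizure_times=[(12.0, 15.0)],
        preictal_horizon_s=8.0,
        seed=1,
    )
    return hs.generate_record(cfg)


@pytest.fixture(scope="session")
def planted_dataset():
    """Feature matrix with 5 informative of 40 columns at effect size 3."""
    cfg = hs.SynthFeatureConfig(
        n_samples=400, n_features=40, n_informative=5, effect_size=3.0, seed=3
    )
    X, y, informative = hs.generate_feature_dataset(cfg)
    return X, y, informative


@pytest.fixture(scope="session")
def separable_1d():
    """1-D data separable at 0: negatives below, positives above."""
    rng = np.random.default_rng(0)
    x_neg = -rng.uniform(0.5, 2.0, 30)
    x_pos = rng.uniform(0.5, 2.0, 30)
    X = np.concatenate([x_neg, x_pos])[:, None]
    y = np.concatenate([np.zeros(30, int), np.ones(30, int)])
    return X, y
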