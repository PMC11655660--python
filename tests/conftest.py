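import numpy as np
import pandas as pd
import pytest

from specdecode import EpochSet, SimConfig, gen_epoch_set
from specdecode.containers import make_channel_table
from specdecode.simulate import Evoked


@pytest.fixture(scope="session")
def small_epochs():
    """Two-subject, six-channel cohort with an evoked transient and an
    alpha oscillation; shared across read-only tests."""
    cfg = SimConfig(
        n_subjects=2,
        n_trials_per_condition=10,
        n_channels=6,
        seed=11,
        evoked=Evoked(latency=0.1, duration=0.3, amplitude=1.0),
    )
    epochs, truth = gen_epoch_set(cfg)
    return epochs, truth, cfg


def manual_epochs(data, fs=200.0, t0=-1.0, kinds=None, labels=None):
    """Hand-built EpochSet for targeted preprocessing tests."""
    n_epochs, n_channels, _ = data.shape
    kinds = kinds or ["eeg"] * n_channels
    if labels is None:
        labels = pd.DataFrame(
            {
                "subject": "S00",
                "task": "WM",
                "content": "alphanumeric",
                "demand": np.where(np.arange(n_epochs) % 2 == 0, "easy", "hard"),
                "trial": np.arange(n_epochs),
            }
        )
    return EpochSet(
        data=data, fs=fs, t0=t0, channels=make_channel_table(kinds), labels=labels
    )


@pytest.fixture
def gaussian_features():
    """Feature-level two-class Gaussian factory: one subject's trials."""

    def _make(n_per_class=40, n_features=8, effect=0.0, informative=None, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((2 * n_per_class, n_features))
        y = np.repeat(["easy", "hard"], n_per_class)
        if effect:
            sel = informative if informative is not None else slice(None)
            X[n_per_class:, sel] += effect
        return X, y

    return _make
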