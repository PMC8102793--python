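import numpy as np
import pandas as pd
import pytest

from pafmod.config import SimConfig, default_posterior_labels
from pafmod.preprocess import EpochSet


@pytest.fixture
def tiny_sim() -> SimConfig:
    """Two-subject, one-block cohort small enough for per-test simulation."""
    return SimConfig(n_females=1, n_males=1, n_blocks=1, trials_per_block=8,
                     n_channels=8, posterior_channels=default_posterior_labels(8, 5),
                     seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_epochs(data: np.ndarray, fs: float = 64.0, n_eog: int = 1,
                task_types=None, correct=None, t0: float = -2.0) -> EpochSet:
    """EpochSet around a raw (trials, channels, samples) array; last ``n_eog``
    channels are EOG, the rest posterior scalp."""
    n_trials, n_ch, n_samp = data.shape
    labels = [f"c{i}" for i in range(n_ch)]
    roles = {lab: ("EOG" if i >= n_ch - n_eog else "posterior")
             for i, lab in enumerate(labels)}
    if task_types is None:
        task_types = np.tile(["2P", "2R", "3P", "3R"],
                             int(np.ceil(n_trials / 4)))[:n_trials]
    if correct is None:
        correct = np.ones(n_trials, dtype=bool)
    meta = pd.DataFrame({"task_type": task_types, "correct": correct,
                         "rt_ms": np.full(n_trials, 700.0)})
    return EpochSet(data=data, sampling_rate=fs, channel_labels=labels,
                    channel_roles=roles,
                    time_axis=t0 + np.arange(n_samp) / fs, trial_meta=meta)
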