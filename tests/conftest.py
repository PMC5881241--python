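import numpy as np
import pytest

import oddballerp as ob


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete study: 2 subjects, 1:12:1 ratio kept."""
    return ob.make_config(
        n_subjects=2, n_targets=20, n_deviants=20, n_standards=240, seed=42
    )


@pytest.fixture(scope="session")
def tiny_pooled(tiny_config):
    """Pooled classification-branch epochs for both conditions (tiny study)."""
    return {
        cond: ob.pooled_condition_epochs(tiny_config, cond)
        for cond in ("simple", "dual")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate=250.0, labels=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i + 1}" for i in range(data.shape[0]))
    return ob.Recording(data=data, rate=rate, channel_labels=labels)


def make_epochs(data, rate=25.0, t0=0.0, labels=None, trial_labels=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i + 1}" for i in range(data.shape[1]))
    if trial_labels is None:
        trial_labels = np.array(["target"] * data.shape[0], dtype=object)
    return ob.EpochSet(
        data=data, rate=rate, t0_offset_ms=t0, channel_labels=labels,
        labels=np.asarray(trial_labels, dtype=object),
    )
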