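import numpy as np
import pytest

import emgelm as eg


@pytest.fixture(scope="session")
def small_protocol():
    """Four movements, three repetitions, short bursts: fast but structurally
    identical to the full assays."""
    return eg.Protocol(
        n_movements=4,
        n_repetitions=3,
        movement_duration_s=1.0,
        rest_duration_s=0.6,
        sample_rate_hz=2000.0,
        n_channels=4,
    )


@pytest.fixture(scope="session")
def small_subject(small_protocol):
    return eg.SubjectModel.random(
        small_protocol.n_movements, small_protocol.n_channels, seed=11
    )


@pytest.fixture(scope="session")
def small_recording(small_protocol, small_subject):
    return eg.generate_trial(small_protocol, small_subject)


@pytest.fixture(scope="session")
def small_table(small_recording):
    return eg.segment_and_extract(small_recording, eg.WindowSpec(200, 10), "true")


def random_feature_table(n=200, d=10, n_classes=3, seed=0):
    """A labeled random feature matrix for solver tests."""
    rng = np.random.default_rng(seed)
    return eg.FeatureTable(
        X=rng.normal(size=(n, d)),
        y=rng.integers(0, n_classes, size=n),
        feature_names=[f"f{i}" for i in range(d)],
        window_starts=np.arange(n),
    )


def burst_onsets(labels):
    labels = np.asarray(labels)
    on = np.flatnonzero((labels[1:] != 0) & (labels[:-1] == 0)) + 1
    if labels[0] != 0:
        on = np.concatenate(([0], on))
    return on


def burst_runs(labels):
    """(start, end, class) per nonzero run."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends) if labels[s] != 0]
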