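import numpy as np
import pytest

from fcsweep import ConnectivityMatrix


def make_matrix(weights, subject_id="s", measure="wpli", labels=None, group=""):
    w = np.asarray(weights, dtype=float)
    if labels is None:
        labels = [f"n{i:02d}" for i in range(w.shape[0])]
    return ConnectivityMatrix(
        subject_id=subject_id, measure=measure, band=(8.0, 13.0),
        node_labels=list(labels), weights=w, group=group,
    )


@pytest.fixture
def k4_matrix():
    """Complete 4-node graph with distinct weights 0.1 ... 0.6."""
    w = np.zeros((4, 4))
    w[np.triu_indices(4, 1)] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    return make_matrix(w + w.T, labels=list("abcd"))


@pytest.fixture
def random_matrix():
    """64-node symmetric matrix with all-distinct continuous weights."""
    rng = np.random.default_rng(7)
    n = 64
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return make_matrix(a)


@pytest.fixture(scope="session")
def sine_pair():
    """Factory: two 10 Hz sinusoids at a constant phase lag, 60 s at 256 Hz."""
    def _make(lag, sfreq=256.0, f0=10.0, duration=60.0):
        from fcsweep.synthcohort import Recording

        t = np.arange(int(sfreq * duration)) / sfreq
        x = np.cos(2 * np.pi * f0 * t)
        y = np.cos(2 * np.pi * f0 * t - lag)
        return Recording("pair", "", np.vstack([x, y]), sfreq, epoch_length=1024)

    return _make
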