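import numpy as np
import pytest

from fcsfrap import BeamGeometry


@pytest.fixture
def geom() -> BeamGeometry:
    """Calibrated geometry used throughout: 145 nm waist, structure parameter 5."""
    return BeamGeometry(wxy=0.145, s=5.0)


@pytest.fixture
def lag_grid() -> np.ndarray:
    """200 log-spaced lags from 0.01 ms to 1 s, the standard fit window."""
    return np.geomspace(1e-5, 1.0, 200)


def brute_force_multitau(counts, bin_width, channels_per_octave=16):
    """Naive re-implementation of the multi-tau estimator, loops and all.

    Independently computes, for every channel, the symmetrically normalized
    correlation of the mean-rebinned trace by direct summation. Used as the
    oracle the fast implementation must match exactly.
    """
    x = [float(v) for v in counts]
    dt = bin_width
    m = channels_per_octave
    lags, g = [], []
    level = 0
    while True:
        block = 2**level
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            n_pairs = len(x) - k
            if n_pairs < 2:
                break
            s = sum(x[i] * x[i + k] for i in range(n_pairs))
            mu_l = sum(x[:n_pairs]) / n_pairs
            mu_r = sum(x[k:]) / n_pairs
            raw = k * block
            lags.append(((raw - (block - 1)) * (raw + (block - 1))) ** 0.5 * dt)
            g.append(s / (n_pairs * mu_l * mu_r) - 1.0)
        level += 1
        half = len(x) // 2
        x = [0.5 * (x[2 * i] + x[2 * i + 1]) for i in range(half)]
        if len(x) < m + 2:
            break
    return np.array(lags), np.array(g)
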