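"""Multi-tau autocorrelation of binned photon-count traces.

A software correlator replacing the hardware correlator of an FCS
instrument: it turns a uniformly binned intensity trace into a
fluctuation-normalized autocorrelation curve g(tau) on a quasi-logarithmic
lag grid, and averages replicate curves (e.g. the ten 10-second runs
acquired per cell) into the mean curve used for fitting.

The estimator is symmetrically normalized: at each lag the product sum is
divided by the means of the two (left and right) trace segments actually
entering the sum, which removes the bias that slow monotonic drifts such as
acquisition photobleaching would otherwise introduce. Uncorrelated signal
gives g = 0 and Poisson-emitting diffusers give g(0) ~ 1/N, matching the
amplitude convention of the analytic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityTrace", "CorrelationCurve", "multitau_autocorrelate", "average_curves"]


@dataclass(frozen=True)
class IntensityTrace:
    """Uniformly binned photon counts.

    ``bin_width`` is in seconds; ``counts`` holds one non-negative photon
    count per bin.
    """

    bin_width: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def duration(self) -> float:
        """Total trace duration in seconds."""
        return self.bin_width * self.counts.size

    @property
    def mean_rate(self) -> float:
        """Mean count rate in photons per second."""
        return float(self.counts.mean()) / self.bin_width


@dataclass(frozen=True)
class CorrelationCurve:
    """Autocorrelation amplitudes on a strictly increasing lag grid (seconds)."""

    lags: np.ndarray
    g: np.ndarray
    n_replicates: int = 1
    sd: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValueError("lags and g must be 1D arrays of equal length")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("g must be finite")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != g.shape:
                raise ValueError("sd must match g in shape")
            object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)

    def __len__(self) -> int:
        return self.lags.size


def _rebin_by_two(x: np.ndarray) -> np.ndarray:
    n = x.size // 2
    return 0.5 * (x[: 2 * n : 2] + x[1 : 2 * n : 2])


def _symmetric_g(x: np.ndarray, k: int) -> float:
    # g(k) = <x_t x_{t+k}> / (<x_t><x_{t+k}>) - 1 over the overlapping window
    left = x[:-k]
    right = x[k:]
    mu_l = left.mean()
    mu_r = right.mean()
    if mu_l == 0 or mu_r == 0:
        raise ValueError("trace segment has zero mean; correlation undefined")
    return float(np.dot(left, right) / (left.size * mu_l * mu_r) - 1.0)


def multitau_autocorrelate(
    trace: IntensityTrace, channels_per_octave: int = 16
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a binned intensity trace.

    The lag grid is quasi-logarithmic: the first ``channels_per_octave``
    lags are single-bin spaced, then the trace is mean-rebinned by two and
    the upper half of the channels repeated at each coarser level until the
    rebinned trace runs out. Each channel's lag is reported at the
    geometric mean of the span of raw lags it averages over, which for the
    finest level is the exact lag itself.

    Parameters
    ----------
    trace : IntensityTrace
        Binned photon counts; must contain at least ``2 * channels_per_octave``
        bins and have a positive mean.
    channels_per_octave : int
        Number of correlator channels per doubling of the lag (even, >= 4).
    """
    m = int(channels_per_octave)
    if m < 4 or m % 2:
        raise ValueError("channels_per_octave must be an even integer >= 4")
    x = np.asarray(trace.counts, dtype=float)
    if x.size < 2 * m:
        raise ValueError(
            f"trace too short: {x.size} bins < {2 * m} required for {m} channels/octave"
        )
    if x.mean() == 0:
        raise ValueError("all-zero trace: mean intensity is zero")

    dt = trace.bin_width
    lags: list[float] = []
    g: list[float] = []

    level = 0
    while True:
        block = 2**level
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            if x.size - k < 2:
                break
            raw_lag = k * block  # lag in units of the original bin width
            lo, hi = raw_lag - (block - 1), raw_lag + (block - 1)
            lags.append(float(np.sqrt(lo * hi)) * dt)
            g.append(_symmetric_g(x, k))
        level += 1
        x = _rebin_by_two(x)
        if x.size < m + 2:
            break

    return CorrelationCurve(lags=np.array(lags), g=np.array(g), n_replicates=1)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of replicate correlation curves sharing one lag grid.

    Returns the averaged curve with the per-lag standard deviation across
    replicates attached (``sd`` is None for a single input).
    """
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    ref = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != ref.shape or not np.array_equal(c.lags, ref):
            raise ValueError("all curves must share an identical lag grid")
    stack = np.vstack([c.g for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else None
    return CorrelationCurve(
        lags=ref.copy(),
        g=stack.mean(axis=0),
        n_replicates=len(curves),
        sd=sd,
    )
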