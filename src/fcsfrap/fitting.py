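"""Nonlinear least-squares fitting of FCS autocorrelation and FRAP recovery curves.

The ACF fits use the calibrated detection-volume geometry with the structure
parameter held fixed, restrict the fit to lags above a configurable cutoff
(0.01 ms by default, below which afterpulsing and shot noise dominate
measured curves), and run a small multistart over log-spaced diffusion-time
initializations to avoid the local minima of the two-time-scale model. The
two-component model is parameterized with tau_d2 = tau_d1 * (1 + exp(u)) so
the fast/slow ordering is built in and no label swapping can occur.

Model selection between the one-component 3D and the two-component 3D+2D
model operationalizes the visual judgement "the one-component model does not
fit" as an AIC comparison, optionally backed by a Wald–Wolfowitz runs test
on the one-component residuals: structured (non-random) residuals are the
signature of a missing slow component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from statsmodels.sandbox.stats.runs import runstest_1samp

from .correlator import CorrelationCurve
from .models import (
    ACFParams1C,
    ACFParams2C,
    BeamGeometry,
    FRAPParams,
    acf_one_component,
    acf_two_component,
    diffusion_from_tau,
    frap_model,
    mobile_fraction,
)

__all__ = [
    "FitConfig",
    "ACFFitResult",
    "FRAPFitResult",
    "fit_acf",
    "fit_calibration",
    "select_model",
    "normalize_frap",
    "fit_frap",
]

ONE_COMPONENT = "one_component_3d"
TWO_COMPONENT = "two_component_3d2d"

_MIN_LAGS = 8
_TAU_INIT_RANGE = (1e-6, 1.0)  # seconds, spans free dye to membrane diffusion


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by the ACF and FRAP fitting routines.

    ``min_lag``/``max_lag`` bound the fitted lag window in seconds (the
    default cutoff excludes lags below 0.01 ms). ``multistart_count``
    controls how many log-spaced diffusion-time initializations are tried;
    ``model_selection_criterion`` is ``"aic"`` or ``"aic_plus_runs_test"``.
    ``weighting`` is ``"unit"`` or ``"sd"`` (inverse per-lag standard
    deviation, available when replicate curves were averaged).
    """

    min_lag: float = 1e-5
    max_lag: float | None = None
    multistart_count: int = 8
    rng_seed: int = 0
    tolerance: float = 1e-12
    model_selection_criterion: str = "aic"
    runs_test_alpha: float = 0.05
    weighting: str = "unit"

    def __post_init__(self) -> None:
        if self.min_lag < 0:
            raise ValueError("min_lag must be non-negative")
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")
        if self.model_selection_criterion not in ("aic", "aic_plus_runs_test"):
            raise ValueError(
                f"unknown model_selection_criterion {self.model_selection_criterion!r}"
            )
        if self.weighting not in ("unit", "sd"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class ACFFitResult:
    """Result of fitting an autocorrelation curve.

    Diffusion coefficients are derived from the fitted translational times
    through the fixed geometry (D = wxy^2 / 4 tau_d); ``slow_fraction_pct``
    is 100 * (1 - F1) for the two-component model and None otherwise.
    ``aic`` is the Akaike information criterion used for model selection.
    """

    model_id: str
    params: ACFParams1C | ACFParams2C | None
    geom: BeamGeometry
    d_fast: float | None
    d_slow: float | None
    slow_fraction_pct: float | None
    residuals: np.ndarray
    lags: np.ndarray
    sse: float
    aic: float
    converged: bool

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "converged": self.converged,
            "sse": self.sse,
            "aic": self.aic,
            "d_fast_um2_per_s": self.d_fast,
            "d_slow_um2_per_s": self.d_slow,
            "slow_fraction_pct": self.slow_fraction_pct,
            "geom": {"wxy_um": self.geom.wxy, "s": self.geom.s},
        }
        if isinstance(self.params, ACFParams1C):
            d["params"] = {"n_particles": self.params.n_particles, "tau_d_s": self.params.tau_d}
        elif isinstance(self.params, ACFParams2C):
            d["params"] = {
                "n_particles": self.params.n_particles,
                "f1": self.params.f1,
                "tau_d1_s": self.params.tau_d1,
                "tau_d2_s": self.params.tau_d2,
            }
        else:
            d["params"] = None
        return d


@dataclass(frozen=True)
class FRAPFitResult:
    """Result of fitting a normalized FRAP recovery curve."""

    params: FRAPParams | None
    t_half: float | None
    mobile_fraction_pct: float | None
    residuals: np.ndarray
    times: np.ndarray
    sse: float
    converged: bool

    def to_dict(self) -> dict:
        d = {
            "converged": self.converged,
            "sse": self.sse,
            "t_half_s": self.t_half,
            "mobile_fraction_pct": self.mobile_fraction_pct,
        }
        if self.params is not None:
            d["params"] = {
                "fd": self.params.fd,
                "fi": self.params.fi,
                "m_s": self.params.m,
                "alpha": self.params.alpha,
            }
        else:
            d["params"] = None
        return d


def _fit_window(curve: CorrelationCurve, config: FitConfig):
    hi = np.inf if config.max_lag is None else config.max_lag
    mask = (curve.lags >= config.min_lag) & (curve.lags <= hi)
    if mask.sum() < _MIN_LAGS:
        raise ValueError(
            f"only {int(mask.sum())} lags in the fit window "
            f"[{config.min_lag}, {hi}] s; need at least {_MIN_LAGS}"
        )
    lags = curve.lags[mask]
    g = curve.g[mask]
    if config.weighting == "sd" and curve.sd is not None:
        sd = curve.sd[mask]
        w = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 1.0)
    else:
        w = np.ones_like(g)
    return lags, g, w


def _n_aic(n: int, sse: float, k: int, scale: float) -> float:
    # floor the SSE at numerical noise so perfect fits are ranked by
    # parameter count, not by machine-epsilon residual differences
    floor = n * (100 * np.finfo(float).eps * max(scale, 1e-300)) ** 2
    return n * np.log(max(sse, floor) / n) + 2 * k


def _failed_acf(model_id, geom, lags, g, config) -> ACFFitResult:
    sse = float(np.sum(g**2))
    k = 2 if model_id == ONE_COMPONENT else 4
    return ACFFitResult(
        model_id=model_id, params=None, geom=geom, d_fast=None, d_slow=None,
        slow_fraction_pct=None, residuals=g.copy(), lags=lags, sse=sse,
        aic=_n_aic(lags.size, sse, k, float(np.max(np.abs(g), initial=1.0))),
        converged=False,
    )


def _tau_starts(config: FitConfig) -> np.ndarray:
    return np.geomspace(*_TAU_INIT_RANGE, num=config.multistart_count)


def fit_acf(
    curve: CorrelationCurve,
    model_id: str,
    geom: BeamGeometry,
    config: FitConfig | None = None,
) -> ACFFitResult:
    """Weighted least-squares fit of one ACF model with the geometry fixed.

    ``model_id`` is ``"one_component_3d"`` or ``"two_component_3d2d"``.
    Non-convergence (including unidentifiable curves with no positive
    amplitude) is reported through the ``converged`` flag, not an exception.
    """
    config = config or FitConfig()
    lags, g, w = _fit_window(curve, config)
    g_max = float(np.max(g))
    if g_max <= 0:
        return _failed_acf(model_id, geom, lags, g, config)
    n0 = 1.0 / g_max

    tol = config.tolerance

    if model_id == ONE_COMPONENT:
        def resid(x):
            p = ACFParams1C(n_particles=np.exp(x[0]), tau_d=np.exp(x[1]))
            return w * (acf_one_component(lags, p, geom) - g)

        starts = [np.array([np.log(n0), np.log(t)]) for t in _tau_starts(config)]
        bounds = (-np.inf, np.inf)
        k = 2
    elif model_id == TWO_COMPONENT:
        def resid(x):
            tau1 = np.exp(x[2])
            p = ACFParams2C(
                n_particles=np.exp(x[0]), f1=x[1],
                tau_d1=tau1, tau_d2=tau1 * (1.0 + np.exp(x[3])),
            )
            return w * (acf_two_component(lags, p, geom) - g)

        starts = [
            np.array([np.log(n0), 0.5, np.log(t), np.log(30.0)])
            for t in _tau_starts(config)
        ]
        # nested start from the one-component solution: lets the fit collapse
        # onto it exactly when the data carry no slow component
        fit1 = fit_acf(curve, ONE_COMPONENT, geom, config)
        if fit1.params is not None:
            starts.append(np.array([
                np.log(fit1.params.n_particles), 1.0,
                np.log(fit1.params.tau_d), -20.0,
            ]))
        bounds = (
            np.array([-np.inf, 1e-9, -np.inf, -20.0]),
            np.array([np.inf, 1.0, np.inf, 30.0]),
        )
        k = 4
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                resid, x0, bounds=bounds, xtol=tol, ftol=tol, gtol=tol, max_nfev=2000
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return _failed_acf(model_id, geom, lags, g, config)

    x = best.x
    if model_id == ONE_COMPONENT:
        params: ACFParams1C | ACFParams2C = ACFParams1C(
            n_particles=float(np.exp(x[0])), tau_d=float(np.exp(x[1]))
        )
        model = acf_one_component(lags, params, geom)
        d_fast = diffusion_from_tau(params.tau_d, geom)
        d_slow = slow_pct = None
    else:
        tau1 = float(np.exp(x[2]))
        params = ACFParams2C(
            n_particles=float(np.exp(x[0])), f1=float(x[1]),
            tau_d1=tau1, tau_d2=tau1 * (1.0 + float(np.exp(x[3]))),
        )
        model = acf_two_component(lags, params, geom)
        d_fast = diffusion_from_tau(params.tau_d1, geom)
        d_slow = diffusion_from_tau(params.tau_d2, geom)
        slow_pct = 100.0 * (1.0 - params.f1)

    residuals = g - model
    sse = float(np.sum((w * residuals) ** 2))
    return ACFFitResult(
        model_id=model_id, params=params, geom=geom,
        d_fast=d_fast, d_slow=d_slow, slow_fraction_pct=slow_pct,
        residuals=residuals, lags=lags, sse=sse,
        aic=_n_aic(lags.size, sse, k, g_max), converged=bool(best.success),
    )


def fit_calibration(
    curve: CorrelationCurve,
    standard,
    config: FitConfig | None = None,
) -> tuple[BeamGeometry, ACFParams1C, float]:
    """Calibrate the detection-volume geometry from a reference-dye ACF.

    Fits the one-component 3D model with the structure parameter free (the
    only fit in which it is), then converts the fitted diffusion time to the
    lateral beam waist through the dye's known diffusion coefficient.
    Returns the calibrated geometry, the fitted ACF parameters and the SSE.
    The structure parameter obtained here is what cell fits hold fixed.
    """
    from .models import beam_waist_from_calibration  # local to avoid cycle noise

    config = config or FitConfig()
    lags, g, w = _fit_window(curve, config)
    g_max = float(np.max(g))
    if g_max <= 0:
        raise ValueError("calibration curve has no positive amplitude")
    n0 = 1.0 / g_max

    def resid(x):
        geom = BeamGeometry(wxy=1.0, s=1.0 + np.exp(x[2]))
        p = ACFParams1C(n_particles=np.exp(x[0]), tau_d=np.exp(x[1]))
        return w * (acf_one_component(lags, p, geom) - g)

    best = None
    for t0 in _tau_starts(config):
        x0 = np.array([np.log(n0), np.log(t0), np.log(4.0)])
        res = least_squares(
            resid, x0, xtol=config.tolerance, ftol=config.tolerance,
            gtol=config.tolerance, max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    params = ACFParams1C(
        n_particles=float(np.exp(best.x[0])), tau_d=float(np.exp(best.x[1]))
    )
    s = 1.0 + float(np.exp(best.x[2]))
    wxy = beam_waist_from_calibration(params.tau_d, standard)
    return BeamGeometry(wxy=wxy, s=s), params, float(2 * best.cost)


def _residuals_nonrandom(residuals: np.ndarray, alpha: float) -> bool:
    """True when a runs test rejects randomness of the residual signs."""
    signs = residuals[residuals != 0]
    if signs.size < 10:
        return False
    _, pvalue = runstest_1samp(signs, cutoff=0, correction=False)
    return bool(pvalue < alpha)


def select_model(
    curve: CorrelationCurve,
    geom: BeamGeometry,
    config: FitConfig | None = None,
) -> tuple[str, ACFFitResult]:
    """Fit both ACF models and pick one.

    The two-component model is returned only when it is preferred by the
    configured criterion: lower AIC, and — under ``aic_plus_runs_test`` —
    additionally a runs test rejecting randomness of the one-component
    residuals at ``runs_test_alpha``.
    """
    config = config or FitConfig()
    fit1 = fit_acf(curve, ONE_COMPONENT, geom, config)
    fit2 = fit_acf(curve, TWO_COMPONENT, geom, config)

    if fit2.converged and not fit1.converged:
        return TWO_COMPONENT, fit2
    if fit1.converged and not fit2.converged:
        return ONE_COMPONENT, fit1

    prefer_two = fit2.aic < fit1.aic
    if prefer_two and config.model_selection_criterion == "aic_plus_runs_test":
        prefer_two = _residuals_nonrandom(fit1.residuals, config.runs_test_alpha)
    if prefer_two:
        return TWO_COMPONENT, fit2
    return ONE_COMPONENT, fit1


def normalize_frap(
    times: np.ndarray,
    i_bleach: np.ndarray,
    i_cell: np.ndarray,
    i_background: np.ndarray,
    plateau_fraction: float = 0.2,
    smooth_frames: int = 3,
) -> np.ndarray:
    """Bleach-corrected, plateau-normalized FRAP recovery curve.

    Computes (Ib - Bg) / (Ic - Bg) frame by frame — dividing by the
    whole-cell signal cancels acquisition photobleaching — then normalizes
    by the highest value in the plateau, taken as the maximum of a
    ``smooth_frames``-frame moving average over the last ``plateau_fraction``
    of frames so a single noise spike cannot set the scale.
    """
    times = np.asarray(times, dtype=float)
    ib = np.asarray(i_bleach, dtype=float)
    ic = np.asarray(i_cell, dtype=float)
    bg = np.asarray(i_background, dtype=float)
    if not (times.shape == ib.shape == ic.shape == bg.shape):
        raise ValueError("times, i_bleach, i_cell and i_background must have equal length")
    denom = ic - bg
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(
            f"cell intensity does not exceed background at frame {int(bad[0])} "
            f"(t = {times[bad[0]]:g} s)"
        )
    frap = (ib - bg) / denom

    n = frap.size
    n_plateau = max(int(np.ceil(plateau_fraction * n)), min(smooth_frames, n))
    window = frap[n - n_plateau:]
    if window.size >= smooth_frames:
        kernel = np.ones(smooth_frames) / smooth_frames
        smoothed = np.convolve(window, kernel, mode="valid")
    else:
        smoothed = window
    peak = float(np.max(smoothed))
    if peak <= 0:
        raise ValueError("plateau maximum is non-positive; cannot normalize")
    return frap / peak


def fit_frap(
    times: np.ndarray,
    curve: np.ndarray,
    config: FitConfig | None = None,
) -> FRAPFitResult:
    """Least-squares fit of the anomalous-diffusion recovery model.

    ``times`` are seconds since the end of the bleach (first acquired
    post-bleach frame at one frame interval); the half-recovery time and
    mobile fraction are derived from the fitted parameters.
    """
    config = config or FitConfig()
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if times.shape != curve.shape:
        raise ValueError("times and curve must have equal length")
    if times.size < 8:
        raise ValueError(f"need at least 8 frames, got {times.size}")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    t_pos = times[times > 0]
    m_lo = float(t_pos.min()) if t_pos.size else 0.1
    m_hi = float(times.max())

    def resid(x):
        fd, dfi, logm, alpha = x
        fi = fd + np.exp(dfi)
        p_ok = fi <= FRAPParams._FI_MAX
        fi = min(fi, FRAPParams._FI_MAX)
        p = FRAPParams(fd=fd, fi=fi, m=np.exp(logm), alpha=alpha)
        r = frap_model(times, p) - curve
        return r if p_ok else r + 1e3 * (fd + np.exp(dfi) - FRAPParams._FI_MAX)

    fd0 = float(np.clip(curve[0], 0.0, 0.95))
    plateau0 = float(np.clip(np.mean(curve[-max(3, times.size // 5):]), fd0 + 1e-3, 1.05))
    bounds = (
        np.array([0.0, np.log(1e-9), np.log(m_lo / 10), 0.01]),
        np.array([0.999, np.log(1.2), np.log(m_hi * 10), 2.0]),
    )
    best = None
    for m0 in np.geomspace(max(m_lo, 1e-3), m_hi, num=config.multistart_count):
        x0 = np.array([fd0, np.log(max(plateau0 - fd0, 1e-6)), np.log(m0), 1.0])
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(
                resid, x0, bounds=bounds,
                xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
                max_nfev=2000,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FRAPFitResult(
            params=None, t_half=None, mobile_fraction_pct=None,
            residuals=curve.copy(), times=times, sse=float(np.sum(curve**2)),
            converged=False,
        )

    fd, dfi, logm, alpha = best.x
    fi = min(fd + float(np.exp(dfi)), FRAPParams._FI_MAX)
    fi = max(fi, fd + 1e-12)  # degenerate flat curves: keep fd < fi
    params = FRAPParams(fd=float(fd), fi=float(fi), m=float(np.exp(logm)), alpha=float(alpha))
    residuals = curve - frap_model(times, params)
    return FRAPFitResult(
        params=params, t_half=params.m,
        mobile_fraction_pct=100.0 * mobile_fraction(params),
        residuals=residuals, times=times, sse=float(np.sum(residuals**2)),
        converged=bool(best.success),
    )
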