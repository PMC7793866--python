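"""Closed-form diffusion models for confocal fluorescence fluctuation analysis.

This module evaluates the autocorrelation functions (ACFs) used to analyse
fluorescence correlation spectroscopy (FCS) measurements of a protein that
partitions between a freely diffusing cytosolic pool and a membrane-bound
pool, the anomalous-diffusion recovery model used for fluorescence recovery
after photobleaching (FRAP), and the calibration relations that link
translational diffusion times to diffusion coefficients through the geometry
of the confocal detection volume.

Conventions
-----------
* The detection volume is a 3D Gaussian with lateral 1/e**2 waist ``wxy``
  (micrometres) and axial extent ``s * wxy``, where ``s`` is the structure
  parameter (axial-to-lateral ratio).
* Times are seconds and lengths micrometres everywhere in this module;
  millisecond lag axes are converted at the I/O boundary.
* ACF amplitudes are fluctuation-normalized: ``G(0) = 1/N`` where ``N`` is
  the mean number of particles in the detection volume, and ``G -> 0`` at
  long lags (no additive offset term, no triplet term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamGeometry",
    "ACFParams1C",
    "ACFParams2C",
    "FRAPParams",
    "CalibrationStandard",
    "acf_one_component",
    "acf_two_component",
    "frap_model",
    "diffusion_from_tau",
    "beam_waist_from_calibration",
    "mobile_fraction",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Calibrated confocal detection-volume geometry.

    Parameters
    ----------
    wxy : float
        Lateral 1/e**2 beam-waist radius in micrometres.
    s : float
        Structure parameter: ratio of axial to lateral extent of the
        detection volume. Dimensionless, > 1 for a confocal volume
        elongated along the optical axis.
    """

    wxy: float
    s: float

    def __post_init__(self) -> None:
        if not self.wxy > 0:
            raise ValueError(f"wxy must be positive, got {self.wxy}")
        if not self.s > 1:
            raise ValueError(f"structure parameter s must exceed 1, got {self.s}")


@dataclass(frozen=True)
class ACFParams1C:
    """Parameters of the one-component free 3D diffusion ACF.

    ``n_particles`` is the mean occupancy N of the detection volume and
    ``tau_d`` the translational diffusion time in seconds.
    """

    n_particles: float
    tau_d: float

    def __post_init__(self) -> None:
        if not self.n_particles > 0:
            raise ValueError(f"n_particles must be positive, got {self.n_particles}")
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")


@dataclass(frozen=True)
class ACFParams2C:
    """Parameters of the two-component (fast 3D + slow 2D) diffusion ACF.

    ``f1`` is the amplitude fraction of the fast, freely 3D-diffusing
    component; ``1 - f1`` is the fraction of the slow component diffusing
    in 2D within a membrane. ``tau_d1 < tau_d2`` is enforced so that
    component 1 is always the fast one.
    """

    n_particles: float
    f1: float
    tau_d1: float
    tau_d2: float

    def __post_init__(self) -> None:
        if not self.n_particles > 0:
            raise ValueError(f"n_particles must be positive, got {self.n_particles}")
        if not 0 < self.f1 <= 1:
            raise ValueError(f"f1 must lie in (0, 1], got {self.f1}")
        if not 0 < self.tau_d1 < self.tau_d2:
            raise ValueError(
                f"need 0 < tau_d1 < tau_d2, got tau_d1={self.tau_d1}, tau_d2={self.tau_d2}"
            )


@dataclass(frozen=True)
class FRAPParams:
    """Parameters of the anomalous-diffusion FRAP recovery model.

    ``fd`` is the normalized fluorescence immediately after bleaching,
    ``fi`` the normalized plateau fluorescence, ``m`` the half-recovery
    time t_1/2 in seconds and ``alpha`` the anomalous exponent (alpha = 1
    is simple diffusion-like recovery).
    """

    fd: float
    fi: float
    m: float
    alpha: float

    # fi may slightly exceed 1 on noisy normalized data
    _FI_MAX = 1.05

    def __post_init__(self) -> None:
        if not 0 <= self.fd < self.fi <= self._FI_MAX:
            raise ValueError(
                f"need 0 <= fd < fi <= {self._FI_MAX}, got fd={self.fd}, fi={self.fi}"
            )
        if not self.m > 0:
            raise ValueError(f"half-recovery time m must be positive, got {self.m}")
        if not 0 < self.alpha <= 2:
            raise ValueError(f"alpha must lie in (0, 2], got {self.alpha}")


@dataclass(frozen=True)
class CalibrationStandard:
    """A dye of known diffusion coefficient used to calibrate the beam waist.

    The default is Atto-488 in aqueous solution at 37 degrees Celsius,
    whose diffusion coefficient is taken as 400 um^2/s.
    """

    d_ref: float = 400.0
    label: str = "Atto-488"
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if not self.d_ref > 0:
            raise ValueError(f"d_ref must be positive, got {self.d_ref}")


def _as_nonnegative_lags(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag times must be non-negative")
    return tau


def acf_one_component(tau, params: ACFParams1C, geom: BeamGeometry):
    """One-component free 3D diffusion autocorrelation G(tau).

    G(tau) = (1/N) * (1 + tau/tau_d)^-1 * (1 + tau/(s^2 tau_d))^-1/2

    Accepts scalar or array ``tau`` (seconds); returns matching shape.
    """
    tau = _as_nonnegative_lags(tau)
    x = tau / params.tau_d
    g = (1.0 / params.n_particles) / (1.0 + x) / np.sqrt(1.0 + x / geom.s**2)
    return g if g.ndim else float(g)


def acf_two_component(tau, params: ACFParams2C, geom: BeamGeometry):
    """Two-component autocorrelation: fast free 3D plus slow free 2D diffusion.

    G(tau) = (1/N) * [ F1 * (1 + tau/tau_d1)^-1 * (1 + tau/(s^2 tau_d1))^-1/2
                       + (1 - F1) * (1 + tau/tau_d2)^-1 ]

    The 2D term has no axial factor: a membrane-confined diffuser never
    leaves the focal plane, so only lateral transit depopulates the volume.
    """
    tau = _as_nonnegative_lags(tau)
    x1 = tau / params.tau_d1
    x2 = tau / params.tau_d2
    g3d = params.f1 / (1.0 + x1) / np.sqrt(1.0 + x1 / geom.s**2)
    g2d = (1.0 - params.f1) / (1.0 + x2)
    g = (g3d + g2d) / params.n_particles
    return g if g.ndim else float(g)


def frap_model(t, params: FRAPParams):
    """Anomalous-diffusion FRAP recovery curve.

    F(t) = (fd + fi * (t/m)^alpha) / (1 + (t/m)^alpha)

    F(0) = fd, F(m) = (fd + fi)/2 and F -> fi as t -> infinity; the
    anomalous exponent alpha controls the sharpness of the recovery in the
    crowded intracellular environment.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since bleach must be non-negative")
    with np.errstate(over="ignore"):
        x = (t / params.m) ** params.alpha
        f = np.where(
            np.isinf(x), params.fi, (params.fd + params.fi * x) / (1.0 + x)
        )
    return f if f.ndim else float(f)


def diffusion_from_tau(tau_d: float, geom: BeamGeometry) -> float:
    """Diffusion coefficient (um^2/s) from a translational time via D = wxy^2 / (4 tau_d)."""
    if not tau_d > 0:
        raise ValueError(f"tau_d must be positive, got {tau_d}")
    return geom.wxy**2 / (4.0 * tau_d)


def beam_waist_from_calibration(
    tau_d_measured: float, standard: CalibrationStandard
) -> float:
    """Lateral beam waist (um) from the measured diffusion time of a reference dye.

    Inverts D = wxy^2 / (4 tau_d) for wxy given the dye's known diffusion
    coefficient: wxy = sqrt(4 * d_ref * tau_d).
    """
    if not tau_d_measured > 0:
        raise ValueError(f"tau_d_measured must be positive, got {tau_d_measured}")
    return float(np.sqrt(4.0 * standard.d_ref * tau_d_measured))


def mobile_fraction(params: FRAPParams) -> float:
    """Mobile fraction (fi - fd) / (1 - fd), clipped to [0, 1.05].

    The standard convention: the fraction of the bleached population that is
    replaced by unbleached molecules at the recovery plateau.
    """
    if params.fd >= 1:
        raise ValueError(f"mobile fraction undefined for fd >= 1, got fd={params.fd}")
    return float(np.clip((params.fi - params.fd) / (1.0 - params.fd), 0.0, 1.05))
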