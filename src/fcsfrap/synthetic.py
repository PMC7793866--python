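"""Synthetic data with known ground truth for every input the pipeline consumes.

Four generators:

* analytic autocorrelation curves with optional multiplicative noise, for
  round-trip tests of the fitting routines;
* a Brownian-dynamics photon-trace simulator: point emitters diffusing in a
  periodic box (a freely diffusing 3D cytosolic pool plus a 2D pool confined
  to a flat membrane plane) observed through a 3D Gaussian detection volume,
  with Poisson photon statistics and a uniform background — a physics
  stand-in for a confocal FCS acquisition;
* image-derived FRAP intensity vectors (bleached ROI, whole cell,
  background) with exponential acquisition photobleaching and additive
  Gaussian read noise;
* two-channel synthetic cell images (membrane ring, cytosol disc, endosomal
  puncta with a controllable colocalized fraction) plus the ROI masks the
  quantification operations expect.

Every generator is deterministic given its ``rng_seed`` and returns a truth
record carrying the generating parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correlator import CorrelationCurve, IntensityTrace
from .imaging import ROISet
from .models import (
    ACFParams1C,
    ACFParams2C,
    BeamGeometry,
    FRAPParams,
    acf_one_component,
    acf_two_component,
    frap_model,
)

__all__ = [
    "FCSSimConfig",
    "FRAPSimConfig",
    "ImageSimConfig",
    "generate_analytic_acf",
    "simulate_fcs_trace",
    "generate_frap_timeseries",
    "generate_colocalization_images",
]


def generate_analytic_acf(
    params: ACFParams1C | ACFParams2C,
    geom: BeamGeometry,
    lag_grid: np.ndarray,
    noise_model: str = "none",
    noise_scale: float = 0.0,
    rng_seed: int = 0,
) -> tuple[CorrelationCurve, dict]:
    """Evaluate an ACF model on a lag grid, optionally with multiplicative noise.

    Under ``noise_model="multiplicative_gaussian"`` each point is scaled by
    (1 + eps) with eps ~ N(0, noise_scale^2) i.i.d., mimicking the roughly
    constant relative noise of measured correlation curves.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    if lag_grid.size == 0:
        raise ValueError("lag grid must not be empty")
    if isinstance(params, ACFParams1C):
        g = acf_one_component(lag_grid, params, geom)
        truth = {"model": "one_component_3d", "n_particles": params.n_particles,
                 "tau_d_s": params.tau_d}
    elif isinstance(params, ACFParams2C):
        g = acf_two_component(lag_grid, params, geom)
        truth = {"model": "two_component_3d2d", "n_particles": params.n_particles,
                 "f1": params.f1, "tau_d1_s": params.tau_d1, "tau_d2_s": params.tau_d2}
    else:
        raise TypeError(f"unsupported params type {type(params).__name__}")
    if noise_model == "multiplicative_gaussian":
        rng = np.random.default_rng(rng_seed)
        g = g * (1.0 + noise_scale * rng.standard_normal(g.shape))
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    truth.update({"geom_wxy_um": geom.wxy, "geom_s": geom.s,
                  "noise_model": noise_model, "noise_scale": noise_scale,
                  "rng_seed": rng_seed})
    return CorrelationCurve(lags=lag_grid, g=np.asarray(g)), truth


@dataclass(frozen=True)
class FCSSimConfig:
    """Brownian-dynamics FCS simulation settings.

    Defaults emulate a confocal measurement at a cell's plasma membrane:
    a fast cytosolic pool (~39 um^2/s, typical of a small soluble GFP
    fusion), a slow membrane pool (~1.3 um^2/s) confined to a plane through
    the focus, a calibrated 145 nm beam waist with structure parameter 5,
    10 us binning and a 60 s acquisition.
    """

    box_size: float = 3.0                 # um, cubic periodic box
    n_cytosolic: int = 30
    d_cytosolic: float = 38.7             # um^2/s
    n_membrane: int = 15
    d_membrane: float = 1.3               # um^2/s
    membrane_z: float = 0.0               # um, plane offset from the focus
    geom: BeamGeometry = field(default_factory=lambda: BeamGeometry(wxy=0.145, s=5.0))
    brightness: float = 1.0e5             # photons/s per particle at focus center
    background_rate: float = 200.0        # photons/s
    bin_width: float = 1.0e-5             # s
    duration: float = 60.0                # s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size < 10 * self.geom.wxy:
            raise ValueError("box_size must be at least 10 beam waists")
        if min(self.n_cytosolic, self.n_membrane) < 0:
            raise ValueError("particle counts must be non-negative")
        if min(self.brightness, self.background_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.bin_width <= 0 or self.duration <= 0:
            raise ValueError("bin_width and duration must be positive")
        if self.duration / self.bin_width < 1e4:
            raise ValueError("need at least 1e4 bins for usable statistics")
        step = np.sqrt(2 * max(self.d_cytosolic, self.d_membrane) * self.bin_width)
        if step > 0.3 * self.geom.wxy:
            warnings.warn(
                f"per-step RMS displacement {step:.3g} um is not small versus the "
                f"beam waist {self.geom.wxy:.3g} um; decrease bin_width",
                stacklevel=2,
            )


def _wrap(x: np.ndarray, half: float) -> np.ndarray:
    return (x + half) % (2 * half) - half


def simulate_fcs_trace(config: FCSSimConfig) -> tuple[IntensityTrace, dict]:
    """Simulate a binned photon-count trace from diffusing point emitters.

    Each bin, cytosolic particles take an isotropic Gaussian step with per-axis
    standard deviation sqrt(2 D dt) (periodic wrap in the box) while membrane
    particles step only in-plane at ``membrane_z``. The expected photon count
    is the sum of per-particle detection efficiencies through the Gaussian
    volume, exp(-2 rho^2 / wxy^2 - 2 z^2 / (s wxy)^2), scaled by brightness
    and bin width, plus the uniform background; counts are drawn Poisson.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_bins = int(round(config.duration / config.bin_width))
    L = config.box_size
    half = L / 2.0
    dt = config.bin_width
    w = config.geom.wxy
    wz = config.geom.s * w
    a_xy = 2.0 / w**2
    a_z = 2.0 / wz**2
    photons_per_bin = config.brightness * dt

    pos_c = rng.uniform(-half, half, size=(config.n_cytosolic, 3))
    pos_m = rng.uniform(-half, half, size=(config.n_membrane, 2))
    sig_c = np.sqrt(2.0 * config.d_cytosolic * dt)
    sig_m = np.sqrt(2.0 * config.d_membrane * dt)
    z_m2 = config.membrane_z**2

    counts = np.empty(n_bins, dtype=np.int64)
    chunk = max(1, int(2e7 // (3 * max(config.n_cytosolic + config.n_membrane, 1))))
    start = 0
    while start < n_bins:
        stop = min(start + chunk, n_bins)
        nsteps = stop - start
        expected = np.full(nsteps, config.background_rate * dt)
        if config.n_cytosolic:
            steps = rng.normal(0.0, sig_c, size=(nsteps, config.n_cytosolic, 3))
            traj = _wrap(pos_c[None] + np.cumsum(steps, axis=0), half)
            r2 = traj[..., 0] ** 2 + traj[..., 1] ** 2
            expected += photons_per_bin * np.exp(
                -a_xy * r2 - a_z * traj[..., 2] ** 2
            ).sum(axis=1)
            pos_c = traj[-1]
        if config.n_membrane:
            steps = rng.normal(0.0, sig_m, size=(nsteps, config.n_membrane, 2))
            traj = _wrap(pos_m[None] + np.cumsum(steps, axis=0), half)
            r2 = traj[..., 0] ** 2 + traj[..., 1] ** 2
            expected += photons_per_bin * np.exp(-a_xy * r2 - a_z * z_m2).sum(axis=1)
            pos_m = traj[-1]
        counts[start:stop] = rng.poisson(expected)
        start = stop

    # analytic mean detection efficiency over the box, for diagnostics
    psf_int_xy = w * np.sqrt(np.pi / 2.0)
    mean_psf_c = psf_int_xy**2 * (wz * np.sqrt(np.pi / 2.0)) / L**3
    mean_psf_m = psf_int_xy**2 * np.exp(-a_z * z_m2) / L**2
    truth = {
        "d_cytosolic_um2_per_s": config.d_cytosolic,
        "d_membrane_um2_per_s": config.d_membrane,
        "n_cytosolic": config.n_cytosolic,
        "n_membrane": config.n_membrane,
        "membrane_z_um": config.membrane_z,
        "geom_wxy_um": w,
        "geom_s": config.geom.s,
        "expected_mean_rate_per_s": config.background_rate
        + config.brightness * (config.n_cytosolic * mean_psf_c
                               + config.n_membrane * mean_psf_m),
        "rng_seed": config.rng_seed,
    }
    return IntensityTrace(bin_width=dt, counts=counts), truth


@dataclass(frozen=True)
class FRAPSimConfig:
    """FRAP time-series simulation settings.

    Defaults emulate the recovery of a fast membrane-exchanging protein:
    ~90% mobile fraction, 2 s half-recovery, 1 s frames over one minute,
    with mild exponential acquisition photobleaching of the whole-cell
    signal.
    """

    frap_params: FRAPParams = field(
        default_factory=lambda: FRAPParams(fd=0.1, fi=0.91, m=2.0, alpha=1.0)
    )
    frame_interval: float = 1.0           # s
    n_frames: int = 60
    acquisition_bleach_rate: float = 0.005  # 1/s
    cell_intensity0: float = 1000.0       # a.u. above background at t=0
    background_level: float = 10.0        # a.u.
    noise_sd: float = 0.0                 # a.u., additive Gaussian per reading
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.n_frames < 8:
            raise ValueError("need positive frame_interval and at least 8 frames")
        if self.cell_intensity0 <= 0 or self.background_level < 0:
            raise ValueError("intensities must be positive")
        if self.noise_sd < 0 or self.acquisition_bleach_rate < 0:
            raise ValueError("noise_sd and bleach rate must be non-negative")


def generate_frap_timeseries(
    config: FRAPSimConfig,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], dict]:
    """Raw FRAP intensity vectors (times, bleached ROI, whole cell, background).

    The whole-cell signal decays exponentially with the acquisition bleach
    rate; the bleached-ROI signal is the cell signal scaled by the recovery
    model, so the bleach-correction ratio recovers the model curve exactly
    in the noiseless case. The first frame is one frame interval after the
    end of the bleach.
    """
    rng = np.random.default_rng(config.rng_seed)
    times = config.frame_interval * np.arange(1, config.n_frames + 1)
    decay = config.cell_intensity0 * np.exp(-config.acquisition_bleach_rate * times)
    f = frap_model(times, config.frap_params)

    def noisy(x):
        if config.noise_sd == 0:
            return x.astype(float)
        return x + rng.normal(0.0, config.noise_sd, size=x.shape)

    i_cell = noisy(config.background_level + decay)
    i_bleach = noisy(config.background_level + decay * f)
    i_background = noisy(np.full_like(times, config.background_level))
    truth = {
        "fd": config.frap_params.fd,
        "fi": config.frap_params.fi,
        "m_s": config.frap_params.m,
        "alpha": config.frap_params.alpha,
        "acquisition_bleach_rate_per_s": config.acquisition_bleach_rate,
        "noise_sd": config.noise_sd,
        "rng_seed": config.rng_seed,
    }
    return (times, i_bleach, i_cell, i_background), truth


@dataclass(frozen=True)
class ImageSimConfig:
    """Two-channel synthetic cell image settings.

    A circular cell (cytosol disc plus a brighter membrane ring) with
    punctate endosomes; channel 2 carries endosomal puncta of which a
    configurable fraction is co-placed with channel 1's. Pixel size defaults
    to 40 nm, typical of a zoomed confocal acquisition.
    """

    image_size: int = 256                 # pixels (square)
    pixel_size: float = 0.04              # um
    cell_radius: float = 3.5              # um
    membrane_ring_width: int = 4          # pixels
    membrane_intensity: float = 200.0
    cytosol_intensity: float = 80.0
    background_intensity: float = 5.0
    n_endosomes: int = 12
    endosome_intensity: float = 150.0
    endosome_sigma_px: float = 2.0
    channel2_coloc_fraction: float = 1.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        r_px = self.cell_radius / self.pixel_size
        if r_px + 2 >= self.image_size / 2:
            raise ValueError("cell does not fit in the image with a background margin")
        if not 0 <= self.channel2_coloc_fraction <= 1:
            raise ValueError("channel2_coloc_fraction must lie in [0, 1]")
        if min(self.membrane_intensity, self.cytosol_intensity,
               self.background_intensity, self.endosome_intensity) < 0:
            raise ValueError("intensities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _add_puncta(img: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> None:
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    for cy, cx in centers:
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def generate_colocalization_images(
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, ROISet, dict]:
    """Synthetic two-channel cell images plus quantification ROI masks.

    Returns ``(channel1, channel2, rois, truth)`` where the ROI set marks
    four membrane arcs, the whole-cell disc and a background frame outside
    the cell.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    r_cell = config.cell_radius / config.pixel_size
    ring = (r <= r_cell) & (r > r_cell - config.membrane_ring_width)
    cytosol = r <= r_cell - config.membrane_ring_width
    cell = ring | cytosol
    background = r > r_cell + max(4, config.membrane_ring_width)

    ch1 = np.full((n, n), config.background_intensity, dtype=float)
    ch1[cytosol] = config.background_intensity + config.cytosol_intensity
    ch1[ring] = config.background_intensity + config.membrane_intensity
    ch2 = np.full((n, n), config.background_intensity, dtype=float)

    if config.n_endosomes:
        # endosome centers uniformly inside the inner two thirds of the cytosol
        rho = (r_cell - config.membrane_ring_width - 3) * np.sqrt(
            rng.uniform(0, 1, config.n_endosomes)
        )
        theta = rng.uniform(0, 2 * np.pi, config.n_endosomes)
        centers1 = np.column_stack([c + rho * np.sin(theta), c + rho * np.cos(theta)])
        _add_puncta(ch1, centers1, config.endosome_intensity, config.endosome_sigma_px)

        n_coloc = int(round(config.channel2_coloc_fraction * config.n_endosomes))
        centers2 = [centers1[:n_coloc]]
        n_free = config.n_endosomes - n_coloc
        if n_free:
            rho = (r_cell - config.membrane_ring_width - 3) * np.sqrt(
                rng.uniform(0, 1, n_free)
            )
            theta = rng.uniform(0, 2 * np.pi, n_free)
            centers2.append(
                np.column_stack([c + rho * np.sin(theta), c + rho * np.cos(theta)])
            )
        _add_puncta(ch2, np.vstack(centers2), config.endosome_intensity,
                    config.endosome_sigma_px)

    if config.noise_sd:
        ch1 += rng.normal(0.0, config.noise_sd, ch1.shape)
        ch2 += rng.normal(0.0, config.noise_sd, ch2.shape)

    # four membrane arcs as separate ROIs, mirroring manual ROI placement
    angle = np.arctan2(yy - c, xx - c)
    arcs = []
    for k in range(4):
        lo = -np.pi + k * np.pi / 2
        arcs.append(ring & (angle >= lo) & (angle < lo + np.pi / 2))
    rois = ROISet(membrane_rois=arcs, total_roi=cell, background_roi=background)

    truth = {
        "channel2_coloc_fraction": config.channel2_coloc_fraction,
        "membrane_intensity": config.membrane_intensity,
        "cytosol_intensity": config.cytosol_intensity,
        "background_intensity": config.background_intensity,
        "n_endosomes": config.n_endosomes,
        "rng_seed": config.rng_seed,
    }
    return ch1, ch2, rois, truth
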