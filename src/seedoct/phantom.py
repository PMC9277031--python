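"""Synthetic germinating-seed observations with known ground truth.

Forward models for the three observation channels of an SD-OCT germination
monitor:

* **OCT B-scans** of a layered seed (testa surface, coat/cotyledon interface,
  cotyledon layers, a subsurface radicle) with multiplicative exponential
  speckle, depth attenuation and time-dependent morphological events,
* **camera photographs** of the growing seed disc above a water-surface
  shadow band, with surface wrinkles after the wrinkle event,
* **gravimetric weight series** following the classic triphasic germination
  curve (imbibition → lag plateau → renewed uptake), sampled on the standard
  weighing schedule (every 30 min for the first 10 h, then every 5 h).

The default coat-thickness time course is a monotone piecewise-cubic (PCHIP)
interpolation through the reference 3-hourly thickness table (112 μm at 3 h
rising to 197 μm at 36 h); lateral coat unevenness follows a zero-mean random
low-frequency profile whose amplitude tracks the per-time-point spread of the
same table (largest around 9–15 h).  Everything rendered is recorded in a
:class:`GroundTruth` object so estimators can be scored against the exact
simulated state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .reconstruction import AScan, BScan, SourceSpec, axial_resolution, max_imaging_depth

__all__ = [
    "TABLE_TIMES_H",
    "TABLE_MEAN_UM",
    "TABLE_SD_UM",
    "EventTimes",
    "CameraConfig",
    "WeightConfig",
    "PhantomConfig",
    "GroundTruth",
    "WeightSeries",
    "SimulatedTimecourse",
    "weight_schedule",
    "simulate_weight",
    "render_bscan",
    "render_camera_image",
    "synthesize_spectral_frame",
    "make_ascan",
    "simulate_timecourse",
    "simulate_cohort",
]

# Reference seed-coat thickness time course (3-hourly mean and spread, μm).
TABLE_TIMES_H = np.array([3, 6, 9, 12, 15, 18, 21, 24, 27, 30, 33, 36], dtype=float)
TABLE_MEAN_UM = np.array([112, 133, 155, 170, 175, 178, 185, 186, 190, 190, 196, 197], dtype=float)
TABLE_SD_UM = np.array([4.6, 5.4, 13.1, 15.3, 12.6, 4.2, 5.8, 4.1, 2.9, 4.3, 4.0, 4.8], dtype=float)


def _default_thickness_nodes() -> tuple[tuple[float, ...], tuple[float, ...]]:
    # dry-coat anchor at t=0 continues the 3-6 h slope backwards: the coat
    # imbibes from the moment of soaking, co-varying with weight gain
    times = (0.0, *map(float, TABLE_TIMES_H), 40.0)
    values = (100.0, *map(float, TABLE_MEAN_UM), float(TABLE_MEAN_UM[-1]))
    return times, values


def _default_roughness_nodes() -> tuple[tuple[float, ...], tuple[float, ...]]:
    times = (0.0, *map(float, TABLE_TIMES_H), 40.0)
    values = (float(TABLE_SD_UM[0]), *map(float, TABLE_SD_UM), float(TABLE_SD_UM[-1]))
    return times, values


@dataclass
class EventTimes:
    """Onset hours of the four morphological indicators (None = disabled)."""

    wrinkle_h: float | None = 5.0
    cotyledon_h: float | None = 6.0
    radicle_h: float | None = 13.0 + 40.0 / 60.0
    crack_h: float | None = 31.0

    def validate(self) -> None:
        seq = [t for t in (self.wrinkle_h, self.cotyledon_h, self.radicle_h, self.crack_h)
               if t is not None]
        if any(t < 0 for t in seq):
            raise ValueError("event times must be nonnegative")
        if self.radicle_h is not None and self.crack_h is not None:
            if self.crack_h < self.radicle_h:
                raise ValueError("crack event cannot precede radicle event")

    def as_dict(self) -> dict[str, float | None]:
        return dataclasses.asdict(self)


@dataclass
class CameraConfig:
    """Web-camera geometry and seed-disc appearance."""

    width_px: int = 644
    height_px: int = 482
    pixel_scale_mm: float = 11.0 / 644.0   # mm per pixel, square pixels assumed
    water_line_frac: float = 0.7           # fraction of image height
    center_frac: tuple[float, float] = (0.5, 0.34)  # (x, y) of disc centre
    seed_rgb: tuple[int, int, int] = (190, 170, 140)
    background_rgb: tuple[int, int, int] = (20, 18, 16)
    diameter0_mm: float = 4.2
    diameter_gain_mm: float = 1.2
    diameter_tau_h: float = 8.0
    wrinkle_amp_mm: float = 0.05
    wrinkle_growth_mm_per_h: float = 0.004
    wrinkle_modes: int = 12
    pixel_noise: float = 2.0

    def diameter_mm(self, t_h: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_h, dtype=float)
        d = self.diameter0_mm + self.diameter_gain_mm * (1.0 - np.exp(-t / self.diameter_tau_h))
        return d if d.ndim else float(d)


@dataclass
class WeightConfig:
    """Triphasic water-uptake model parameters (grams, hours)."""

    dry_weight_g: float = 0.35
    uptake_frac: float = 0.45       # phase-I relative gain
    tau1_h: float = 10.0            # imbibition time constant, matching the
                                    # observed coat-thickening timescale
    plateau_slope_g_per_h: float = 0.001
    phase3_gain_g: float = 0.05
    tau3_h: float = 5.0
    noise_frac: float = 0.005       # multiplicative measurement noise (sd)


@dataclass
class PhantomConfig:
    """Complete description of a simulated germinating seed.

    The rendered B-scan carries a bright testa surface line (smooth convex
    arc), the coat/cotyledon interface at optical distance ``thickness × RI``
    below it, cotyledon layers at the flanks after the cotyledon event, a
    central subsurface radicle after the radicle event, and a surface gap plus
    depth discontinuity after the crack event.
    """

    seed_rng: int = 0
    lateral_extent_mm: float = 6.0
    depth_extent_mm: float = 2.2
    n_lateral: int = 1000
    n_depth: int = 1024
    # surface: smooth convex arc z(x) = apex + curvature (x - centre)^2
    # gentle arc: adjacent boundary picks (60 across the span) stay well below
    # the crack detector's 5-axial-pixel jump criterion on smooth surfaces
    apex_depth_um: float = 350.0
    surface_curvature_um_per_mm2: float = 10.0
    # coat thickness and lateral unevenness time courses (nodes, PCHIP between)
    thickness_times_h: tuple[float, ...] = field(default_factory=lambda: _default_thickness_nodes()[0])
    thickness_values_um: tuple[float, ...] = field(default_factory=lambda: _default_thickness_nodes()[1])
    roughness_times_h: tuple[float, ...] = field(default_factory=lambda: _default_roughness_nodes()[0])
    roughness_values_um: tuple[float, ...] = field(default_factory=lambda: _default_roughness_nodes()[1])
    roughness_n_modes: int = 4
    coat_ri: float = 1.42
    # backscatter amplitudes (linear, relative); radicle capped below surface
    reflectivity_testa: float = 1.0
    reflectivity_endocarp: float = 0.6
    reflectivity_cotyledon: float = 0.4
    reflectivity_radicle: float = 0.75
    attenuation_per_mm: float = 0.5
    speckle_contrast: float = 0.5    # sd/mean of multiplicative intensity noise
    span_fraction: float = 0.9       # lateral fraction occupied by the seed
    cotyledon_offset_um: float = 250.0  # optical depth below the interface
    radicle_offset_um: float = 350.0
    radicle_halfwidth_mm: float = 0.6
    crack_width_um: float = 200.0
    crack_depth_um: float = 40.0
    events: EventTimes = field(default_factory=EventTimes)
    cadence_min: float = 10.0
    duration_h: float = 40.0
    source: SourceSpec = field(default_factory=SourceSpec)
    camera: CameraConfig = field(default_factory=CameraConfig)
    weight: WeightConfig = field(default_factory=WeightConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.coat_ri <= 0:
            raise ValueError("coat_ri must be positive")
        for name in ("reflectivity_testa", "reflectivity_endocarp",
                     "reflectivity_cotyledon", "reflectivity_radicle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must be in [0, 1]")
        tt = np.asarray(self.thickness_times_h, dtype=float)
        tv = np.asarray(self.thickness_values_um, dtype=float)
        if tt.shape != tv.shape or tt.size < 2:
            raise ValueError("thickness curve needs matching time/value nodes")
        if np.any(np.diff(tt) <= 0):
            raise ValueError("thickness curve times must be strictly increasing")
        bad = np.nonzero(np.diff(tv) < 0)[0]
        if bad.size:
            raise ValueError(
                f"coat thickness curve decreases at t = {tt[bad[0] + 1]:g} h; "
                "the thickness time course must be nondecreasing"
            )
        self.events.validate()
        if self.cadence_min <= 0 or self.duration_h < 0:
            raise ValueError("cadence must be positive and duration nonnegative")

    # -- derived time courses -------------------------------------------------
    def thickness_curve(self) -> Callable[[np.ndarray], np.ndarray]:
        return PchipInterpolator(np.asarray(self.thickness_times_h),
                                 np.asarray(self.thickness_values_um), extrapolate=True)

    def roughness_curve(self) -> Callable[[np.ndarray], np.ndarray]:
        return PchipInterpolator(np.asarray(self.roughness_times_h),
                                 np.asarray(self.roughness_values_um), extrapolate=True)

    @property
    def axial_pixel_um(self) -> float:
        return self.depth_extent_mm * 1000.0 / self.n_depth

    @property
    def lateral_pixel_mm(self) -> float:
        return self.lateral_extent_mm / self.n_lateral

    def span_mm(self) -> tuple[float, float]:
        half = self.span_fraction * self.lateral_extent_mm / 2.0
        c = self.lateral_extent_mm / 2.0
        return c - half, c + half

    def times_h(self) -> np.ndarray:
        n = int(math.floor(self.duration_h * 60.0 / self.cadence_min))
        return np.arange(n) * self.cadence_min / 60.0

    def surface_um(self, x_mm: np.ndarray) -> np.ndarray:
        c = self.lateral_extent_mm / 2.0
        return self.apex_depth_um + self.surface_curvature_um_per_mm2 * (np.asarray(x_mm) - c) ** 2


def _roughness_profile(config: PhantomConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Zero-mean, unit-sd lateral unevenness profile g(x) over the seed span.

    Low-frequency random Fourier modes drawn deterministically from the
    phantom seed; normalised to zero mean and unit standard deviation across
    the seed span so the roughness curve directly sets the per-time spread.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed_rng, 3]))
    m = config.roughness_n_modes
    a = rng.normal(size=m)
    b = rng.normal(size=m)
    lo, hi = config.span_mm()
    span = hi - lo

    def raw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        phase = 2.0 * math.pi * (x[..., None] - lo) / span * np.arange(1, m + 1)
        return (a * np.cos(phase) + b * np.sin(phase)).sum(axis=-1)

    xs = np.linspace(lo, hi, 512)
    vals = raw(xs)
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    return lambda x: (raw(x) - mu) / sd


@dataclass
class WeightSeries:
    """Weights (g) of one seed on the gravimetric sampling schedule."""

    seed_id: str
    times_h: np.ndarray
    weights_g: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.weights_g = np.asarray(self.weights_g, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.weights_g <= 0):
            raise ValueError("weights must be positive")


def weight_schedule(duration_h: float = 40.0) -> np.ndarray:
    """Weighing times: every 30 min for the first 10 h, every 5 h afterwards."""
    dense = np.arange(0.0, min(10.0, duration_h) + 1e-9, 0.5)
    sparse = np.arange(15.0, duration_h + 1e-9, 5.0)
    return np.concatenate([dense, sparse[sparse > dense[-1]]])


def _true_weight(config: PhantomConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free triphasic weight curve, continuous and nondecreasing."""
    w = config.weight
    ev = config.events
    t = np.asarray(t, dtype=float)
    t_r = ev.radicle_h if ev.radicle_h is not None else np.inf
    t_c = ev.crack_h if ev.crack_h is not None else np.inf

    def phase1(tt):
        return w.dry_weight_g * (1.0 + w.uptake_frac * (1.0 - np.exp(-tt / w.tau1_h)))

    out = phase1(np.minimum(t, t_r))
    if np.isfinite(t_r):
        lag = np.clip(np.minimum(t, t_c) - t_r, 0.0, None)
        out = out + w.plateau_slope_g_per_h * lag
    if np.isfinite(t_c):
        grow = np.clip(t - t_c, 0.0, None)
        out = out + w.phase3_gain_g * (1.0 - np.exp(-grow / w.tau3_h))
    return out


def simulate_weight(
    config: PhantomConfig,
    seed_id: str = "seed1",
    rng: np.random.Generator | int | None = None,
) -> WeightSeries:
    """Sample the triphasic weight model on the standard weighing schedule."""
    rng = np.random.default_rng(rng)
    t = weight_schedule(config.duration_h)
    true = _true_weight(config, t)
    noise = rng.normal(scale=config.weight.noise_frac, size=t.size) if config.weight.noise_frac else 0.0
    return WeightSeries(seed_id, t, true * np.exp(noise))


# ---------------------------------------------------------------------------
# OCT forward model


def _layers_at(config: PhantomConfig, t_h: float, x_mm: np.ndarray,
               g: Callable[[np.ndarray], np.ndarray]) -> list[tuple[np.ndarray, np.ndarray]]:
    """(optical depth μm, amplitude) per layer at each lateral position.

    Amplitudes are zero outside the seed span or before the layer's event.
    """
    ev = config.events
    lo, hi = config.span_mm()
    in_span = (x_mm >= lo) & (x_mm <= hi)
    surface = config.surface_um(x_mm)
    thick_phys = config.thickness_curve()(t_h) + config.roughness_curve()(t_h) * g(x_mm)
    thick_opt = np.clip(thick_phys, 1.0, None) * config.coat_ri
    interface = surface + thick_opt

    c = config.lateral_extent_mm / 2.0
    cracked = ev.crack_h is not None and t_h >= ev.crack_h
    crack_mask = np.zeros_like(x_mm, dtype=bool)
    if cracked:
        crack_mask = np.abs(x_mm - c) <= config.crack_width_um / 2000.0
        surface = surface + np.where(crack_mask, config.crack_depth_um, 0.0)
        interface = interface + np.where(crack_mask, config.crack_depth_um, 0.0)

    att = np.exp(-2.0 * config.attenuation_per_mm * thick_opt * 1e-3)
    amp_surf = np.where(in_span, config.reflectivity_testa, 0.0)
    amp_surf = np.where(crack_mask, amp_surf * 0.5, amp_surf)
    amp_if = np.where(in_span, config.reflectivity_endocarp * att, 0.0)
    amp_if = np.where(crack_mask, amp_if * 0.5, amp_if)

    layers = [(surface, amp_surf), (interface, amp_if)]

    if ev.cotyledon_h is not None and t_h >= ev.cotyledon_h:
        # cotyledon layers visible on both flanks, absent in the central band
        flank = in_span & (np.abs(x_mm - c) > config.radicle_halfwidth_mm)
        depth = interface + config.cotyledon_offset_um
        amp = np.where(flank, config.reflectivity_cotyledon * att, 0.0)
        layers.append((depth, amp))

    if ev.radicle_h is not None and t_h >= ev.radicle_h:
        # subsurface radicle blob in the centre, rounded depth profile,
        # amplitude capped below the surface peak
        u = (x_mm - c) / config.radicle_halfwidth_mm
        central = in_span & (np.abs(u) <= 1.0)
        depth = interface + config.radicle_offset_um + 80.0 * u**2
        cap = 0.9 * config.reflectivity_testa
        amp = np.where(central, min(config.reflectivity_radicle, cap) * att, 0.0)
        layers.append((depth, amp))

    return layers


def render_bscan(
    config: PhantomConfig,
    t_h: float,
    rng: np.random.Generator | int | None = None,
    *,
    speckle: bool | None = None,
) -> BScan:
    """Render one log-magnitude B-scan of the phantom at time ``t_h``.

    Layer lines are Gaussian in depth with sigma set by the source's axial
    resolution; multiplicative exponential-intensity speckle of the configured
    contrast is applied to the signal before log compression, and the log
    floor sits 80 dB below the frame maximum.  Identical ``rng`` state gives
    bit-identical images.
    """
    if not (0.0 <= t_h <= config.duration_h):
        raise ValueError(f"time {t_h} h outside the simulated window [0, {config.duration_h}] h")
    rng = np.random.default_rng(rng)
    if speckle is None:
        speckle = config.speckle_contrast > 0

    x = (np.arange(config.n_lateral) + 0.5) * config.lateral_pixel_mm
    g = _roughness_profile(config)
    layers = _layers_at(config, t_h, x, g)

    ax_px = config.axial_pixel_um
    sigma_px = axial_resolution(config.source, 1.0) / 2.355 / ax_px
    halfwidth = max(4, int(math.ceil(6.0 * sigma_px)))
    offs = np.arange(-halfwidth, halfwidth + 1)

    intensity = np.zeros((config.n_depth, config.n_lateral), dtype=np.float64)
    cols = np.arange(config.n_lateral)
    contrast = config.speckle_contrast if speckle else 0.0
    for depth_um, amp in layers:
        center_px = depth_um / ax_px
        base = np.round(center_px).astype(int)
        rows = base[None, :] + offs[:, None]            # (2h+1, n_lateral)
        profile = np.exp(-((rows - center_px[None, :]) ** 2) / (2.0 * sigma_px**2))
        vals = amp[None, :] * profile
        if contrast > 0:
            factor = 1.0 - contrast + contrast * rng.exponential(size=vals.shape)
            vals = vals * factor
        valid = (rows >= 0) & (rows < config.n_depth)
        np.add.at(intensity, (rows.clip(0, config.n_depth - 1), np.broadcast_to(cols, rows.shape)),
                  np.where(valid, vals, 0.0))

    peak = intensity.max()
    if peak <= 0:
        img = np.full(intensity.shape, -80.0)
    else:
        floor = peak * 10.0 ** (-80.0 / 20.0)
        img = 20.0 * np.log10(np.maximum(intensity, floor))
    return BScan(img, lateral_extent_mm=config.lateral_extent_mm,
                 depth_extent_mm=config.depth_extent_mm, timestamp_h=t_h)


def synthesize_spectral_frame(
    config: PhantomConfig | None,
    column_reflectors: Sequence[tuple[float, float]],
    source: SourceSpec | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    noise_scale: float = 0.0,
    reference_reflectivity: float = 1.0,
):
    """Synthesize one spectral interferogram for a set of point reflectors.

    ``frame = G(λ) · (1 + Σ_i 2 √(R_ref R_i) cos(2 k z_i))`` sampled on the
    spectrometer wavelength grid, with optional additive detector noise.
    Reflector depths are optical depths in μm.
    """
    from .reconstruction import SpectralFrame  # local to avoid cycle at import

    if source is None:
        source = config.source if config is not None else SourceSpec()
    z_max_um = max_imaging_depth(source) * 1000.0
    for z, _ in column_reflectors:
        if z >= z_max_um:
            raise ValueError(
                f"reflector at {z:.1f} um exceeds the maximum imaging depth "
                f"{z_max_um:.1f} um and would alias"
            )
    rng = np.random.default_rng(rng)
    lam = source.wavelength_grid_nm()
    k = 2.0 * math.pi / lam                      # rad / nm
    lam0 = source.center_wavelength_nm
    sigma_lam = source.bandwidth_fwhm_nm / 2.355
    envelope = np.exp(-((lam - lam0) ** 2) / (2.0 * sigma_lam**2))
    fringes = np.zeros_like(lam)
    for z_um, refl in column_reflectors:
        z_nm = z_um * 1000.0
        fringes += 2.0 * math.sqrt(reference_reflectivity * refl) * np.cos(2.0 * k * z_nm)
    intensities = envelope * (1.0 + fringes)
    if noise_scale > 0:
        intensities = intensities + rng.normal(scale=noise_scale, size=lam.size)
    return SpectralFrame(lam, intensities)


def make_ascan(
    peaks: Sequence[tuple[float, float]],
    *,
    n_depth: int = 1024,
    depth_extent_mm: float = 2.2,
    sigma_um: float = 2.7,
    floor_db: float = -80.0,
) -> AScan:
    """Construct a log-magnitude depth profile with Gaussian peaks.

    ``peaks`` are (optical depth μm, linear amplitude) pairs — a convenience
    for building worked-example A-scan sequences without the full phantom.
    """
    depths = np.arange(n_depth) * depth_extent_mm * 1000.0 / n_depth
    linear = np.zeros(n_depth)
    for z, amp in peaks:
        linear += amp * np.exp(-((depths - z) ** 2) / (2.0 * sigma_um**2))
    peak = linear.max()
    ref = peak if peak > 0 else 1.0
    floor = ref * 10.0 ** (floor_db / 20.0)
    return AScan(depths, 20.0 * np.log10(np.maximum(linear, floor)))


# ---------------------------------------------------------------------------
# Camera forward model


def render_camera_image(
    config: PhantomConfig,
    t_h: float,
    rng: np.random.Generator | int | None = None,
):
    """Render an RGB photo: bright seed disc, dark background, water band.

    The disc boundary is antialiased; after the wrinkle event the radius is
    modulated sinusoidally around the circumference with the configured
    amplitude (growing slowly after onset).
    """
    from .morphometry import CameraImage  # avoid import cycle

    if not (0.0 <= t_h <= config.duration_h):
        raise ValueError(f"time {t_h} h outside the simulated window")
    rng = np.random.default_rng(rng)
    cam = config.camera
    h, w = cam.height_px, cam.width_px
    cx, cy = cam.center_frac[0] * w, cam.center_frac[1] * h
    r_px = cam.diameter_mm(t_h) / 2.0 / cam.pixel_scale_mm

    ev = config.events
    wrinkled = ev.wrinkle_h is not None and t_h >= ev.wrinkle_h
    amp_px = 0.0
    phi = 0.0
    if wrinkled:
        phase_rng = np.random.default_rng(np.random.SeedSequence([config.seed_rng, 4]))
        phi = phase_rng.uniform(0, 2 * math.pi)
        amp_mm = cam.wrinkle_amp_mm + cam.wrinkle_growth_mm_per_h * (t_h - ev.wrinkle_h)
        amp_px = amp_mm / cam.pixel_scale_mm

    bg = np.array(cam.background_rgb, dtype=float)
    fg = np.array(cam.seed_rgb, dtype=float)
    img = np.broadcast_to(bg, (h, w, 3)).copy()

    # water-surface shadow on the background: dark band at the water line,
    # dimmed region below (the seed, composited later, occludes it)
    wl = int(round(cam.water_line_frac * h))
    band = min(h, wl + int(0.04 * h))
    img[wl:band] *= 0.25
    img[band:] *= 0.55

    # disc rendered only inside its bounding box (antialiased coverage)
    pad = int(math.ceil(r_px + abs(amp_px) + 3))
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    radius = np.full_like(dist, r_px)
    if wrinkled:
        theta = np.arctan2(dy, dx)
        radius = radius + amp_px * np.sin(cam.wrinkle_modes * theta + phi)
    alpha = np.clip(0.5 - (dist - radius), 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + alpha * fg

    if cam.pixel_noise > 0:
        img[y0:y1, x0:x1] += rng.normal(scale=cam.pixel_noise, size=(y1 - y0, x1 - x0, 3))
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return CameraImage(pixels, pixel_scale_mm=cam.pixel_scale_mm, timestamp_h=t_h)


# ---------------------------------------------------------------------------
# Ground truth and the full time course


@dataclass
class GroundTruth:
    """Exact simulated state used during rendering.

    ``thickness_map(t, x)`` reproduces the rendered physical coat thickness
    bit-for-bit; event times, the noise-free weight curves and the diameter
    curve are stored as sampled arrays on the acquisition grid.
    """

    times_h: np.ndarray
    mean_thickness_um: np.ndarray
    event_times: dict[str, float | None]
    diameter_mm: np.ndarray
    true_weights_g: dict[str, np.ndarray]
    weight_times_h: np.ndarray
    _config: PhantomConfig = field(repr=False)

    def thickness_map(self, t_h: float, x_mm: np.ndarray) -> np.ndarray:
        c = self._config
        g = _roughness_profile(c)
        return c.thickness_curve()(t_h) + c.roughness_curve()(t_h) * g(np.asarray(x_mm, dtype=float))

    def to_json(self, path: str | Path, n_lateral_samples: int = 60) -> Path:
        c = self._config
        lo, hi = c.span_mm()
        xs = np.linspace(lo, hi, n_lateral_samples)
        payload = {
            "times_h": self.times_h.tolist(),
            "mean_thickness_um": self.mean_thickness_um.tolist(),
            "event_times_h": self.event_times,
            "diameter_mm": self.diameter_mm.tolist(),
            "weight_times_h": self.weight_times_h.tolist(),
            "true_weights_g": {k: v.tolist() for k, v in self.true_weights_g.items()},
            "lateral_samples_mm": xs.tolist(),
            "thickness_maps_um": [self.thickness_map(t, xs).tolist() for t in self.times_h],
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


class SimulatedTimecourse:
    """Lazily rendered observation series for one monitored seed.

    Frames are rendered on access with per-frame seeds derived from the
    phantom seed, so any frame is reproducible independently of access order;
    ``len(tc)`` equals ``floor(duration / cadence)``.
    """

    def __init__(self, config: PhantomConfig, n_weight_seeds: int = 10):
        config.validate()
        self.config = config
        self.times_h = config.times_h()
        sched = weight_schedule(config.duration_h)
        self.weights: list[WeightSeries] = []
        truths: dict[str, np.ndarray] = {}
        for i in range(n_weight_seeds):
            wcfg = config
            if i > 0:
                jr = np.random.default_rng(np.random.SeedSequence([config.seed_rng, 5, i]))
                wcfg = replace(config, weight=replace(
                    config.weight, dry_weight_g=config.weight.dry_weight_g * (1 + 0.05 * jr.standard_normal())))
            sid = f"seed{i + 1}"
            rng = np.random.default_rng(np.random.SeedSequence([config.seed_rng, 2, i]))
            self.weights.append(simulate_weight(wcfg, sid, rng))
            truths[sid] = _true_weight(wcfg, sched)
        thick = config.thickness_curve()(self.times_h) if self.times_h.size else np.array([])
        diam = np.asarray([config.camera.diameter_mm(t) for t in self.times_h])
        events = config.events.as_dict() if self.times_h.size else {
            k: None for k in config.events.as_dict()}
        self.truth = GroundTruth(
            times_h=self.times_h,
            mean_thickness_um=np.asarray(thick, dtype=float),
            event_times=events,
            diameter_mm=diam,
            true_weights_g=truths,
            weight_times_h=sched,
            _config=config,
        )

    def __len__(self) -> int:
        return len(self.times_h)

    def _frame_rng(self, stream: int, index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.config.seed_rng, stream, index]))

    def bscan(self, index: int) -> BScan:
        t = self.times_h[index]
        return render_bscan(self.config, t, self._frame_rng(0, index))

    def camera(self, index: int):
        t = self.times_h[index]
        return render_camera_image(self.config, t, self._frame_rng(1, index))

    def save(self, outdir: str | Path, indices: Sequence[int] | None = None) -> dict[str, Path]:
        """Write OCT TIFF stack, camera PNGs, weight CSV and ground-truth JSON."""
        from .reconstruction import write_bscan_tiff

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        idx = list(range(len(self))) if indices is None else list(indices)
        paths: dict[str, Path] = {}
        if idx:
            paths["oct"] = write_bscan_tiff([self.bscan(i) for i in idx], outdir / "bscans.tiff")
            for i in idx:
                frame = self.camera(i)
                iio.imwrite(outdir / f"camera_{i:04d}.png", frame.pixels)
            paths["camera_dir"] = outdir
        rows = [
            {"seed_id": ws.seed_id, "time_h": t, "weight_g": w}
            for ws in self.weights
            for t, w in zip(ws.times_h, ws.weights_g)
        ]
        paths["weights"] = outdir / "weights.csv"
        pd.DataFrame(rows, columns=["seed_id", "time_h", "weight_g"]).to_csv(
            paths["weights"], index=False)
        paths["ground_truth"] = self.truth.to_json(outdir / "ground_truth.json")
        return paths


def simulate_timecourse(config: PhantomConfig, n_weight_seeds: int = 10) -> SimulatedTimecourse:
    """Simulate the full acquisition: OCT + camera series and a weight cohort.

    The number of time points is ``floor(duration / cadence)`` (240 for the
    default 10-min cadence over 40 h); a zero duration yields an empty series.
    """
    return SimulatedTimecourse(config, n_weight_seeds=n_weight_seeds)


def simulate_cohort(config: PhantomConfig, n_seeds: int = 10) -> list[SimulatedTimecourse]:
    """Simulate ``n_seeds`` independently jittered seeds (one weight series each).

    Event times are jittered by up to ±45 min (ordering preserved), the coat
    thickness trajectory scaled by a ±2% factor, dry weight by ±5% and the
    initial diameter by ±3%, emulating within-batch variability.
    """
    cohort = []
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed_rng, 6, i]))
        ev = config.events
        shift = lambda t: None if t is None else max(0.0, t + rng.uniform(-0.75, 0.75))
        wr = shift(ev.wrinkle_h)
        co = shift(ev.cotyledon_h)
        if wr is not None and co is not None:
            co = max(co, wr)
        ra = shift(ev.radicle_h)
        if co is not None and ra is not None:
            ra = max(ra, co)
        cr = shift(ev.crack_h)
        if ra is not None and cr is not None:
            cr = max(cr, ra)
        scale = 1.0 + 0.02 * rng.standard_normal()
        member = replace(
            config,
            seed_rng=int(np.random.SeedSequence([config.seed_rng, 7, i]).generate_state(1)[0] % (2**31)),
            events=EventTimes(wr, co, ra, cr),
            thickness_values_um=tuple(v * scale for v in config.thickness_values_um),
            weight=replace(config.weight,
                           dry_weight_g=config.weight.dry_weight_g * (1 + 0.05 * rng.standard_normal())),
            camera=replace(config.camera,
                           diameter0_mm=config.camera.diameter0_mm * (1 + 0.03 * rng.standard_normal())),
        )
        cohort.append(SimulatedTimecourse(member, n_weight_seeds=1))
    return cohort
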