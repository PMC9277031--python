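"""Spectral-domain OCT reconstruction.

In SD-OCT the depth-resolved reflectivity profile (A-scan) is encoded in the
spectrum of the interference signal: a reflector at optical depth ``z``
contributes a fringe ``cos(2 k z)`` across the wavenumber axis ``k = 2π/λ``.
Reconstruction therefore amounts to background removal, resampling the
spectrometer's uniform-wavelength grid onto a uniform-wavenumber grid,
windowing, and an inverse Fourier transform.  A B-scan is a stack of adjacent
A-scans across a lateral scan.

Closed-form system figures of merit for a Gaussian source:

* axial resolution  ``δz = (2 ln 2 / π) · λ0² / Δλ / n``  (FWHM bandwidth Δλ,
  medium refractive index n),
* maximum imaging depth  ``z_max = λ0² / (4 δλ)``  (spectrometer resolution δλ).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SourceSpec",
    "SpectralFrame",
    "AScan",
    "BScan",
    "axial_resolution",
    "max_imaging_depth",
    "reconstruct_ascan",
    "assemble_bscan",
    "average_ascans",
    "write_bscan_tiff",
    "read_bscan_tiff",
]


@dataclass(frozen=True)
class SourceSpec:
    """Optical source and spectrometer parameters.

    Defaults describe a superluminescent diode centred at 840 nm with a 50 nm
    FWHM bandwidth, read out by a spectrometer with 0.09 nm resolution over
    1024 pixels.
    """

    center_wavelength_nm: float = 840.0
    bandwidth_fwhm_nm: float = 50.0
    spectrometer_resolution_nm: float = 0.09
    n_spectral_pixels: int = 1024

    def __post_init__(self) -> None:
        if not (
            self.center_wavelength_nm >= 0
            and self.bandwidth_fwhm_nm > 0
            and self.spectrometer_resolution_nm > 0
            and self.n_spectral_pixels >= 2
        ):
            raise ValueError("source parameters must be positive")
        if self.spectrometer_resolution_nm > self.bandwidth_fwhm_nm:
            raise ValueError("spectrometer resolution cannot exceed source bandwidth")

    def wavelength_grid_nm(self) -> np.ndarray:
        """Uniform wavelength grid centred on λ0 with δλ spacing."""
        n = self.n_spectral_pixels
        offsets = np.arange(n) - (n - 1) / 2.0
        return self.center_wavelength_nm + offsets * self.spectrometer_resolution_nm


def axial_resolution(source: SourceSpec, refractive_index: float = 1.0) -> float:
    """Axial (depth) resolution in μm for a Gaussian source.

    ``(2 ln 2 / π) · λ0² / Δλ / n``.  With the default source and n = 1 this is
    ≈ 6.23 μm.
    """
    if refractive_index < 1:
        raise ValueError("refractive_index must be >= 1")
    lam0 = source.center_wavelength_nm
    dlam = source.bandwidth_fwhm_nm
    res_nm = (2.0 * math.log(2.0) / math.pi) * lam0**2 / dlam / refractive_index
    return res_nm * 1e-3


def max_imaging_depth(source: SourceSpec) -> float:
    """Maximum (Nyquist) imaging depth in mm, ``λ0² / (4 δλ)``."""
    lam0 = source.center_wavelength_nm
    dl = source.spectrometer_resolution_nm
    return lam0**2 / (4.0 * dl) * 1e-6


@dataclass
class SpectralFrame:
    """One spectral interferogram sampled on a uniform wavelength grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        d = np.diff(self.wavelengths_nm)
        if not np.all(d > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wavelength grid must be uniform")


@dataclass
class AScan:
    """Depth profile: log magnitude (dB) on a uniform optical-depth grid (μm)."""

    optical_depths_um: np.ndarray
    log_magnitude_db: np.ndarray
    lateral_index: int = 0

    def __post_init__(self) -> None:
        self.optical_depths_um = np.asarray(self.optical_depths_um, dtype=float)
        self.log_magnitude_db = np.asarray(self.log_magnitude_db, dtype=float)

    @property
    def depth_pixel_um(self) -> float:
        return float(self.optical_depths_um[1] - self.optical_depths_um[0])

    def linear_magnitude(self) -> np.ndarray:
        return 10.0 ** (self.log_magnitude_db / 20.0)


@dataclass
class BScan:
    """Cross-sectional log-magnitude image, depth (rows) × lateral (columns)."""

    image: np.ndarray
    lateral_extent_mm: float = 6.0
    depth_extent_mm: float = 2.2
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("B-scan image must be 2-D")

    @property
    def n_depth(self) -> int:
        return self.image.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.image.shape[1]

    @property
    def axial_pixel_um(self) -> float:
        return self.depth_extent_mm * 1000.0 / self.n_depth

    @property
    def lateral_pixel_mm(self) -> float:
        return self.lateral_extent_mm / self.n_lateral

    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.axial_pixel_um

    def lateral_axis_mm(self) -> np.ndarray:
        return (np.arange(self.n_lateral) + 0.5) * self.lateral_pixel_mm

    def ascan(self, column: int) -> AScan:
        if not 0 <= column < self.n_lateral:
            raise IndexError("column outside image")
        return AScan(self.depth_axis_um(), self.image[:, column], lateral_index=column)


def _depth_axis_um(source: SourceSpec, n_fft: int, n_keep: int) -> np.ndarray:
    lam = source.wavelength_grid_nm()
    k = 2.0 * math.pi / lam
    dk = (k.max() - k.min()) / (len(k) - 1)  # rad / nm
    z_unit_nm = math.pi / (n_fft * dk)
    return np.arange(n_keep) * z_unit_nm * 1e-3


def reconstruct_ascan(
    frame: SpectralFrame,
    source: SourceSpec,
    *,
    window: str = "hann",
    log_floor_db: float = -80.0,
    lateral_index: int = 0,
) -> AScan:
    """Reconstruct a depth profile from one spectral interferogram.

    Pipeline: subtract the slowly-varying source background → resample from the
    uniform-wavelength grid onto a uniform-wavenumber grid (cubic spline) →
    apply a Hann window → zero-pad to twice the length → inverse FFT → keep the
    one-sided magnitude (``n_spectral_pixels`` bins) → 20·log10 with a floor
    ``log_floor_db`` below the frame maximum.
    """
    if len(frame.wavelengths_nm) != source.n_spectral_pixels:
        raise ValueError("frame grid does not match source pixel count")
    if not np.all(np.isfinite(frame.intensities)):
        raise ValueError("frame intensities contain NaN/inf")

    n = source.n_spectral_pixels
    spec = frame.intensities
    background = uniform_filter1d(spec, size=max(8, n // 16), mode="nearest")
    ac = spec - background

    # wavelength → wavenumber; k decreases with λ, so flip to ascending k
    k = 2.0 * math.pi / frame.wavelengths_nm
    order = np.argsort(k)
    k_sorted = k[order]
    ac_sorted = ac[order]
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], n)
    ac_k = CubicSpline(k_sorted, ac_sorted)(k_uniform)

    if window == "hann":
        ac_k = ac_k * np.hanning(n)
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")

    n_fft = 2 * n
    spectrum = np.fft.ifft(ac_k, n=n_fft)
    mag = np.abs(spectrum[:n])

    peak = mag.max()
    if peak <= 0:
        db = np.full(n, log_floor_db)
    else:
        floor_lin = peak * 10.0 ** (log_floor_db / 20.0)
        db = 20.0 * np.log10(np.maximum(mag, floor_lin))

    depths = _depth_axis_um(source, n_fft, n)
    return AScan(depths, db, lateral_index=lateral_index)


def assemble_bscan(
    frames: Sequence[SpectralFrame],
    source: SourceSpec,
    *,
    scan_length_mm: float = 6.0,
    timestamp_h: float = 0.0,
    window: str = "hann",
) -> BScan:
    """Assemble adjacent reconstructed A-scans into a B-scan (scan order)."""
    if len(frames) == 0:
        raise ValueError("need at least one spectral frame")
    lengths = {len(f.wavelengths_nm) for f in frames}
    if len(lengths) != 1:
        raise ValueError("mixed spectral grid lengths")
    cols = [reconstruct_ascan(f, source, window=window, lateral_index=i) for i, f in enumerate(frames)]
    image = np.stack([c.log_magnitude_db for c in cols], axis=1)
    depth_extent_mm = cols[0].optical_depths_um[-1] * 1e-3 + cols[0].depth_pixel_um * 1e-3
    return BScan(image, lateral_extent_mm=scan_length_mm, depth_extent_mm=depth_extent_mm,
                 timestamp_h=timestamp_h)


def average_ascans(bscan: BScan, center_lateral_index: int, window: int = 20) -> AScan:
    """Average ``window`` neighbouring A-scans (linear intensity) around a column.

    The quick-readout convention averages 20 depth profiles centred on a
    marked lateral position before peak analysis; averaging is done on linear
    intensity and the result re-log-compressed.  Windows are clipped at the
    image edges.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 <= center_lateral_index < bscan.n_lateral:
        raise ValueError("center column outside image")
    half = window // 2
    lo = max(0, center_lateral_index - half)
    hi = min(bscan.n_lateral, lo + window)
    lo = max(0, hi - window)
    linear = 10.0 ** (bscan.image[:, lo:hi] / 20.0)
    mean = linear.mean(axis=1)
    db = 20.0 * np.log10(np.maximum(mean, 1e-300))
    return AScan(bscan.depth_axis_um(), db, lateral_index=center_lateral_index)


# ---------------------------------------------------------------------------
# File interchange: 16-bit TIFF images with a JSON axis-metadata sidecar.

def write_bscan_tiff(bscans: Sequence[BScan] | BScan, path: str | Path) -> Path:
    """Write one or more B-scans as a 16-bit multi-page TIFF plus sidecar."""
    if isinstance(bscans, BScan):
        bscans = [bscans]
    path = Path(path)
    lo = min(b.image.min() for b in bscans)
    hi = max(b.image.max() for b in bscans)
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    pages = [np.round((b.image - lo) * scale).astype(np.uint16) for b in bscans]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    meta = {
        "db_min": float(lo),
        "db_max": float(hi),
        "lateral_extent_mm": bscans[0].lateral_extent_mm,
        "depth_extent_mm": bscans[0].depth_extent_mm,
        "timestamps_h": [float(b.timestamp_h) for b in bscans],
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def write_spectral_stack(frames: Sequence[SpectralFrame], path: str | Path) -> Path:
    """Write spectral interferograms as a 16-bit multi-page TIFF plus sidecar."""
    if len(frames) == 0:
        raise ValueError("no frames to write")
    path = Path(path)
    lo = min(float(f.intensities.min()) for f in frames)
    hi = max(float(f.intensities.max()) for f in frames)
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    pages = [np.round((f.intensities - lo) * scale).astype(np.uint16)[None, :] for f in frames]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    meta = {"lo": lo, "hi": hi, "wavelengths_nm": frames[0].wavelengths_nm.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_spectral_stack(path: str | Path) -> list[SpectralFrame]:
    """Read spectral frames written by :func:`write_spectral_stack`."""
    path = Path(path)
    raw = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    lo, hi = meta["lo"], meta["hi"]
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    lam = np.asarray(meta["wavelengths_nm"])
    raw = raw.reshape(-1, lam.size)
    return [SpectralFrame(lam, page.astype(float) * scale + lo) for page in raw]


def read_bscan_tiff(path: str | Path) -> list[BScan]:
    """Read B-scans written by :func:`write_bscan_tiff`."""
    path = Path(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    lo, hi = meta["db_min"], meta["db_max"]
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    out = []
    for page, t in zip(raw, meta["timestamps_h"]):
        img = page.astype(float) * scale + lo
        out.append(BScan(img, lateral_extent_mm=meta["lateral_extent_mm"],
                         depth_extent_mm=meta["depth_extent_mm"], timestamp_h=t))
    return out
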