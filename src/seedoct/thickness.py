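"""Seed-coat thickness from B-scans.

The estimator mirrors the manual workflow used on real scans: mark boundary
points at 60 equally spaced lateral positions on the coat's upper (testa
surface) and lower (coat/cotyledon interface) boundaries, fit each point set
with a shape-preserving monotone cubic (PCHIP), take the vertical distance
between the two fitted curves as the optical thickness, and divide by the
coat refractive index (1.42) for physical thickness.  Point picking is
automated here as per-column peak detection; user-supplied point files are
accepted to mirror the manual workflow.

Convention: thickness is measured along the depth axis (vertical), not normal
to the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .reconstruction import AScan, BScan, SourceSpec, average_ascans, axial_resolution

__all__ = [
    "PickResult",
    "BoundaryCurve",
    "ThicknessProfile",
    "ThicknessSummary",
    "seed_span_columns",
    "pick_boundary_points",
    "fit_boundary",
    "thickness_profile",
    "central_quick_thickness",
    "summarize_thickness",
    "measure_bscan_thickness",
    "write_control_points",
    "read_control_points",
]

DEFAULT_COAT_RI = 1.42


def _subpixel_peak(y: np.ndarray, i: int) -> float:
    """Parabolic three-point refinement of a peak index."""
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def _column_peaks(db: np.ndarray, prominence_db: float, distance_px: float,
                  smooth_sigma_px: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak positions (subpixel), amplitudes (dB) and prominences of a profile."""
    if smooth_sigma_px > 0:
        linear = 10.0 ** (db / 20.0)
        linear = gaussian_filter1d(linear, smooth_sigma_px, mode="nearest")
        db = 20.0 * np.log10(np.maximum(linear, 1e-300))
    idx, props = find_peaks(db, prominence=prominence_db, distance=max(1, int(round(distance_px))))
    pos = np.array([_subpixel_peak(db, i) for i in idx])
    return pos, db[idx], props["prominences"]


def seed_span_columns(bscan: BScan, margin_db: float = 10.0) -> tuple[int, int]:
    """Widest contiguous run of columns whose peak exceeds noise floor + margin.

    The noise floor is the image median (background-dominated); returns
    (first, last) inclusive column indices of the seed span.
    """
    colmax = bscan.image.max(axis=0)
    floor = float(np.median(bscan.image))
    above = colmax > floor + margin_db
    if not above.any():
        raise ValueError("no seed found: no columns rise above the noise floor")
    best_len, best = 0, (0, 0)
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best = j - i + 1, (i, j)
            i = j + 1
        else:
            i += 1
    return best


@dataclass
class PickResult:
    """Boundary picks at equally spaced lateral positions (NaN = no valid pair)."""

    x_mm: np.ndarray
    upper_um: np.ndarray      # surface optical depth
    lower_um: np.ndarray      # coat interface optical depth
    span_columns: tuple[int, int]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.upper_um) & np.isfinite(self.lower_um)

    def upper_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.isfinite(self.upper_um)
        return self.x_mm[m], self.upper_um[m]

    def lower_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.valid
        return self.x_mm[m], self.lower_um[m]


def pick_boundary_points(
    bscan: BScan,
    n_points: int = 60,
    *,
    min_prominence_db: float = 6.0,
    min_separation_um: float | None = None,
    smooth_sigma_px: float = 1.5,
    edge_margin_frac: float = 0.02,
) -> PickResult:
    """Automatic surface/interface picks at ``n_points`` lateral positions.

    At each position the upper point is the first detected peak of the
    (speckle-smoothed) depth profile and the lower point the next prominent
    peak below it; positions without a valid peak pair are flagged NaN.
    Raises if fewer than 4 positions yield a valid pair.
    """
    if min_separation_um is None:
        min_separation_um = axial_resolution(SourceSpec(), 1.0)
    ax_px = bscan.axial_pixel_um
    first, last = seed_span_columns(bscan)
    lo = first + int(edge_margin_frac * bscan.n_lateral)
    hi = last - int(edge_margin_frac * bscan.n_lateral)
    if hi <= lo:
        lo, hi = first, last
    cols = np.unique(np.round(np.linspace(lo, hi, n_points)).astype(int))
    xs = (cols + 0.5) * bscan.lateral_pixel_mm

    upper = np.full(len(cols), np.nan)
    lower = np.full(len(cols), np.nan)
    for j, c in enumerate(cols):
        pos, _, _ = _column_peaks(bscan.image[:, c], min_prominence_db,
                                  min_separation_um / ax_px, smooth_sigma_px)
        if len(pos) >= 1:
            upper[j] = pos[0] * ax_px
        if len(pos) >= 2:
            lower[j] = pos[1] * ax_px
    if (np.isfinite(upper) & np.isfinite(lower)).sum() < 4:
        raise ValueError("fewer than 4 valid boundary-point pairs; cannot fit curves")
    return PickResult(xs, upper, lower, (first, last))


@dataclass
class BoundaryCurve:
    """Monotone piecewise-cubic Hermite (PCHIP) fit through boundary points."""

    x_mm: np.ndarray
    z_um: np.ndarray
    role: str = "upper"
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.x_mm.size < 4:
            raise ValueError("need at least 4 boundary points")
        d = np.diff(self.x_mm)
        if np.any(d == 0):
            raise ValueError("duplicate lateral coordinates")
        if np.any(d < 0):
            raise ValueError("points must be strictly increasing laterally")
        self._interp = PchipInterpolator(self.x_mm, self.z_um, extrapolate=False)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self._interp(x)

    @property
    def span_mm(self) -> tuple[float, float]:
        return float(self.x_mm[0]), float(self.x_mm[-1])


def fit_boundary(points: tuple[np.ndarray, np.ndarray] | np.ndarray, role: str = "upper") -> BoundaryCurve:
    """Fit a shape-preserving interpolant through (lateral mm, depth μm) points."""
    if isinstance(points, tuple):
        x, z = points
    else:
        pts = np.asarray(points, dtype=float)
        x, z = pts[:, 0], pts[:, 1]
    return BoundaryCurve(x, z, role=role)


@dataclass
class ThicknessProfile:
    """Coat thickness versus lateral position at one time point."""

    x_mm: np.ndarray
    optical_um: np.ndarray
    coat_ri: float = DEFAULT_COAT_RI
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.optical_um = np.asarray(self.optical_um, dtype=float)

    @property
    def physical_um(self) -> np.ndarray:
        return self.optical_um / self.coat_ri

    @property
    def crossing_mask(self) -> np.ndarray:
        """Positions where the fitted curves cross (negative thickness)."""
        return self.optical_um < 0


def thickness_profile(
    upper: BoundaryCurve,
    lower: BoundaryCurve,
    coat_ri: float = DEFAULT_COAT_RI,
    grid: np.ndarray | None = None,
    timestamp_h: float = 0.0,
) -> ThicknessProfile:
    """Vertical distance between the fitted curves, RI-converted.

    Negative thickness (crossing curves) is flagged via ``crossing_mask``
    rather than silently clipped.
    """
    lo = max(upper.span_mm[0], lower.span_mm[0])
    hi = min(upper.span_mm[1], lower.span_mm[1])
    if hi <= lo:
        raise ValueError("boundary curves do not overlap laterally")
    if grid is None:
        grid = np.linspace(lo, hi, 200)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError("grid extends outside the curves' common span")
    optical = np.asarray(lower(grid)) - np.asarray(upper(grid))
    return ThicknessProfile(grid, optical, coat_ri=coat_ri, timestamp_h=timestamp_h)


@dataclass
class ThicknessSummary:
    """Distribution summary with 2×IQR whiskers (boxplot convention)."""

    mean_um: float
    sd_um: float
    median_um: float
    q1_um: float
    q3_um: float
    whisker_low_um: float
    whisker_high_um: float
    n: int


def summarize_thickness(profile: ThicknessProfile | np.ndarray) -> ThicknessSummary:
    """Mean, sample SD, linear-interpolation quartiles and 2×IQR whiskers."""
    values = profile.physical_um if isinstance(profile, ThicknessProfile) else np.asarray(profile, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty thickness profile")
    if values.size < 5:
        raise ValueError("need at least 5 valid positions to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    in_low = values[values >= q1 - 2.0 * iqr]
    in_high = values[values <= q3 + 2.0 * iqr]
    return ThicknessSummary(
        mean_um=float(values.mean()),
        sd_um=float(values.std(ddof=1)),
        median_um=float(med),
        q1_um=float(q1),
        q3_um=float(q3),
        whisker_low_um=float(in_low.min()),
        whisker_high_um=float(in_high.max()),
        n=int(values.size),
    )


def central_quick_thickness(
    bscan: BScan,
    window: int = 20,
    coat_ri: float = DEFAULT_COAT_RI,
    *,
    min_prominence_db: float = 6.0,
    min_separation_um: float | None = None,
) -> float:
    """Quick coat-thickness readout from the 20-average central depth profile.

    Optical distance between the first two prominent peaks of the averaged
    central A-scan, divided by the coat RI.  Raises if fewer than two peaks
    are resolved (coat thinner than the axial resolution).
    """
    if min_separation_um is None:
        min_separation_um = axial_resolution(SourceSpec(), 1.0)
    first, last = seed_span_columns(bscan)
    center = (first + last) // 2
    avg = average_ascans(bscan, center, window=window)
    pos, _, _ = _column_peaks(avg.log_magnitude_db, min_prominence_db,
                              min_separation_um / bscan.axial_pixel_um, 0.0)
    if len(pos) < 2:
        raise ValueError("coat unresolvable: fewer than two peaks in the central averaged A-scan")
    optical = (pos[1] - pos[0]) * bscan.axial_pixel_um
    return float(optical / coat_ri)


def measure_bscan_thickness(
    bscan: BScan,
    n_points: int = 60,
    coat_ri: float = DEFAULT_COAT_RI,
    **pick_kwargs,
) -> tuple[ThicknessProfile, ThicknessSummary, PickResult]:
    """Full per-B-scan pipeline: pick → fit both boundaries → profile → summary."""
    pick = pick_boundary_points(bscan, n_points, **pick_kwargs)
    m = pick.valid
    upper = fit_boundary((pick.x_mm[m], pick.upper_um[m]), role="upper")
    lower = fit_boundary((pick.x_mm[m], pick.lower_um[m]), role="lower")
    profile = thickness_profile(upper, lower, coat_ri=coat_ri, timestamp_h=bscan.timestamp_h)
    return profile, summarize_thickness(profile), pick


# ---------------------------------------------------------------------------
# Control-point interchange (`role,x_mm,z_um`) for the manual workflow.

def write_control_points(path: str | Path, upper: tuple[np.ndarray, np.ndarray],
                         lower: tuple[np.ndarray, np.ndarray]) -> Path:
    rows = [("upper", x, z) for x, z in zip(*upper)] + [("lower", x, z) for x, z in zip(*lower)]
    df = pd.DataFrame(rows, columns=["role", "x_mm", "z_um"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_control_points(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path)
    out = {}
    for role, grp in df.groupby("role"):
        grp = grp.sort_values("x_mm")
        out[str(role)] = (grp["x_mm"].to_numpy(), grp["z_um"].to_numpy())
    return out
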