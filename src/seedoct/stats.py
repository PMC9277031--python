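"""Alignment and correlation of OCT-, camera- and gravimetry-derived series.

Weight gain is the gravimetric gold standard for staging germination; the OCT
coat-thickness and camera diameter time courses are validated against it with
the Pearson correlation coefficient

    r = Σ (x_i − x̄)(y_i − ȳ) / √( Σ (x_i − x̄)² · Σ (y_i − ȳ)² )

computed after linear interpolation of the finer-sampled series onto the
coarser (weighing) grid, restricted to the overlapping time span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PairedSeries", "CorrelationResult", "align_series", "pearson_r",
           "validate_against_weight"]


@dataclass
class PairedSeries:
    """Two series on a common time grid after alignment."""

    times_h: np.ndarray
    x: np.ndarray
    y: np.ndarray
    method: str = "linear"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times_h) == len(self.x) == len(self.y)):
            raise ValueError("aligned series must have equal length")
        if len(self.times_h) < 3:
            raise ValueError("need at least 3 aligned samples")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("missing values after alignment")


@dataclass
class CorrelationResult:
    r: float
    n: int
    label: str = ""


def align_series(
    times_x, x, times_y, y, *, method: str = "linear"
) -> PairedSeries:
    """Interpolate both series onto the coarser grid inside the overlap.

    The target grid is the time stamps of whichever series has fewer samples
    inside the overlapping span (ties go to x, conventionally the weight
    series); the other series is linearly interpolated onto it.
    """
    tx = np.asarray(times_x, dtype=float)
    ty = np.asarray(times_y, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tx.size < 3 or ty.size < 3:
        raise ValueError("each series needs at least 3 samples")
    lo = max(tx.min(), ty.min())
    hi = min(tx.max(), ty.max())
    if hi <= lo:
        raise ValueError("series have no overlapping time span")
    tx_in = tx[(tx >= lo) & (tx <= hi)]
    ty_in = ty[(ty >= lo) & (ty <= hi)]
    grid = tx_in if len(tx_in) <= len(ty_in) else ty_in
    xi = np.interp(grid, tx, x)
    yi = np.interp(grid, ty, y)
    return PairedSeries(grid, xi, yi, method=method)


def pearson_r(paired: PairedSeries, label: str = "") -> CorrelationResult:
    """Pearson correlation coefficient of an aligned pair.

    Raises on a constant series (zero denominator).
    """
    x, y = paired.x, paired.y
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a constant series")
    r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    return CorrelationResult(r, len(x), label)


def validate_against_weight(
    weight: tuple[np.ndarray, np.ndarray],
    thickness: tuple[np.ndarray, np.ndarray] | None = None,
    diameter: tuple[np.ndarray, np.ndarray] | None = None,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Correlate OCT thickness and camera diameter against the weight standard.

    Returns a table with one row per available pair:
    ``pair, x_label, y_label, n, r, passes_0.95`` where the flag is
    ``|r| > threshold``.
    """
    tw, w = weight
    rows = []
    for name, series in (("weight~thickness", thickness), ("weight~diameter", diameter)):
        if series is None:
            continue
        ts, v = series
        paired = align_series(tw, w, ts, v)
        res = pearson_r(paired, label=name)
        rows.append({
            "pair": name,
            "x_label": "weight_g",
            "y_label": name.split("~")[1],
            "n": res.n,
            "r": res.r,
            f"passes_{threshold:g}": bool(abs(res.r) > threshold),
        })
    if not rows:
        raise ValueError("no series supplied to validate")
    return pd.DataFrame(rows)
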