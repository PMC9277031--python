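"""Morphological germination indicators and phase segmentation.

Four indicators partition a germination record:

1. **surface wrinkles** (camera; detected by :mod:`seedoct.morphometry`),
2. **cotyledon layers** become visible as new subsurface peaks in the flank
   depth profiles (lateral fractions 0.25 and 0.75 of the seed span),
3. **radicle emergence** — a persistent new subsurface peak in the central
   averaged depth profile whose amplitude stays below the surface peak; this
   marks the start of the lag phase (phase II),
4. **seed-coat crack** — a surface discontinuity (missing surface picks or a
   depth jump exceeding 5 axial pixels between adjacent picks); this marks
   the start of phase III.

A persistence rule (default 2 consecutive frames) suppresses speckle-induced
transient peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .reconstruction import AScan, SourceSpec, axial_resolution
from .thickness import _subpixel_peak

__all__ = [
    "PeakSet",
    "Detection",
    "IndicatorTimeline",
    "PhaseSegmentation",
    "detect_peaks",
    "detect_radicle_emergence",
    "detect_cotyledon_layer",
    "detect_coat_crack",
    "classify_phases",
]


@dataclass
class PeakSet:
    """Detected peaks of one depth profile, sorted by depth."""

    depths_um: np.ndarray
    amplitudes_db: np.ndarray
    prominences_db: np.ndarray

    def __len__(self) -> int:
        return len(self.depths_um)

    @property
    def surface_depth_um(self) -> float:
        if len(self) == 0:
            raise ValueError("no peaks")
        return float(self.depths_um[0])

    @property
    def surface_amplitude_db(self) -> float:
        if len(self) == 0:
            raise ValueError("no peaks")
        return float(self.amplitudes_db[0])

    def n_subsurface(self, min_depth_um: float = 0.0) -> int:
        """Peaks deeper than the surface peak with amplitude below it."""
        if len(self) == 0:
            return 0
        deeper = self.depths_um > self.surface_depth_um + min_depth_um
        weaker = self.amplitudes_db < self.surface_amplitude_db
        return int(np.count_nonzero(deeper & weaker))


def detect_peaks(
    ascan: AScan,
    min_prominence_db: float = 6.0,
    min_separation_um: float | None = None,
) -> PeakSet:
    """Local maxima of a depth profile passing prominence/separation filters."""
    db = np.asarray(ascan.log_magnitude_db, dtype=float)
    if not np.all(np.isfinite(db)):
        raise ValueError("A-scan contains non-finite values")
    if min_separation_um is None:
        min_separation_um = axial_resolution(SourceSpec(), 1.0)
    px = ascan.depth_pixel_um
    idx, props = find_peaks(db, prominence=min_prominence_db,
                            distance=max(1, int(round(min_separation_um / px))))
    pos = np.array([_subpixel_peak(db, i) for i in idx]) * px
    return PeakSet(pos, db[idx], props["prominences"])


@dataclass
class Detection:
    """One detected onset: time, frame index (0-based) and evidence notes."""

    onset_h: float
    frame_index: int
    evidence: list[str] = field(default_factory=list)


@dataclass
class IndicatorTimeline:
    """Onset times of the four indicators for one seed (None = never seen)."""

    wrinkle: Detection | None = None
    cotyledon: Detection | None = None
    radicle: Detection | None = None
    crack: Detection | None = None

    def onset_h(self, name: str) -> float | None:
        det = getattr(self, name)
        return None if det is None else det.onset_h


def _check_cadence(times_h: Sequence[float]) -> None:
    t = np.asarray(times_h, dtype=float)
    if t.size >= 2:
        d = np.diff(t)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("acquisition cadence is irregular")


def _first_persistent(flags: np.ndarray, persistence: int) -> int | None:
    """First index i such that flags[i : i+persistence] are all True."""
    n = len(flags)
    for i in range(n - persistence + 1):
        if flags[i:i + persistence].all():
            return i
    return None


def _emergence_flags(
    ascans: Sequence[AScan],
    min_prominence_db: float,
    min_separation_um: float | None,
) -> np.ndarray:
    """Per-frame flag: the profile has gained a new subsurface peak vs frame 0."""
    counts = []
    for a in ascans:
        ps = detect_peaks(a, min_prominence_db, min_separation_um)
        counts.append(ps.n_subsurface() if len(ps) else 0)
    counts = np.asarray(counts)
    baseline = counts[0]
    return counts > baseline


def detect_radicle_emergence(
    ascans: Sequence[AScan],
    times_h: Sequence[float],
    persistence: int = 2,
    *,
    min_prominence_db: float = 6.0,
    min_separation_um: float | None = None,
) -> Detection | None:
    """Earliest persistent new subsurface peak in the central averaged profiles.

    The new peak must be deeper than the surface peak and weaker than it, and
    must persist for at least ``persistence`` consecutive frames; returns
    None if no such emergence occurs.  The frame cadence must be regular.
    """
    if len(ascans) < 2:
        raise ValueError("need at least two frames")
    if len(ascans) != len(times_h):
        raise ValueError("times and frames differ in length")
    _check_cadence(times_h)
    flags = _emergence_flags(ascans, min_prominence_db, min_separation_um)
    i = _first_persistent(flags, persistence)
    if i is None:
        return None
    return Detection(float(times_h[i]), i, ["new subsurface peak in central averaged A-scan"])


def detect_cotyledon_layer(
    left_ascans: Sequence[AScan] | None,
    right_ascans: Sequence[AScan] | None,
    times_h: Sequence[float],
    persistence: int = 2,
    *,
    min_prominence_db: float = 6.0,
    min_separation_um: float | None = None,
) -> Detection | None:
    """Earliest frame at which BOTH flank profiles have gained a subsurface peak.

    If only one flank is available the detector degrades to single-flank and
    records a warning in the detection evidence.
    """
    if left_ascans is None and right_ascans is None:
        raise ValueError("at least one flank position is required")
    _check_cadence(times_h)
    evidence: list[str] = []
    onsets: list[int] = []
    for name, seq in (("left", left_ascans), ("right", right_ascans)):
        if seq is None:
            evidence.append(f"warning: {name} flank unavailable, single-flank detection")
            continue
        flags = _emergence_flags(seq, min_prominence_db, min_separation_um)
        i = _first_persistent(flags, persistence)
        if i is None:
            return None
        onsets.append(i)
        evidence.append(f"{name} flank new peak at frame {i}")
    i = max(onsets)
    return Detection(float(times_h[i]), i, evidence)


def detect_coat_crack(
    surface_depths_um: Sequence[np.ndarray],
    times_h: Sequence[float],
    axial_pixel_um: float,
    persistence: int = 2,
    *,
    gap_run: int = 3,
    jump_pixels: float = 5.0,
) -> Detection | None:
    """Earliest persistent surface discontinuity across per-frame pick arrays.

    A frame is flagged cracked when either ``gap_run`` consecutive pick
    positions have no detectable surface (NaN) or the depth jump between
    adjacent valid picks strictly exceeds ``jump_pixels`` axial pixels.
    """
    if len(surface_depths_um) != len(times_h):
        raise ValueError("times and frames differ in length")
    threshold_um = jump_pixels * axial_pixel_um
    flags = []
    for depths in surface_depths_um:
        depths = np.asarray(depths, dtype=float)
        missing = ~np.isfinite(depths)
        gap = False
        run = 0
        for m in missing:
            run = run + 1 if m else 0
            if run >= gap_run:
                gap = True
                break
        jump = False
        valid = depths[np.isfinite(depths)]
        if valid.size >= 2:
            # adjacent in pick order among valid positions
            idx = np.nonzero(np.isfinite(depths))[0]
            adjacent = np.diff(idx) == 1
            diffs = np.abs(np.diff(depths[idx]))[adjacent]
            jump = bool(np.any(diffs > threshold_um))
        flags.append(gap or jump)
    i = _first_persistent(np.asarray(flags), persistence)
    if i is None:
        return None
    return Detection(float(times_h[i]), i, ["surface discontinuity"])


@dataclass
class PhaseSegmentation:
    """Germination phases as [start, end) intervals (phase III closed at end).

    Phase I (imbibition) runs to the radicle onset, phase II (lag) from the
    radicle onset to the crack onset, phase III (completion) afterwards.
    Missing onsets collapse later phases to empty.
    """

    phase_1: tuple[float, float]
    phase_2: tuple[float, float]
    phase_3: tuple[float, float]

    def phase_at(self, t_h: float) -> int:
        if self.phase_3[0] <= t_h <= self.phase_3[1] and self.phase_3[1] > self.phase_3[0]:
            return 3
        if self.phase_2[0] <= t_h < self.phase_2[1]:
            return 2
        return 1


def classify_phases(timeline: IndicatorTimeline, record_span_h: float) -> PhaseSegmentation:
    """Segment the record at the radicle and crack onsets."""
    if record_span_h <= 0:
        raise ValueError("record span must be positive")
    r = timeline.onset_h("radicle")
    c = timeline.onset_h("crack")
    if r is not None and c is not None and c < r:
        raise ValueError("inconsistent timeline: crack onset precedes radicle onset")
    end = record_span_h
    r_eff = min(r, end) if r is not None else end
    c_eff = min(c, end) if c is not None else end
    if r is None:
        c_eff = end  # no phase II start -> phase III undefined too
    return PhaseSegmentation(
        phase_1=(0.0, r_eff),
        phase_2=(r_eff, c_eff),
        phase_3=(c_eff, end),
    )
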