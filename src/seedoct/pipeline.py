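"""End-to-end orchestration: simulate → reconstruct → quantify → detect → correlate.

`run_pipeline` produces, per run: a thickness CSV, an indicator-timeline CSV,
a phase CSV, a diameter CSV, a correlation CSV, a phase-annotated thickness
boxplot, a normalized weight/thickness/diameter time-course plot, a per-seed
indicator bar chart, and a machine-readable manifest (config + version +
seed + per-stage timing) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indicators import (Detection, IndicatorTimeline, classify_phases,
                         detect_coat_crack, detect_cotyledon_layer,
                         detect_radicle_emergence)
from .morphometry import outline_from_image, wrinkle_index
from .phantom import (CameraConfig, EventTimes, PhantomConfig, SimulatedTimecourse,
                      WeightConfig, simulate_cohort, simulate_timecourse)
from .reconstruction import average_ascans
from .thickness import measure_bscan_thickness

__all__ = ["RunConfig", "OctSeriesAnalysis", "CameraSeriesAnalysis",
           "analyze_oct_timecourse", "analyze_bscan_series",
           "analyze_camera_timecourse", "run_pipeline"]

log = logging.getLogger("seedoct")

FLANK_FRACTIONS = (0.25, 0.75)   # lateral positions 1 and 3 within the seed span
CENTER_FRACTION = 0.50           # position 2


@dataclass
class RunConfig:
    """Reproducible description of one pipeline run (YAML round-trippable)."""

    mode: str = "simulate"                 # "simulate" or a path to input files
    outdir: str = "seedoct_run"
    seed: int = 0
    n_seeds: int = 10
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_boundary_points: int = 60
    coat_ri: float = 1.42
    min_prominence_db: float = 6.0
    averaging_window: int = 20

    def to_yaml(self, path: str | Path) -> Path:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        payload = plain(dataclasses.asdict(self))
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        ph = payload.pop("phantom", None)
        cfg = cls(**payload)
        if ph is not None:
            for key in ("events", "camera", "weight", "source"):
                sub = ph.get(key)
                if isinstance(sub, dict):
                    if key == "camera":
                        for tup in ("center_frac", "seed_rgb", "background_rgb"):
                            if isinstance(sub.get(tup), list):
                                sub[tup] = tuple(sub[tup])
                    klass = {"events": EventTimes, "camera": CameraConfig,
                             "weight": WeightConfig}.get(key)
                    if klass is not None:
                        ph[key] = klass(**sub)
                    else:
                        from .reconstruction import SourceSpec
                        ph[key] = SourceSpec(**sub)
            for key in ("thickness_times_h", "thickness_values_um",
                        "roughness_times_h", "roughness_values_um"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            cfg.phantom = PhantomConfig(**ph)
        return cfg


@dataclass
class OctSeriesAnalysis:
    """Per-frame thickness statistics plus the OCT-derived indicator onsets."""

    times_h: np.ndarray
    mean_um: np.ndarray
    sd_um: np.ndarray
    median_um: np.ndarray
    q1_um: np.ndarray
    q3_um: np.ndarray
    n_points: np.ndarray
    radicle: Detection | None
    cotyledon: Detection | None
    crack: Detection | None

    def summary_frame(self, seed_id: str = "seed1") -> pd.DataFrame:
        return pd.DataFrame({
            "seed_id": seed_id,
            "time_h": self.times_h,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "median_um": self.median_um,
            "q1_um": self.q1_um,
            "q3_um": self.q3_um,
            "n_points": self.n_points,
        })


def analyze_oct_timecourse(
    tc: SimulatedTimecourse,
    *,
    n_points: int = 60,
    coat_ri: float = 1.42,
    window: int = 20,
    min_prominence_db: float = 6.0,
    persistence: int = 2,
) -> OctSeriesAnalysis:
    """Run the full OCT analysis over a simulated series (one pass per frame).

    Each frame is rendered once; the boundary-fit thickness summary, the
    averaged depth profiles at the flank/central positions and the per-pick
    surface depths are extracted, then the radicle, cotyledon and crack
    detectors run over the assembled per-frame records.
    """
    return _analyze_bscan_frames(
        (tc.bscan(i) for i in range(len(tc))), tc.times_h,
        n_points=n_points, coat_ri=coat_ri, window=window,
        min_prominence_db=min_prominence_db, persistence=persistence)


def analyze_bscan_series(
    bscans,
    times_h=None,
    *,
    n_points: int = 60,
    coat_ri: float = 1.42,
    window: int = 20,
    min_prominence_db: float = 6.0,
    persistence: int = 2,
) -> OctSeriesAnalysis:
    """Same OCT analysis over pre-reconstructed B-scans (e.g. loaded from TIFF)."""
    bscans = list(bscans)
    if times_h is None:
        times_h = np.asarray([b.timestamp_h for b in bscans], dtype=float)
    return _analyze_bscan_frames(
        iter(bscans), np.asarray(times_h, dtype=float),
        n_points=n_points, coat_ri=coat_ri, window=window,
        min_prominence_db=min_prominence_db, persistence=persistence)


def _analyze_bscan_frames(
    frames,
    times,
    *,
    n_points: int,
    coat_ri: float,
    window: int,
    min_prominence_db: float,
    persistence: int,
) -> OctSeriesAnalysis:
    times = np.asarray(times, dtype=float)
    n = len(times)
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    med = np.full(n, np.nan)
    q1 = np.full(n, np.nan)
    q3 = np.full(n, np.nan)
    npts = np.zeros(n, dtype=int)
    center_scans, left_scans, right_scans, surfaces = [], [], [], []
    axial_px = None
    for i, bscan in enumerate(frames):
        axial_px = bscan.axial_pixel_um
        profile, summary, pick = measure_bscan_thickness(
            bscan, n_points, coat_ri, min_prominence_db=min_prominence_db)
        mean[i], sd[i] = summary.mean_um, summary.sd_um
        med[i], q1[i], q3[i] = summary.median_um, summary.q1_um, summary.q3_um
        npts[i] = summary.n
        first, last = pick.span_columns
        span = last - first
        for frac, store in ((FLANK_FRACTIONS[0], left_scans),
                            (CENTER_FRACTION, center_scans),
                            (FLANK_FRACTIONS[1], right_scans)):
            col = int(round(first + frac * span))
            store.append(average_ascans(bscan, col, window=window))
        surfaces.append(pick.upper_um)

    radicle = cotyledon = crack = None
    if n >= 2:
        radicle = detect_radicle_emergence(center_scans, times, persistence,
                                           min_prominence_db=min_prominence_db)
        cotyledon = detect_cotyledon_layer(left_scans, right_scans, times, persistence,
                                           min_prominence_db=min_prominence_db)
        crack = detect_coat_crack(surfaces, times, axial_px, persistence)
    return OctSeriesAnalysis(times, mean, sd, med, q1, q3, npts, radicle, cotyledon, crack)


@dataclass
class CameraSeriesAnalysis:
    """Per-frame diameter and roughness plus the wrinkle onset."""

    times_h: np.ndarray
    diameter_mm: np.ndarray
    roughness: np.ndarray
    wrinkle: Detection | None

    def frame(self, seed_id: str = "seed1") -> pd.DataFrame:
        return pd.DataFrame({
            "seed_id": seed_id,
            "time_h": self.times_h,
            "diameter_mm": self.diameter_mm,
            "roughness": self.roughness,
        })


def analyze_camera_timecourse(tc: SimulatedTimecourse, **wrinkle_kwargs) -> CameraSeriesAnalysis:
    """Segment every camera frame; measure diameter, roughness, wrinkle onset."""
    outlines = []
    diam = np.full(len(tc), np.nan)
    for i in range(len(tc)):
        try:
            outline = outline_from_image(tc.camera(i),
                                         water_line_frac=tc.config.camera.water_line_frac)
        except ValueError:
            log.warning("frame %d: no seed found, skipped", i)
            outlines.append(None)
            continue
        outlines.append(outline)
        diam[i] = outline.equivalent_diameter_mm
    rough, wrinkle = wrinkle_index(outlines, tc.times_h, **wrinkle_kwargs)
    return CameraSeriesAnalysis(tc.times_h, diam, rough, wrinkle)


def _timeline(oct_a: OctSeriesAnalysis, cam_a: CameraSeriesAnalysis) -> IndicatorTimeline:
    return IndicatorTimeline(wrinkle=cam_a.wrinkle, cotyledon=oct_a.cotyledon,
                             radicle=oct_a.radicle, crack=oct_a.crack)


# ---------------------------------------------------------------------------
# Plots (one per headline figure style)


def _plot_boxes(analyses: Sequence[OctSeriesAnalysis], path: Path) -> None:
    a = analyses[0]
    sel = [i for i, t in enumerate(a.times_h) if t > 0 and abs(t / 3.0 - round(t / 3.0)) < 1e-9]
    if not sel:
        sel = list(range(0, len(a.times_h), max(1, len(a.times_h) // 12)))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar([a.times_h[i] for i in sel], [a.mean_um[i] for i in sel],
                yerr=[a.sd_um[i] for i in sel], fmt="s", capsize=3)
    for i in sel:
        ax.add_patch(plt.Rectangle((a.times_h[i] - 0.5, a.q1_um[i]), 1.0,
                                   a.q3_um[i] - a.q1_um[i], fill=False))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("seed-coat thickness (μm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_timecourse(weight, thickness, diameter, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for (t, v), label in ((weight, "weight (norm.)"), (thickness, "coat thickness (norm.)"),
                          (diameter, "diameter (norm.)")):
        v = np.asarray(v, dtype=float)
        rng = v.max() - v.min()
        norm = (v - v.min()) / rng if rng > 0 else v * 0
        ax.plot(t, norm, marker=".", label=label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_indicator_bars(timelines: dict[str, IndicatorTimeline], span_h: float, path: Path) -> None:
    names = ["wrinkle", "cotyledon", "radicle", "crack"]
    colors = {"wrinkle": "0.5", "cotyledon": "peru", "radicle": "tab:blue", "crack": "tab:green"}
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(4, len(timelines))))
    for row, (sid, tl) in enumerate(timelines.items()):
        for k, name in enumerate(names):
            onset = tl.onset_h(name)
            if onset is not None:
                ax.barh(row + k * 0.18 - 0.27, span_h - onset, left=onset, height=0.15,
                        color=colors[name], label=name if row == 0 else None)
    ax.set_yticks(range(len(timelines)), list(timelines))
    ax.set_xlim(0, span_h)
    ax.set_xlabel("time (h)")
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                manifest["stages"][name] = {
                    "seconds": round(dt, 3),
                    "ok": exc_type is None,
                    "error": None if exc_type is None else repr(exc),
                }
                log.info("stage %s done in %.2fs", name, dt)
                return False
        return _Timer()

    if config.mode != "simulate":
        indir = Path(config.mode)
        if not indir.is_dir() or not any(indir.iterdir()):
            raise ValueError(f"input directory {indir} is missing or empty")
        try:
            _run_file_stages(config, indir, outdir, manifest, stage)
        finally:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest

    phantom = dataclasses.replace(config.phantom, seed_rng=config.seed)
    try:
        _run_stages(config, phantom, outdir, manifest, stage)
    finally:
        # partial failures stay visible: the manifest is written regardless
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _run_file_stages(config: RunConfig, indir: Path, outdir: Path,
                     manifest: dict, stage) -> None:
    """Analyze pre-reconstructed B-scan TIFF stacks from ``indir``.

    Optional ``weights.csv`` (``seed_id,time_h,weight_g``) enables the
    weight-correlation stage; there is no camera stream in file mode, so the
    wrinkle indicator is unavailable (recorded as a warning).
    """
    from .reconstruction import read_bscan_tiff

    with stage("load"):
        bscans = []
        for tiff in sorted(list(indir.glob("*.tif")) + list(indir.glob("*.tiff"))):
            bscans.extend(read_bscan_tiff(tiff))
        if not bscans:
            raise ValueError(f"no B-scan TIFF stacks found in {indir}")

    with stage("analyze"):
        oa = analyze_bscan_series(
            bscans, n_points=config.n_boundary_points, coat_ri=config.coat_ri,
            window=config.averaging_window, min_prominence_db=config.min_prominence_db)
        manifest["warnings"].append(
            "file mode: no camera stream, wrinkle indicator unavailable")
        tl = IndicatorTimeline(cotyledon=oa.cotyledon, radicle=oa.radicle, crack=oa.crack)

    corr = None
    weights_csv = indir / "weights.csv"
    if weights_csv.exists():
        with stage("correlate"):
            from .stats import validate_against_weight
            wdf = pd.read_csv(weights_csv)
            mean_w = wdf.groupby("time_h")["weight_g"].mean()
            corr = validate_against_weight(
                (mean_w.index.to_numpy(), mean_w.to_numpy()),
                thickness=(oa.times_h, oa.mean_um))

    with stage("write"):
        paths = {"thickness": outdir / "thickness.csv",
                 "timeline": outdir / "timeline.csv",
                 "phases": outdir / "phases.csv"}
        oa.summary_frame().to_csv(paths["thickness"], index=False)
        timeline_rows = []
        for name in ("wrinkle", "cotyledon", "radicle", "crack"):
            det = getattr(tl, name)
            timeline_rows.append({
                "seed_id": "seed1", "indicator": name,
                "onset_h": "" if det is None else det.onset_h,
                "frame_index": "" if det is None else det.frame_index,
            })
        pd.DataFrame(timeline_rows).to_csv(paths["timeline"], index=False)
        span = float(oa.times_h[-1]) if len(oa.times_h) else 0.0
        phase_rows = []
        if span > 0:
            seg = classify_phases(tl, span)
            for pname, (a, b) in (("I", seg.phase_1), ("II", seg.phase_2),
                                  ("III", seg.phase_3)):
                phase_rows.append({"seed_id": "seed1", "phase": pname,
                                   "start_h": a, "end_h": b})
        pd.DataFrame(phase_rows).to_csv(paths["phases"], index=False)
        if corr is not None:
            paths["correlation"] = outdir / "correlation.csv"
            corr.to_csv(paths["correlation"], index=False)
            manifest["correlation"] = corr.to_dict(orient="records")
        _plot_boxes([oa], outdir / "thickness_boxplot.png")
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}


def _run_stages(config: RunConfig, phantom: PhantomConfig, outdir: Path,
                manifest: dict, stage) -> None:
    with stage("simulate"):
        cohort = simulate_cohort(phantom, n_seeds=config.n_seeds)

    oct_rows, cam_rows, timeline_rows, phase_rows = [], [], [], []
    oct_analyses, cam_analyses = [], []
    timelines: dict[str, IndicatorTimeline] = {}
    with stage("analyze"):
        for s, tc in enumerate(cohort):
            sid = f"seed{s + 1}"
            oa = analyze_oct_timecourse(
                tc, n_points=config.n_boundary_points, coat_ri=config.coat_ri,
                window=config.averaging_window, min_prominence_db=config.min_prominence_db)
            ca = analyze_camera_timecourse(tc)
            oct_analyses.append(oa)
            cam_analyses.append(ca)
            oct_rows.append(oa.summary_frame(sid))
            cam_rows.append(ca.frame(sid))
            tl = _timeline(oa, ca)
            timelines[sid] = tl
            for name in ("wrinkle", "cotyledon", "radicle", "crack"):
                det = getattr(tl, name)
                timeline_rows.append({
                    "seed_id": sid, "indicator": name,
                    "onset_h": "" if det is None else det.onset_h,
                    "frame_index": "" if det is None else det.frame_index,
                })
                if det is not None:
                    for note in det.evidence:
                        if note.startswith("warning"):
                            manifest["warnings"].append(f"{sid}/{name}: {note}")
            try:
                seg = classify_phases(tl, phantom.duration_h)
                for pname, (a, b) in (("I", seg.phase_1), ("II", seg.phase_2),
                                      ("III", seg.phase_3)):
                    phase_rows.append({"seed_id": sid, "phase": pname,
                                       "start_h": a, "end_h": b})
            except ValueError as exc:
                manifest["warnings"].append(f"{sid}/phases: {exc}")

    with stage("correlate"):
        mean_thick = np.nanmean(np.stack([a.mean_um for a in oct_analyses]), axis=0)
        mean_diam = np.nanmean(np.stack([a.diameter_mm for a in cam_analyses]), axis=0)
        weights = np.stack([tc.weights[0].weights_g for tc in cohort])
        wt = cohort[0].weights[0].times_h
        mean_weight = weights.mean(axis=0)
        from .stats import validate_against_weight
        corr = validate_against_weight(
            (wt, mean_weight),
            thickness=(cohort[0].times_h, mean_thick),
            diameter=(cohort[0].times_h, mean_diam),
        )

    with stage("write"):
        paths = {
            "thickness": outdir / "thickness.csv",
            "diameter": outdir / "diameter.csv",
            "timeline": outdir / "timeline.csv",
            "phases": outdir / "phases.csv",
            "correlation": outdir / "correlation.csv",
        }
        pd.concat(oct_rows, ignore_index=True).to_csv(paths["thickness"], index=False)
        pd.concat(cam_rows, ignore_index=True).to_csv(paths["diameter"], index=False)
        pd.DataFrame(timeline_rows).to_csv(paths["timeline"], index=False)
        pd.DataFrame(phase_rows).to_csv(paths["phases"], index=False)
        corr.to_csv(paths["correlation"], index=False)
        _plot_boxes(oct_analyses, outdir / "thickness_boxplot.png")
        _plot_timecourse((wt, mean_weight), (cohort[0].times_h, mean_thick),
                         (cohort[0].times_h, mean_diam), outdir / "timecourse.png")
        _plot_indicator_bars(timelines, phantom.duration_h, outdir / "indicators.png")
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}

    manifest["correlation"] = corr.to_dict(orient="records")
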