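"""Detect the four germination indicators on a simulated 40-h record.

A coarsened (30-min cadence) default phantom is monitored end to end: the
camera stream yields the surface-wrinkle onset, the flank depth profiles the
cotyledon-layer onset, the central averaged profile the radicle emergence,
and the per-frame surface picks the coat crack.  The radicle and crack
onsets segment the record into the three germination phases.
"""

from dataclasses import replace

from seedoct.indicators import IndicatorTimeline, classify_phases
from seedoct.phantom import PhantomConfig, simulate_timecourse
from seedoct.pipeline import analyze_camera_timecourse, analyze_oct_timecourse

config = replace(PhantomConfig(seed_rng=7), cadence_min=30.0)
tc = simulate_timecourse(config, n_weight_seeds=1)
oct_a = analyze_oct_timecourse(tc)
cam_a = analyze_camera_timecourse(tc)

events = config.events
print(f"{'indicator':<12}{'true (h)':>10}{'detected (h)':>14}")
for name, det, truth in (("wrinkle", cam_a.wrinkle, events.wrinkle_h),
                         ("cotyledon", oct_a.cotyledon, events.cotyledon_h),
                         ("radicle", oct_a.radicle, events.radicle_h),
                         ("crack", oct_a.crack, events.crack_h)):
    shown = "none" if det is None else f"{det.onset_h:.2f}"
    print(f"{name:<12}{truth:>10.2f}{shown:>14}")

timeline = IndicatorTimeline(wrinkle=cam_a.wrinkle, cotyledon=oct_a.cotyledon,
                             radicle=oct_a.radicle, crack=oct_a.crack)
seg = classify_phases(timeline, config.duration_h)
print(f"phase I  (imbibition): {seg.phase_1[0]:.2f} - {seg.phase_1[1]:.2f} h")
print(f"phase II (lag):        {seg.phase_2[0]:.2f} - {seg.phase_2[1]:.2f} h")
print(f"phase III (completion): {seg.phase_3[0]:.2f} - {seg.phase_3[1]:.2f} h")
print("Detected onsets land on the first acquisition at or after each true event.")
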