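"""Simulate one B-scan of a germinating pea seed and measure its coat thickness.

Renders a speckled cross-section at 12 h after soaking, picks 60 boundary
points on the testa surface and the coat/cotyledon interface, fits both with
shape-preserving cubics, and reports the physical thickness after dividing
the optical separation by the coat refractive index (1.42).
"""

import numpy as np

from seedoct.phantom import PhantomConfig, render_bscan
from seedoct.thickness import measure_bscan_thickness

config = PhantomConfig(seed_rng=1)
bscan = render_bscan(config, t_h=12.0, rng=1)
profile, summary, picks = measure_bscan_thickness(bscan, n_points=60, coat_ri=1.42)

true_mean = float(config.thickness_curve()(12.0))
print(f"B-scan: {bscan.n_depth} x {bscan.n_lateral} px, "
      f"{bscan.lateral_extent_mm:g} x {bscan.depth_extent_mm:g} mm at t = 12 h")
print(f"valid boundary-point pairs: {int(picks.valid.sum())} / {len(picks.x_mm)}")
print(f"recovered coat thickness: {summary.mean_um:.1f} +/- {summary.sd_um:.1f} um "
      f"(median {summary.median_um:.1f}, IQR {summary.q1_um:.1f}-{summary.q3_um:.1f})")
print(f"simulated true mean:      {true_mean:.1f} um")
print("The recovered mean should sit within a few microns of the simulated truth;")
print("the spread reflects the lateral coat unevenness plus speckle jitter.")
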