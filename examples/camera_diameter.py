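"""Segment a camera photo of the seed and measure its diameter.

Applies the four-step boundary recognition (inclusive RGB thresholds
62/45/30 to 255, AND-combined; water-shadow exclusion; Canny edges; overlay)
and reports the equivalent-circle diameter and boundary roughness.
"""

from seedoct.morphometry import (canny_boundary, measure_diameter,
                                 outline_from_image, overlay_boundary,
                                 segment_seed)
from seedoct.phantom import PhantomConfig, render_camera_image

config = PhantomConfig(seed_rng=3)
image = render_camera_image(config, t_h=10.0, rng=3)

mask = segment_seed(image)
edges = canny_boundary(mask.astype(float))
annotated = overlay_boundary(image, edges, color=(0, 0, 255))
outline = outline_from_image(image)

print(f"image: {image.pixels.shape[1]} x {image.pixels.shape[0]} px, "
      f"{image.pixel_scale_mm * 1e3:.1f} um/px")
print(f"seed mask area: {mask.sum()} px; boundary pixels: {int(edges.sum())}")
print(f"equivalent-circle diameter: {measure_diameter(outline):.2f} mm "
      f"(simulated truth {config.camera.diameter_mm(10.0):.2f} mm)")
print(f"boundary roughness: {outline.roughness:.4f} "
      "(sd of radial residuals / radius; wrinkles push this above ~0.01)")
print("The blue overlay marks the recognized boundary on a copy of the photo.")
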