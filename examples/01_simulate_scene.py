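"""Generate one synthetic STED-like scene and inspect its ground truth.

The structure channel carries transverse periodic stripes (F-actin rings,
180-190 nm spacing) along part of each neurite, longitudinal lines
(fibers) along another part, and diffuse speckle elsewhere; two
diffraction-limited marker channels flag dendrite-like and axon-like
processes.
"""

import matplotlib

matplotlib.use("Agg")

import numpy as np

import actinseg as a

spec = a.SceneSpec(image_shape=(512, 512), seed=7, ring_fraction=0.5,
                   fiber_fraction=0.3)
image, truth = a.generate_scene(spec)

union = truth.union_mask()
print(f"scene {spec.image_shape} at {spec.pixel_size_nm} nm/px, "
      f"{len(truth.centerlines)} processes")
print(f"process area: {union.sum()} px "
      f"({union.mean() * 100:.1f}% of the field)")
for cls, cmap in truth.class_maps.items():
    print(f"  {cls}: {cmap.sum()} px = {cmap.sum() / union.sum():.2f} "
          "of the process area")
for cl in truth.centerlines:
    print(f"  centerline ({cl.role}): {cl.length_px * spec.pixel_size_nm / 1000:.1f} um, "
          f"width {cl.width_px * spec.pixel_size_nm:.0f} nm, "
          f"ring period {cl.ring_period_px * spec.pixel_size_nm:.0f} nm")

# weak labels: the coarse polygonal boxes an expert would draw
ann = a.weak_labels_from_truth(truth, style="polygon_box", margin_nm=60,
                               jitter_nm=40, seed=1)
print(f"weak labels: {ann.n_instances('rings')} ring boxes, "
      f"{ann.n_instances('fibers')} fiber boxes")
# The box area always exceeds the precise pattern area: that surplus is
# exactly the label coarseness the segmentation network must overcome.
maps = a.rasterize(ann, spec.image_shape)
for cls in ("rings", "fibers"):
    precise = truth.class_maps[cls].sum()
    if precise:
        print(f"  {cls} boxes cover {maps[cls].sum() / precise:.2f}x "
              "the precise area")
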