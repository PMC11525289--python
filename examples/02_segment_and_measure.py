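"""Segment a scene and measure every detected particle.

Chains the pipeline: contrast enhancement -> random-forest pixel
classification (trained from sparse labels sampled off the ground truth)
-> IsoData binarization -> adjustable watershed (tolerance 3) -> per-
particle morphometry, then applies the operational [35, 2000) µm mFD
window.
"""

import numpy as np

from twpscope import (
    SceneSpec, generate_scene, enhance, labels_from_truth, extract_features,
    train_classifier, classify, binarize, adjustable_watershed,
    label_components, measure_particles, filter_particles,
)

spec = SceneSpec(
    width_px=620, height_px=620, halo_width_um=(3.0, 5.0),
    n_random=8, size_range_um=(20.0, 150.0), rng_seed=7,
)
image, truth = generate_scene(spec)

enhanced = enhance(image, exposure_gain=1.5, black_level=30)
labels = labels_from_truth(enhanced, truth, seed=0)
feats, names = extract_features(enhanced)
model = train_classifier(feats, labels, seed=0, feature_names=names)
print(f"forest trained on {len(labels.coords)} labelled pixels, "
      f"out-of-bag accuracy {model.oob_accuracy:.3f}")

mask = binarize(classify(enhanced, model))
split = adjustable_watershed(mask, tolerance=3.0)
table = measure_particles(label_components(split), spec.pixel_size_um)
windowed = filter_particles(table, 35.0, 2000.0)

print(f"\ndetected {len(table)} particles, {len(windowed)} inside [35, 2000) µm mFD:")
df = windowed.to_dataframe()
print(df[["id", "mfd_um", "fd_um", "area_um2", "circularity"]].round(2))
true_n = sum(p.true_mfd_um >= 35 for p in truth.particles)
print(f"\nground truth holds {true_n} particles with true mFD >= 35 µm; the "
      "measured mFD runs\na few µm below truth because the chromatic rim is "
      "not black and is not detected.")
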