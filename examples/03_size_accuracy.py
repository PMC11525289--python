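"""Size-measurement accuracy vs true particle size, with breakpoint fit.

Runs the full pipeline on seeded scenes of particles spanning 10-200 µm,
matches detections to ground truth, and summarises accuracy
(100 x measured mFD / true mFD). The two-segment fit locates where the
accuracy stops degrading; the recovery curve feeds the 80% size-limit
rule.
"""

import numpy as np

from twpscope import (
    recovery_curve, select_size_limit, size_accuracy_experiment,
    detection_experiment,
)

res = size_accuracy_experiment(seed=1, n_particles=120, classifier="forest")
print(f"{res.n_detected_matched} of {res.n_true} particles detected and matched")
print(f"mean accuracy, true mFD >= 25 µm: {res.mean_accuracy(25.0):.1f} %")
print(f"mean accuracy, true mFD <  20 µm: {res.mean_accuracy_below(20.0):.1f} %")
if res.fit is not None and res.fit.converged:
    print(f"breakpoint fit: accuracy stabilises near "
          f"{res.fit.plateau_pct:.0f} % above ~{res.fit.breakpoint_um:.0f} µm")

det = detection_experiment(
    seed=2, n_scenes=3, size_range_um=(10.0, 200.0), classifier="forest"
)
curve = recovery_curve(
    det.true_mfds_by_scene, det.detected_mfds_by_scene,
    np.array([10.0, 15, 20, 25, 30, 35, 40, 45, 50]),
)
print("\nrecovery (% of true particles >= threshold that were detected):")
for t, m, sd in zip(curve.thresholds_um, curve.mean_pct, curve.sd_pct):
    print(f"  >= {t:4.0f} µm : {m:6.1f} % (sd {sd:.1f})")
limit = select_size_limit(curve, min_recovery_pct=80.0)
print(f"smallest threshold with mean recovery >= 80 %: {limit} µm")
print("\nAccuracy collapses below ~20 µm because the chromatic rim removes "
      "the black core\nthat the classifier detects; above the breakpoint the "
      "loss is a fixed few µm and\nbecomes negligible relative to size. "
      "Recovery stays high at every threshold here\nbecause only optical "
      "losses are simulated: with physical extraction losses the\ncurve "
      "crosses 80 % at a nonzero size and the rule returns that threshold.")
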