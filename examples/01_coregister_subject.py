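"""Co-register one synthetic subject and compare with its ground truth.

Generates a synthetic head (scalp mesh + digitized headshape with 1.5 mm
digitizer noise and a few stray points), runs the automated pipeline
(landmark fit -> ICP -> 5 mm outlier rejection -> ICP), and prints the
co-registration error alongside the recovered vs. true transform
parameters.  The median error is the metric a MEG lab would report: the
median distance from each digitized point to the MRI scalp surface.
"""

import numpy as np

from coregkit import (auto_coregister, decompose, generate_head_surface,
                      generate_headshape, sample_ground_truth_transform)
from coregkit.synthetic_data import SubjectSpec

rng = np.random.default_rng(7)
ground_truth = sample_ground_truth_transform(rng)
spec = SubjectSpec(seed=7, ground_truth=ground_truth)
surface = generate_head_surface(spec)
headshape = generate_headshape(surface, spec)

# template-transferred fiducial estimates: true landmarks + 5 mm jitter
fid = surface.fiducials
estimates = {k: fid[k] + rng.normal(0, spec.template_jitter_sd, 3)
             for k in fid}

result = auto_coregister(headshape, surface, estimates)

print(f"headshape points: {headshape.n}")
print(f"median error: {result.median_error:.3f} mm "
      f"(IQR {result.iqr_low:.3f}-{result.iqr_high:.3f})")
print(f"outliers removed at 5 mm: {len(result.outlier_indices)}")
print(f"quality flag (> 2 mm): {result.quality_flag}")

got = decompose(result.transform)
true = decompose(ground_truth)
print("\nparameter        recovered     true")
for name in ("tx", "ty", "tz", "pitch", "roll", "yaw"):
    unit = "mm " if name.startswith("t") else "deg"
    print(f"{name:>6} [{unit}]   {getattr(got, name):9.3f} "
          f"{getattr(true, name):9.3f}")
# With ~1.5 mm noise the error settles near 1 mm (the half-normal median
# of the noise) and the pose is recovered to a fraction of a mm/degree.
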