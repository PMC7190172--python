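"""Inter-method reliability: simulated manual vs automated co-registration.

Generates a small cohort, co-registers each subject automatically, scores
each subject's simulated-manual transform, and prints the comparison:
per-method medians, the ICC(3,1) for the error and for each decomposed
transform parameter, and the error correlation with its Cohen's d.
An ICC above 0.75 is "excellent" agreement on Cicchetti's bands.
"""

import numpy as np

from coregkit import (auto_coregister, compare_methods, evaluate_transform,
                      generate_cohort)
from coregkit.synthetic_data import CohortConfig

cohort = generate_cohort(10, master_seed=7,
                         config=CohortConfig(mesh_subdivisions=3))
automated = [auto_coregister(s.headshape, s.surface, s.fiducial_estimates)
             for s in cohort.subjects]
manual = [evaluate_transform(s.headshape, s.surface, s.manual_transform)
          for s in cohort.subjects]

report = compare_methods(manual, automated,
                         headshape_counts=[s.headshape.n
                                           for s in cohort.subjects])

print(f"n = {report.n_subjects} subjects")
print(f"{'measure':>8} {'manual med':>11} {'auto med':>9} "
      f"{'ICC':>7}  band")
for name, m in report.measures.items():
    print(f"{name:>8} {m.median_a:11.3f} {m.median_b:9.3f} "
          f"{m.icc:7.3f}  {m.icc_band}")
print(f"\nerror correlation r = {report.error_pearson_r:.3f} "
      f"(Cohen's d = {report.error_cohens_d:.2f})")
print(f"subjects excluded at > {report.quality_threshold:g} mm: "
      f"{report.n_excluded}")
# Translation/rotation ICCs are near 1 because between-subject transform
# spread (5 mm / 5 deg) dwarfs the ~1 mm method disagreement; the error
# ICC is lower since per-subject errors differ only through noise.
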