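# coregkit

Automated MEG–MRI co-registration and inter-method reliability analysis,
with a synthetic head-cohort generator for validating the whole workflow
against known ground truth.

## The problem

Interpreting MEG source estimates requires aligning the participant's
anatomical MRI with the MEG head coordinate frame. The alignment is a
rigid-body transform **T** (4×4, rotation **R** with det **R** = +1 plus
translation **t** in mm) mapping MRI coordinates into head coordinates.
It is estimated from the digitized anatomical landmarks (nasion, left and
right preauricular points) and ~100–200 digitized headshape points, fit
against the scalp surface extracted from the MRI. Co-registration quality
is summarized by the **co-registration error**: the median Euclidean
distance from each digitized headshape point to the *nearest point on the
scalp surface* (triangle interiors and edges included, not just vertices)
under the fitted transform; errors beyond ≈2 mm are considered poor
enough to distort source localization.

`coregkit` implements:

- the standard **automated pipeline**: template-landmark transfer → rigid
  landmark fit (SVD orthogonal Procrustes) → iterative closest points
  (ICP) against the scalp mesh → removal of headshape points > 5 mm from
  the surface → final ICP on the retained points;
- **evaluation of externally supplied transforms** (e.g. from a manual
  operator) with the same error metric;
- **inter-method reliability statistics**: the two-way mixed, consistency,
  single-measure intra-class correlation
  ICC(3,1) = (MS_B − MS_E) / (MS_B + (k−1) MS_E),
  Pearson *r* with the Cohen's *d* conversion d = 2r/√(1−r²), Cicchetti
  qualitative bands, and the >2 mm exclusion sensitivity rerun — applied
  to errors and to the six decomposed transform parameters (translations
  x/y/z in mm; pitch/roll/yaw in degrees, extrinsic x-y-z convention,
  R = Rz(yaw)·Ry(roll)·Rx(pitch));
- **geometric de-facing** of scalp surfaces (privacy emulation) to study
  its effect on automated co-registration;
- a **synthetic cohort generator**: ellipsoid-based head surfaces with
  nose/brow/occiput features, Polhemus-style digitization with
  configurable noise and stray points, ground-truth and
  simulated-manual transforms.

## Worked example

```sh
python examples/01_coregister_subject.py
```

```
headshape points: 143
median error: 0.982 mm (IQR 0.470-1.622)
outliers removed at 5 mm: 7
quality flag (> 2 mm): False

parameter        recovered     true
    tx [mm ]      -2.278    -1.994
    ty [mm ]      -3.566    -3.506
    tz [mm ]     -71.794   -71.371
 pitch [deg]      10.094     9.547
  roll [deg]      -0.847    -1.273
   yaw [deg]      -5.331    -5.458
```

One synthetic subject was digitized with 143 headshape points under
1.5 mm digitizer noise; the automated pipeline recovered the true
MRI→head transform to a fraction of a millimetre/degree, and the
resulting 0.98 mm median error sits well inside the 2 mm quality
heuristic (roughly the half-normal median of the digitizer noise). Seven
stray points beyond 5 mm were rejected during fitting but still counted
in the error metric.

`examples/02_method_reliability.py` runs the manual-vs-automated
comparison on a small cohort (ICC per measure, error correlation);
`examples/03_defacing_effect.py` shows the paired intact-vs-defaced
error increase.

The same stages are available as a CLI for scripted use:

```sh
coregkit simulate --n 30 --seed 7 --out cohort/
coregkit coregister --surface cohort/sub-00/surface.ply \
    --fiducials cohort/sub-00/template_fiducials.json \
    --headshape cohort/sub-00/headshape.txt --out auto/sub-00.json
coregkit evaluate --surface cohort/sub-00/surface.ply \
    --headshape cohort/sub-00/headshape.txt \
    --trans cohort/sub-00/manual_trans.txt --out manual/sub-00.json
coregkit compare --results-a manual/ --results-b auto/ \
    --out report.json --csv report.csv
```

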