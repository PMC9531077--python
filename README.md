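# bonessm

Statistical shape modeling and morphometry of the distal humerus.

Elbow hemiarthroplasty replaces the articular surface of the distal humerus
with an implant; when the implant's geometry deviates from the native
trochlea and capitellum, the opposing cartilage wears.  Designing better
implants requires knowing not just mean dimensions but how the articular
*shape* varies across a population.  `bonessm` provides the complete
analysis chain for that question: it builds dense correspondence between
bone surface meshes, fits a PCA statistical shape model (SSM), evaluates it
(compactness, leave-one-out generalization, specificity), measures each
shape in an anatomical coordinate frame (13 standard parameters: widths,
ratios, angles and section radii along the flexion-extension axis), and
quantifies how much each mode of variation deforms the articular surface
proper, once pose is removed by landmark registration.

Because CT cohorts are rarely shareable, the package ships a synthetic
phantom generator: a watertight distal-humerus-like solid with analytically
known landmarks, articular labels, flexion-extension axis and measurement
values, deformed along smooth orthogonal latent modes (size-dominant, as in
real cohorts).  Every stage of the pipeline can therefore be validated
against exact ground truth.  It is aimed at researchers in skeletal
morphometry and implant design who want a transparent, fully testable
reference implementation.

## The model

With n bones in dense correspondence (V shared vertices), each shape is a
vector x in R^{3V} and the SSM is the point-distribution model

    x = mu + sum_k b_k phi_k,   b_k ~ N(0, lambda_k),

where mu is the mean shape and (phi_k, lambda_k) come from the
eigendecomposition of the sample covariance (thin SVD, divisor n-1).
Shapes are rigidly aligned but *not* size-normalized, so PC1 captures
overall size.  Mode instances mu ± 3 sqrt(lambda_k) phi_k visualize each
mode; their articular patches, registered rigidly (no scaling) onto the
mean model via five articular landmarks, give the point-to-mesh distance
summaries that identify which modes change the articulation itself.

## Worked example

```python
import numpy as np
from bonessm import (
    PhantomSpec, PopulationModel, make_template, sample_population,
    correspondence_from_population, StatisticalShapeModel,
)
from bonessm.articular import mode_difference_report

template = make_template(PhantomSpec(mesh_resolution=2000))
model = PopulationModel(template)          # size >> rotation > width > epicondyle
bundles = sample_population(model, 20, seed=42)
cs = correspondence_from_population(bundles, template)   # exact ground truth
results = StatisticalShapeModel.from_correspondence(cs).fit()
print(results.summary())
print(mode_difference_report(results, k_max=3).to_string())
```

prints

```
Statistical shape model (PCA)
==============================================
training shapes : 20
vertices        : 2056
modes retained  : 19
total variance  : 10923.9153 mm^2
----------------------------------------------
mode     variance   percent   cumul %
   1    7278.6398     66.63     66.63
   2    1840.9692     16.85     83.48
   3    1141.3305     10.45     93.93
   4     613.7234      5.62     99.55
   5       3.5699      0.03     99.58
  ...
          Range (mm)  Median (mm)  Mean (mm)  Std Deviation (mm)  RMS (mm)
model
PC1 + 3SD   0 - 3.65         0.85       1.06                0.91      1.39
PC1 - 3SD   0 - 3.77         1.25       1.45                1.09      1.81
PC2 + 3SD   0 - 3.04         0.51       0.73                0.64      0.97
PC2 - 3SD   0 - 2.63         0.68       0.89                0.72      1.14
PC3 + 3SD   0 - 2.80         0.70       0.85                0.62      1.06
PC3 - 3SD   0 - 3.14         0.78       0.96                0.70      1.19
```

Reading this: the four designed latent modes are recovered with a
size-dominant variance profile (these are the sampled cohort's realized
shares; the remaining modes carry only the 0.1 mm measurement noise), and
the articular difference analysis shows the size mode (PC1) deforming the
articular surface most at ±3 SD even after pose is removed by landmark
registration — the structure that implant-design studies report.  On a
population whose *only* mode is scaling, the PC1 articular RMS exceeds all
other modes' several-fold (that sharper experiment is part of the test
suite and the acceptance script).

The full study — mirroring right-sided bones, clipping 50 mm above the
olecranon fossa, non-rigid template morphing instead of ground-truth
correspondence, quality curves, and the 13-parameter measurement table for
the mean and every ±3 SD mode — runs from a config file:

```bash
bonessm run --config config.yaml      # or: python -m bonessm.cli ...
bonessm phantom --n 40 --seed 7 --out phantoms/
```

See `docs/methods.md` for the models, numerical choices and limitations.

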