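# Methods

`bonessm` implements a complete statistical shape analysis of the distal
humerus at desk scale: synthetic bone phantoms in, anatomical measurement
tables, shape-model quality curves and articular surface-difference reports
out.  This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The statistical shape model

Given n bones expressed on a shared template topology (V vertices in
one-to-one correspondence), each shape is a vector x_i in R^{3V}.  The model
is the standard point-distribution model:

    x  =  mu + sum_k b_k phi_k ,     b_k ~ N(0, lambda_k)

with mu the arithmetic mean shape and (phi_k, lambda_k) the eigenvectors and
eigenvalues of the sample covariance (divisor n-1), computed via the thin SVD
of the centered data matrix.  No size normalization is applied before the
PCA — shapes are rigidly aligned only — so the first mode captures overall
size, the dominant variation in long-bone cohorts.  Mode instances
`mu ± c sqrt(lambda_k) phi_k` (default c = 3) visualize each mode at the
edge of its plausible range.

Numerical conventions: eigenvalues below 1e-12 of the leading one are
truncated; each mode's sign is fixed so its largest-magnitude entry is
positive (PCA signs are otherwise arbitrary and determinism is required);
mode indices are 1-based ("PC1").

Model quality follows the standard triple:

- **compactness** C(m) = cumulative variance fraction of the first m modes;
- **generalization**: leave-one-out — refit on n-1 shapes, project the
  held-out shape on the first m modes, reconstruct, and average the mean
  per-vertex Euclidean error over folds;
- **specificity**: draw M instances (scores sampled per mode from
  N(0, lambda_k) truncated at ±3 SD, M = 1000 by default, seed mandatory)
  and average each instance's distance to its most similar training shape.

Because all shapes share the template topology, both error metrics use the
vertex-to-vertex correspondence distance; this choice (not dictated by the
metric definitions themselves) is noted here because point-to-surface
variants give systematically smaller numbers.

Rater reliability of manual steps is quantified with ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
two-way ANOVA mean squares.  The published reliability study did not name
its ICC variant; ICC(2,1) is the most conservative common choice.

## Correspondence

Templates are wrapped onto targets in two stages.

1. **Rigid**: landmark Procrustes (Kabsch, reflections excluded by
   construction) when landmarks exist, otherwise centroid-initialized rigid
   ICP with pair rejection beyond 25 mm.
2. **Non-rigid**: stiffness-scheduled locally-affine non-rigid ICP.  Every
   template vertex carries a 4x3 affine transform; the energy is the
   weighted sum of squared closest-point distances plus alpha^2 times the
   squared differences of neighboring transforms (gamma = 1), solved as a
   sparse linear system per iteration, with the stiffness schedule
   alpha = 50, 20, 5, 2.  Correspondences are rejected beyond 10 mm or 60
   degrees of normal incompatibility, which keeps the olecranon-fossa rim
   from snapping across the fossa.

Three details matter in practice and were the result of genuine design
iteration:

- **Tangential release.** The closest-point data term constrains only the
  normal direction reliably; its tangential component is an arbitrary
  artifact of where the closest point happens to fall.  90 % of the
  tangential pull is released each iteration, so the stiffness term — not
  closest-point geometry — decides where vertices sit on the surface.
- **Landmark-only initialization.** At high stiffness the minimizer of the
  landmark+stiffness energy is the smoothest (for consistent landmarks:
  globally affine) field through the landmark constraints.  Solving this
  before trusting surface data registers the gross deformation first.  Weak
  stay-put anchors (weight 0.005) on all vertices bound the deformation
  gradients a small, nearly coplanar landmark set cannot observe.  Landmarks
  on locally variable features (the epicondylar prominences) are excluded
  from the initialization via `init_landmark_pairs` and handled by the data
  phase, because a small landmark set fits their local displacement with a
  spurious global gradient.
- **Offset-corrected landmark constraints.** The constrained template
  *vertex* sits up to an edge length from the landmark *point*; that offset
  is carried to the target side scaled by the landmark-estimated size ratio.
  Without the scaling, a ±20 % size change injects ~0.2 mm of mutual
  landmark inconsistency and visibly contaminates the first mode.

Registration landmarks are the five articular points (medial trochlear
ridge, trochlear groove, lateral trochlear ridge, trochlea–capitellum
groove, capitellum apex — chosen as a well-spread set on the articulation),
the two epicondylar prominences, and the olecranon-fossa apex.  The fossa
apex is the one well-defined posterior/proximal point and is what makes
out-of-articular-plane deformation observable to the registration.

## Anatomical frame and measurements

The flexion–extension axis ("C line") is the axis of a least-squares
cylinder through the articular surface: minimize sum (d_i - r)^2 over axis
point, direction and radius, initialized from the principal directions of
the patch (all three are tried; the best residual wins, since for an
elongated articular patch the revolution axis is the *largest*-variance
direction).  The measurement frame is x along the transepicondylar line
(medial to lateral), y the shaft direction orthogonalized against x
(proximal), z = x × y (anterior); the origin is the TEL point in the
sagittal plane through the trochlear groove center.  The shaft direction is
a line fitted through cross-section band centroids of the proximal shaft
(everything more than 25 mm above the articular centroid — above the fossa,
with enough length for a stable axis); band centroids are insensitive to the
ridge asymmetry of the cross-section, which would bias a raw inertia axis.

The thirteen parameters: Wtel = epicondyle-to-epicondyle distance;
Wcline/Wtro/Wcap and the component widths MT/LT are extents along the C
line between articular stations; RT = MT/LT, RTC = Wtro/Wcap (always the
exact quotient of their stored components); ATC = acute 3-D angle of TEL
vs C line; Agro = acute angle of origin-to-groove-center vs y, measured
after projecting into the sagittal plane; R1–R5 are circle-fit radii of
sections perpendicular to the C line at the five stations (R5 the largest
capitellar sagittal radius); R6 the largest circle-fit radius of the
anterior capitellum outline on transverse sections.

Stations are located as the alternating extremum pattern
(max/min/max/min/max) of the circle-fit radius profile along the axis,
then refined by fine re-sectioning and a least-squares parabola.  All
section spacings are proportional to the articular extent (coarse step =
extent/84, about 0.5 mm on an adult bone), which makes the whole
measurement scale-equivariant — ratios are then exactly scale-invariant, a
property the pipeline tests exploit.  Circle fits are Pratt's algebraic fit
(the eigenvector of the smallest nonnegative generalized eigenvalue — an
exact fit has eigenvalue zero) refined geometrically.

Landmark detection is a two-pass prominence search: the articular cylinder
axis gives the medio-lateral direction (the medial end is recognized as the
larger-radius end); epicondyles are quadratic-cap apexes of the extreme
band along that direction — *not* along the TEL, which is defined by those
very points and would bias them; groove/capitellum centers come from the
refined radius profile.  Pass 2 repeats the search with the prominence
direction re-orthogonalized against the refined shaft direction and is a
fixed point thereafter.

**Determinism.** Identical inputs must produce byte-identical reports.  Two
measures guarantee this: linear-algebra thread pools are pinned to one
thread for the duration of a pipeline run, and both geometric fits finish
with a deterministic analytic Gauss–Newton polish after the
Levenberg–Marquardt stage, because the LM stop point inside the flat
convergence basin is not bit-reproducible across calls (the cylinder's
translation-along-axis gauge direction is fixed with a full-weight gauge
residual for the same reason).

## Articular surface differences

The articular patch (faces whose three vertices carry the "articular"
label) of each synthesized mode instance is rigidly registered onto the
mean-model patch using the five articular landmarks, tracked through the
correspondence as template vertex indices.  Registration is rigid *without
scaling* — pose is removed, size is not — which is precisely what lets a
pure size mode show up as a large residual.  Distances are one-directional
and unsigned: every mean-patch vertex to its closest point on the
registered instance surface, summarized as range/median/mean/SD (n-1
divisor)/RMS.

## The phantom population

CT cohorts of distal humeri are generally not shareable, so the pipeline is
exercised end-to-end on a synthetic population with exact ground truth.

The template is the zero level set of an implicit solid, surfaced by
marching cubes (pitch chosen in two passes to hit a target vertex count;
9,000 vertices by default, 2,000 for population runs):

- an articular **solid of revolution** about the designed flexion-extension
  axis whose sagittal radius profile is a cubic Hermite spline passing
  *exactly* (with zero slope, hence a local extremum) through the five
  station radii, with a circular-arc capitellum cap whose transverse
  curvature radius realizes the designed R6;
- an **elliptical shaft** (13.5 x 11.5 mm semi-axes, posteriorly offset so
  the articulation sits anteriorly) with medial and lateral supracondylar
  **ridges** — real shafts are not bodies of revolution, and without these
  features azimuthal surface correspondence is fundamentally unidentifiable;
- two **epicondylar ellipsoid bosses** whose apexes realize the designed
  epicondylar width exactly, placed to give the designed TEL-vs-axis angle
  (4.8 degrees);
- a subtracted ball forming the **olecranon fossa**, whose rim apex anchors
  the 50 mm clipping plane.

Default dimensions follow the published mean-model morphometry of an adult
cohort (Wtel 57.4, Wcline 42.1, Wtro 19.2, Wcap 15.2 mm; radii
11.4/8.5/9.2/8.6/9.9/12.2 mm).  Landmarks are placed analytically and
snapped to the surface; surface landmarks are stored barycentrically so
they ride exactly on the deformed surface of every phantom.

The population model deforms the template along smooth latent modes —
uniform scaling about the articular centroid, linearized axial rotation,
a medio-lateral/antero-posterior trade-off, and a local epicondyle-size
change (Gaussian weight, sigma 6 mm) — orthonormalized as vertex
displacement fields (unit RMS displacement per vertex).  Default mode SDs
are 2.3/1.2/1.0/0.85 mm, i.e. variance ratios ~44:12:8:6 mirroring a
size-dominant cohort; at ±3 SD the size mode spans roughly ±23 % of
epicondylar width, matching the published PC1 range.  Isotropic per-vertex
Gaussian noise (SD 0.1 mm, the order of segmentation error at 0.625 mm CT
slices) emulates measurement error; about half the phantoms are generated
right-sided as exact mirror images.  Coefficients are drawn from seeded
zero-mean normals; `exact_variance=True` additionally rescales the draws so
the *sample* covariance equals the design exactly (the
`mvrnorm(empirical=TRUE)` construction) — parameter-recovery experiments
use it because at n = 40 the raw sample shares of a 70/20/10 design
fluctuate with an SD near 6 percentage points, which would otherwise test
the sampler rather than the model.

**What the phantoms do not emulate.**  No scanner pose variation (bones are
generated in a canonical pose; rigid-registration robustness is tested with
explicit random motions instead), no segmentation topology errors, no
cortical interior, no cartilage, and only four latent modes rather than the
dozens of a real cohort.  Passing tests therefore demonstrate correctness
of the machinery and recoverability of known structure — not anatomical
fidelity of any particular measurement value.

## Pipeline and problem sizes

The end-to-end study (`run_pipeline`) samples the population, mirrors
right-sided bones, clips every bone 50 mm proximal to its own fossa apex
(so cut boundaries correspond anatomically and the template rim maps
rim-to-rim), builds correspondence, fits the model, computes quality
curves, measures the mean and every reported mode instance (reported =
all modes explaining at least 3 % of variance, overridable), and writes
the articular difference report.  Desk-scale defaults — 40 phantoms at
~2,000 vertices, 4 inner morph iterations per stiffness level, 500
specificity samples, quality curves up to ~6 modes — complete a run in a
few minutes on one CPU; all are configurable upward.

## Known limitations

- Non-rigid correspondence error grows with deformation amplitude: about
  0.3–0.5 mm mean per-vertex error for typical phantoms, 1–3 mm for extreme
  (|c| > 4 SD-equivalent) size coefficients, concentrated on the featureless
  shaft.  Minor fitted modes of a morph-based model are accordingly
  contaminated relative to ground-truth correspondence; the articular
  region, which carries landmarks and curvature, is several times more
  accurate than the shaft.
- Width measurements carry an O(mesh pitch) discretization bias on steep
  profile flanks (about -0.7 mm on Wtro at a 1 mm pitch); station radii are
  accurate to well under 1 %.
- Agro is intrinsically ill-conditioned: the origin-to-groove-center lever
  is only a few millimetres, so sub-millimetre landmark differences move it
  by degrees.
- The azimuthal position of correspondences on near-revolution surfaces is
  only weakly observable even with shaft ridges; it is pinned by landmarks
  and smoothness, not by data.
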