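# Methods

`qctfe` re-creates, end to end and on synthetic data, a computational
experiment in quantitative-CT (QCT) based vertebral biomechanics: how far
can the CT radiation dose be reduced — by lowering tube current or by
acquiring fewer projection angles — before finite-element (FE) predicted
vertebral failure load stops agreeing with the full-dose prediction?  The
package is a pipeline of seven stages; each is described below with its
model, assumptions, defaults and known limitations.

## Synthetic vertebra phantoms (`qctfe.phantom`)

A subject is an elliptical-cylinder vertebral body (default half-axes
16 × 12 mm, height 24 mm at desk scale) with a cortical shell and a
heterogeneous trabecular interior, embedded in uniform soft tissue
(40 HU), with a two-rod calibration insert (0 and 200 mg/cc equivalent
density, 5 mm radius) beneath the body, the way a QCT reference phantom
lies under the scanner mat.  Rod HU equals equivalent density, so the
ground-truth calibration line is the identity and a subject's target
trabecular BMD maps directly onto mean trabecular HU.

* **Trabecular heterogeneity** is a stationary Gaussian random field
  (Gaussian correlation kernel, 3 mm correlation length, 30 HU standard
  deviation) — a texture model, not a micro-architecture model.  Identical
  spec + seed is bit-identical by construction.
* **Cortical shell**: 2 mm at 300 HU.  This deliberately reflects what a
  thin (sub-millimeter) dense shell looks like *in a clinical-resolution
  CT image* after partial-volume averaging, not the true tissue density of
  cortical bone; with the literature density–modulus mapping it keeps the
  shell's share of the failure load realistic (roughly half) and the
  failure loads in the clinical few-kN range.
* **Cohorts**: per-subject target BMD ~ Normal(89.3, 14.55) mg/cc — an
  elderly, largely osteopenic population; body axes, height and shell
  thickness get mild multiplicative jitter, and the shell HU scales with
  the subject's BMD ratio (cortical and trabecular density co-vary in
  vivo).
* Not emulated: posterior elements, endplate curvature, bone marrow
  composition, patient positioning, beam hardening.  Passing tests on
  these phantoms demonstrate the *pipeline's* dose-response behaviour,
  not segmentation or FE accuracy on real anatomy.

## CT simulation and dose reduction (`qctfe.projsim`)

A 2-D parallel-beam, slice-wise geometry replaces the clinical helical
cone-beam scanner: the study's question concerns dose-versus-strength
fidelity, not scanner geometry, and a small invertible operator makes
every downstream stage testable.  The projector is an explicit sparse
matrix (pixel-driven, linear detector splatting), so forward and
backprojection are exact transposes — the property the iterative
reconstruction's convergence analysis assumes.  The module-level defaults
(360 views over 180°, 10⁵ photons/ray, electronic noise SD 10 counts,
unit gain) describe a generic acquisition.

Tube-current reduction draws detector counts as

    N = Poisson(d · I0 · exp(-p)) · g + Normal(0, sigma_e),

i.e. quantum noise scaled by the dose fraction `d` plus detector-gain-aware
electronic read-out noise; sparse sampling keeps every k-th view of
full-current data and removes the rest.  The log transform floors counts
(default 1 count) so photon starvation cannot produce infinite line
integrals, and carries inverse-variance ray weights `w = max(N, floor)/g`.

**Experiment-level noise parameters.**  The desk phantom (60 mm across) is
far less attenuating than an abdomen, so at the generic 10⁵ photons/ray
even a 90 % dose cut leaves every ray quantum-rich and the dose series
barely degrades.  The experiment configuration therefore matches the
*detector exit counts* of a clinical lumbar acquisition instead: 5 000
incident photons/ray puts the reference scan at the noise level of a
standard-dose abdominal CT for this object, and an electronic noise SD of
20 counts places the electronic-to-quantum crossover at roughly the 10 %
dose fraction, where clinical low-dose imaging becomes read-out limited.
These are the fixed study conditions; they were chosen on these physical
grounds and are not per-run tuning knobs.

## Statistical iterative reconstruction (`qctfe.sir_recon`)

Penalized weighted least squares on the log data,
`Phi(x) = 1/2 Σ w_i (p_i - [Ax]_i)² + β R(x)`, minimized by the
ordered-subset separable paraboloidal surrogate (OS-SPS) update with
precomputed curvature `d_j = Σ_i a_ij w_i (Σ_k a_ik)`, interleaved angle
subsets (10 by default), and Nesterov-type momentum with restart (on
objective increase when the objective is tracked, else the standard
gradient-scheme restart).  With one subset and no momentum the update is a
strict majorize–minimize step, so the objective is provably monotone; that
guarantee is asserted numerically in the test suite.  The roughness
penalty R is quadratic over in-plane first differences (Huber optional,
delta in attenuation units).  Reconstruction is 2-D slice-wise; a volume
is a stack of slices pushed through the same sparse operator, which is
what keeps a full run cheap.  FBP (ramp/Hann filter + matched
backprojector with the exact Riemann-sum scaling) serves as baseline and
initializer.

**Choosing β.**  Clinical low-dose SIR practice states only that a proper
regularization level is used per dose level.  Here the
reference-scan β (3 × 10⁴) is frozen from a documented sweep on a training
phantom: the largest value that keeps the cortical shell above the
segmentation threshold and the calibration-rod centers unbiased (larger β
blurs the shell below threshold and breaks the expert-mask surrogate).
Reduced-dose conditions then scale the prior-to-data-mass ratio with the
noise variance of the raw reconstruction: for tube current the weights
scale with d and the variance with 1/d, giving β ∝ 1/d²; for sparse
sampling the data mass shrinks by k while per-ray variance is unchanged,
so a constant β already scales the ratio by k.  The aggressive smoothing
this implies at 10 % tube current is exactly the clinically reported
behaviour — and is the mechanism by which trabecular BMD inflates there
(the dense shell and noise spikes smear into the interior).

## Segmentation, calibration, BMD (`qctfe.anatomy`)

The expert manual segmentation of the emulated workflow is replaced by a
deterministic recipe: threshold (175 HU, between soft tissue and shell) →
morphological closing (2 mm) → hole filling → largest connected
component → per-slice convex hull (vertebral-body cross-sections are
near-convex; the hull closes shell-ring gaps left by noise) → optional
in-plane erosion by the reconstruction PSF half-width (1.25 mm in the
pipeline) → removal of axial fringe slices below half the median
cross-section (blurred endplates and noise blobs would otherwise define
the FE load faces).  Masks from any source are accepted downstream.

As in the clinical workflow, segmentation is performed **once per
subject**, on the reference (full-dose) reconstruction, and that mask is
imported into every dose level; dose effects therefore flow through the
HU values and material mapping, not through re-segmentation.

QCT calibration fits `density = intercept + slope · HU` through the rod
mean HUs of *each* scan, with rod ROIs center-sampled (half-radius
erosion) so edge blur cannot bias the line.  Trabecular BMD is the
calibrated mean HU over the shared mask restricted to the central 60 % of
its axial extent (the usual mid-vertebral ROI) and eroded 4 mm in-plane —
a margin sized to clear both the shell and the mask's blur-driven
dilation; it adapts downward for small bodies rather than failing.
Classification uses the clinical thresholds (healthy > 120, osteoporotic
< 80 mg/cc, boundaries assigned to osteopenia).

## FE model construction (`qctfe.femodel`)

The mask is resampled onto a grid of approximately cubic cells fitted
exactly to its bounding box (per-axis cell size = extent / round(extent /
edge)); fitting exactly avoids thin partial end layers whose appearance
would otherwise flip with the edge length and destroy the convergence
study.  Each ≥ 50 %-occupied cell splits into six tetrahedra (Kuhn
subdivision, consistent diagonal, conforming faces).  All six tetrahedra
of a cell share the cell's mean HU — the voxel support of the data, and an
exactly testable definition.

The density–modulus–strength mapping is the standard vertebral QCT-FE
literature chain (apparent density linear in HU; ash density proportional
to apparent density; axial modulus linear in apparent density;
transverse/shear moduli fixed fractions of the axial modulus; piecewise
power-law principal-stress limits and a linear plastic-strain capacity in
ash density).  Two readings of the apparent/ash proportionality circulate;
the package defaults to apparent = 0.6 · ash as printed in its source
table, with the conventional ash = 0.6 · apparent selectable — both are
tested.  Ash density is carried in g/cc (the only unit reading that makes
the power-law coefficients and the 0.317 g/cc branch point dimensionally
coherent with mg/cc-scale apparent density).  Poisson ratios are not part
of the published mapping: nu_p = 0.376 makes the in-plane isotropy
relation E_p / 2(1+nu_p) reproduce the tabulated G_xy = 0.121 E_z given
E_p = 0.333 E_z, and nu_zp = 0.30 is a standard bone value; every
element's 6 × 6 stiffness is verified positive definite at build time.
Degenerate HU is clamped (E_z ≥ 0.01 MPa, plastic strain ≥ 10⁻⁴) so
near-air elements stay numerically harmless.

## Nonlinear compression analysis (`qctfe.fesolve`)

Displacement-controlled quasi-static compression: inferior face fixed,
superior face driven axially (transverse DOF free), 12–20 increments to
2 % of specimen height.  At each increment the linear system (constant-
strain tetrahedra, sparse Cholesky-ordered LU, refactorized only when
damage changes) is re-solved while element states update to a fixed
point:

* INTACT → YIELDED when the maximum principal stress exceeds sigma_max or
  the minimum principal stress drops below −sigma_min; the element's
  stiffness is scaled by a secant factor limit/|driving stress| so its
  stress is capped at the limit;
* YIELDED → FAILED when the driving principal strain in excess of the
  strain at first yield exceeds eps_AB; failed elements keep 5 % residual
  stiffness.

Transitions are one-way and the run is deterministic.  The failure load
is the peak of the force–displacement curve; a peak at the displacement
cap is flagged censored.  This element-wise secant-damage scheme
reproduces the defined ingredients (stress limits, plastic-strain
capacity, peak force) with an oracle-testable algorithm; it is not a
return-mapping plasticity and does not model large strain, contact or
non-compressive load cases.  Global equilibrium is checked at every
recorded step (relative residual ≤ 10⁻⁶).

The element-size sensitivity protocol evaluates seven edge lengths from
3.0 to 1.5 mm in 0.25 mm steps and flags convergence when the failure
load changes by less than 2 % from the next-coarser edge.

## Concordance statistics (`qctfe.concord`)

Per reduced-dose condition versus the full-dose reference, over paired
subjects: ordinary least squares with R² (squared Pearson correlation);
RMSCV — the root mean square of per-subject two-point coefficients of
variation, `CV_i = (|ref_i − red_i|/√2) / mean_i`, in percent (the
densitometric precision convention; no formula is given in the emulated
analysis, this is the documented choice); Bland–Altman bias and
±1.96 SD limits of agreement on `d = reference − reduced` (overestimation
at reduced dose appears as negative bias; magnitudes are reported); and a
two-sided paired t-test (the emulated analysis names only the 0.05
two-sided level).  The identity `bias = mean(ref) − mean(reduced)` is
exact and is asserted as a property.  Subjects × vertebrae are pooled as
independent observations by default.

## The experiment (`qctfe.pipeline`) and problem sizes

Desk-scale defaults: 12 subjects; 48 × 48 × 26 voxels at 1.25 mm
isotropic; 300 views; OS-SPS with 10 subsets × 12 iterations (objective
tracking off, gradient-based momentum restart); 3 mm elements; 12
displacement increments.  One full seven-condition, 12-subject experiment
runs in roughly three minutes on one CPU; these sizes were chosen so that
the complete acceptance analysis — three independent master seeds plus
the mesh-sensitivity protocol — stays a desk-scale computation.  A master
seed fans out to per-subject, per-condition seeds through
`numpy.random.SeedSequence([master_seed, subject_index,
condition_index])`; reruns are bit-identical.

With these study conditions the pipeline reproduces, as scaled-down
analogs, the qualitative findings it was built to probe: concordance
degrades monotonically along the tube-current series and only mildly
along the sparse-sampling series; at 90 % dose reduction sparse sampling
clearly outperforms tube-current reduction on both R² and RMSCV; and
trabecular BMD inflates strongly at 10 % tube current while remaining
stable under sparse sampling.  Numbers are computed fresh by the test
suite and `scripts/acceptance.py`; nothing in the documentation restates
values the code does not produce.

## Known limitations

* Parallel-beam 2-D slices; no cone-beam, helix, scatter, beam hardening,
  bowtie or tube-current modulation.
* The noise insertion is generic (validated-simulator class), not
  calibrated to a specific scanner; published simulator parameters are
  scanner-specific and unavailable.
* Failure loads above the censoring cap are reported at the cap with a
  flag; homogeneous specimens plateau rather than peak, by construction
  of the secant cap.
* The BMD inflation at extreme tube-current reduction emerges here from
  the low-dose regularization policy (shell smear + noise nonlinearity);
  with variance-inverse weights and mild smoothing the same chain instead
  biases attenuation slightly downward.  Either regime can be selected
  through `beta_per_condition`; the default follows the documented
  low-dose policy.
* Phantoms are geometric idealizations; absolute failure loads and BMDs
  transfer to real data only in order of magnitude, and the package's
  claims are about dose-response trends, not patient-level accuracy.
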