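# Methods

## Problem and model

A rigid cylinder scanned in CT appears, slice by slice, as a disc whose
centre traces a straight line through the stack. If the cylinder axis were
perfectly aligned with the scanner's longitudinal (z) axis, that line would
be vertical in (x, z) and (y, z); any in-plane offset and any tilt of the
axis shows up as an intercept and a slope. `corealign` estimates exactly
those four quantities — the misalignment quadruple (t_x, t_y, rot_x, rot_y)
— and undoes them. Two motions are structurally invisible and deliberately
out of scope: rotation about the cylinder axis (a featureless cylinder
carries no angular landmark) and translation along z (no longitudinal
landmark).

## Edge detection

Each 1D search minimises the two-section variance objective over every
admissible split of the profile. The length-weighted form
`(s·Var_L + (n−s)·Var_R)/n` is the default because it is the classical
two-class within-variance criterion with a well-defined exhaustive solution;
an unweighted sum is available by configuration. The scan is vectorised with
prefix sums (O(n)) and is therefore already exact and fast — no interval
bisection heuristic is layered on top, since the objective need not be
unimodal on noisy profiles. Numerical details:

* profiles are centred before the prefix sums (the objective is invariant
  under adding a constant; centring keeps the arithmetic well conditioned at
  |HU| ≈ 1000, and makes the invariance hold to the last bit);
* ties break to the smallest index; the edge is the split index itself
  (first sample of the inner section); localisation is voxel-quantised —
  no sub-voxel refinement;
* a constant profile raises a no-edge error; sections of length 1 would have
  zero variance, so the minimum section length defaults to 2;
* each outside-in search is restricted to the half profile between the image
  border and the central line, so exactly one air/object transition lies in
  the window; the y search runs top-to-bottom only, keeping the patient
  table (below the object) out of every profile.

The circle through the three boundary points is computed by the
perpendicular-bisector closed form; collinearity is rejected when twice the
triangle area falls below 1e−9 × the squared point span. Per-slice failures
are encoded as invalid fits, never exceptions, so one empty or corrupt slice
cannot abort a stack.

## Segmentation and axis fit

Stack segmentation is a greedy single pass chained to the previous slice:
a segment breaks at an invalid fit, a relative radius change ≥ 0.5 %, or a
centre jump ≥ 2 voxels in x or y (per-axis test). Runs shorter than 5 slices
are discarded, and the longest surviving segment — ties to the earliest —
is taken as the object's main section. These three constants are the
method's defining stability rules, not tunables. One consequence worth
knowing: 0.5 % of the radius must exceed the one-voxel quantisation step of
the edge detector, or every edge crossing fragments the stack. At 0.39 mm
voxels this requires a body radius ≳ 40 mm; both supported object classes
(a 160 mm phantom, 120 mm cores) satisfy it comfortably.

Ordinary least squares of x₀ and y₀ against physical z over the chosen
segment give the axis; translation is read off at the stack's physical
mid-plane (this decouples it from rotation, which pivots about the stack
centre, and makes the quadruple unique), and slopes become angles via atan.
The small-angle regime (≤ 2.86°) makes the residual cross-term between the
two tilts (a factor 1/cos of the other angle, ≤ 0.13 %) negligible against
the quantisation floor.

Sign convention, fixed operationally by the round-trip identity
`detect(apply(V, p)) ≈ p`: positive rot_x tips the high-z end of the object
toward +y (image rows run downward), positive rot_y toward +x.

## Rigid transform

The forward transform is `p ↦ R(p − c) + c + t` with `R = R_y(rot_y)·R_x(rot_x)`,
`c` the stack centre and `t = (t_x, t_y, 0)`: rotation first, then
translation. Correction resamples with the exact matrix inverse in a single
pass — never two interpolations. Trilinear interpolation is the default
(nearest-neighbour available); out-of-domain voxels are filled with
−1024 HU. Two short-circuits are exact by construction: identity parameters
copy the volume, and pure in-plane translations on the voxel lattice are
applied as array shifts, so integer-voxel motions are value-exact.

`invert_params` negates the quadruple. This is exact for pure translations
and pure single-axis rotations, but the quadruple family is not closed under
inversion in general — the exact inverse of a mixed motion carries a
z-translation of order sin(rot)·|t| and a z-rotation cross term, both
excluded from the parameter space by design. Nothing in the correction path
depends on this approximation.

## Synthetic data

The generators produce piecewise-constant (optionally noisy) volumes; they
emulate geometry and CT number structure, not physics — no beam hardening,
no projection/reconstruction chain, no scanner noise texture. Passing tests
therefore demonstrate geometric correctness of detection and correction, not
robustness to every artefact of a real acquisition (real scans add
reconstruction-kernel correlation, rings, and table structures; only the
table is modelled, implicitly, by the top-down y search).

Phantom defaults: 143 mm long, 80 mm radius, body 0 HU (water-equivalent),
four 7.5 mm-radius insets at −150/−78/−49/−17 HU on a 25 mm circle at
diagonal positions inside a 40 mm low-contrast section, 0.39 mm in-plane
voxels, 1 mm increment, background air at −1000 HU. The field of view is
200 mm (512-ish matrix at 0.39 mm): with the sampler's maxima of 15 mm and
2.86°, the body's worst-case radial reach is 98.6 mm against a 100 mm
half-FOV, so the largest sampled misalignment grazes but never clips the
field of view — the generator enforces this as a hard invariant. ROIs sit
at 60 % of each inset radius with a trimmed slice range, so noise-free ROI
means equal the nominal insert values exactly.

Core defaults: up to 1 m long (1000 mm default; pass a shorter `length` for
interactive work — a full-length section occupies ~2.8 GB), 120 mm
diameter, 3 mm liner at 300 HU, an air-gap circular segment at the top of
the image (3 % of the inner diameter, the settling gap between frozen
sediment and liner), Gaussian sediment texture 700 ± 60 HU, and ellipsoidal
coral clasts of 1400–2200 HU with 3–10 mm semi-axes (~2 cm clasts), placed
uniformly in the sediment with bounded retries. With the gap present, the
top (y) edge search may lock onto the gap→sediment transition instead of the
liner; the fitted radius stays within ~0.5 mm of truth but the y centre can
carry a constant bias — consistent with the general observation that
x-parameters (two search points) are recovered more accurately than
y-parameters (one search point).

The misalignment sampler draws each component i.i.d. uniform on
[−max, +max], defaults 15 mm and 2.86° (0.05 rad); an unsigned mode exists
for sensitivity checks. All generators are deterministic under a fixed seed.

## Validation experiment

`run_experiment` repeats: draw a quadruple, apply it, detect, correct with
the detected parameters, and measure the four ROIs — at fixed image
coordinates — on the original, misaligned and corrected volumes.
Misalignment moving an insert out of its ROI is precisely the measured
effect. Detection failures flag the repetition and are excluded from
summaries but surfaced in the counts. Summaries report mean and population
SD (divisor n) of signed and absolute differences: the population form is
what study-style `mean ± SD` tables reproduce (sample SD demonstrably does
not), while the embedded one-sample two-tailed t test uses the sample SD, as
its definition requires; zero-variance inputs degrade to NaN statistics
rather than errors in summaries.

Problem sizes: the package supports full 1000-repetition runs; the shipped
tests and the acceptance script use 50 repetitions on the full-size default
phantom, which bounds the mean absolute recovery error per axis at well
under a voxel (empirically ≈ 0.01/0.10 mm in x/y and ≈ 0.08°/0.02° about
x/y) while keeping a complete run in minutes on one CPU. Unit tests use
shortened phantoms (unchanged radius, FOV and voxel sizes) so the in-plane
geometry — the part that matters for detection — is identical to the
full-scale object.

`rotation_error_bound(α, l) = tan α · l/2` converts a residual tilt into the
worst-case in-plane displacement at the object end; for the default phantom
a typical residual of 0.15° maps to ≈ 0.19 mm, under half a voxel.

## Slab reconstruction

Sagittal slabs are mean projections over half-open x ranges (default
5 mm / 5 mm), chosen as the plain surrogate for console thick-slice
reconstruction; the plane-count-weighted mean of the slab images equals the
volume mean over the covered range to machine precision. The digital ruler
renders ticks at `round(k·spacing / Δz)` pixel rows with the depth origin at
the first slice, confined to a fixed left margin strip so the image content
outside the strip is untouched. Window/level defaults (centre 300, width
1500 HU) suit sediment; they are parameters, not contracts.

## Known limitations

* No z-rotation or z-translation detection (structural, see above).
* Edge localisation is voxel-quantised; at small tilts the centre track is a
  staircase and the regression slope error is bounded by roughly one voxel
  over the segment's z extent (≈ 0.16° for a 143 mm segment) — the dominant
  term in the observed rotation errors.
* One object per stack; no robust/RANSAC axis fit for strongly deformed
  cores; curvature is not modelled.
* The synthetic core's texture is white Gaussian noise, not a geological
  fabric; detection robustness, not realism, is its purpose.
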