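# Methods

## Coordinate conventions and geometry model

All lengths are mm, all angles degrees on the Varian IEC 601-2-1 scale.
The static room frame has its origin at the BB center: +x to the right
facing the gantry, +y toward the floor, +z toward the gantry. The
vendor scale fixes only the *meaning* of gantry/collimator readouts, not
an algebraic map into room coordinates, so the package adopts

    source(G)  = SAD · (sin G, −cos G, 0)
    beam(G)    = −source(G)/SAD
    u_hat(G)   = (cos G, sin G, 0),   v_hat = (0, 0, 1)

i.e. at gantry 0 the source is above the isocenter and the beam points
toward the floor. Simulator and analyzer share this one convention, and
correctness is defined by internal consistency (round-trip tests);
`row_to_v_sign` in the image metadata mirrors the inplane axis for
machines whose EPID readout is flipped, and a single sign flip of
`u_hat` would accommodate a mirrored scale variant.

Beam central rays are modelled as **parallel rays** along the beam axis
through the measured field center at the isocenter-plane scale — the
natural model when measurements are expressed at that scale, since the
field center is defined *on* the beam axis. For the BB the parallel
back-projection carries a parallax error that is first order in
|b|·ζ/SAD (ζ = component of the BB offset along the beam); it is below
0.01 mm for |b| ≤ 2 mm and largely cancels between opposed gantry
angles. A `perspective` mode builds the true diverging source ray and
is exact for any offset; both modes are exposed and their difference is
bounded in tests. Parallel mode is the default reporting path; the
geometry round-trip guarantee over the full ±5 mm setup cube is stated
for perspective mode.

### Least-squares isocenter

The isocenter minimizes the summed squared point-to-line distances,
solved via the 3×3 normal equations A x = b, A = Σ(I − dᵢdᵢᵀ),
b = Σ(I − dᵢdᵢᵀ)pᵢ. If the smallest eigenvalue of A is below 1e−9 of
the largest (all rays parallel — e.g. offsets from only two opposed
gantry angles), the pseudoinverse minimum-norm solution is returned and
`condition_flag` is set rather than raising: degenerate subsets are a
legitimate analysis outcome, but must be visible. Per-ray distances and
their RMS (the "isocenter size" statistic) are always reported.

## Image analysis

**Scaling.** Pixel centers sit at integer indices, the image center at
((n_row−1)/2, (n_col−1)/2) maps to (u, v) = (0, 0); one pixel step is
the imager pitch × SAD/SID (0.336 × 1000/1500 = 0.224 mm by default).

**BB detection.** Circular Hough transform on Canny edges of the
min-max-normalized image, radii 0.8–1.2× the expected projected BB
radius (≈14.5 px), accumulator threshold 0.3. The coarse center is
refined by the intensity-weighted centroid of the attenuation deficit
(local-annulus median background minus image, clipped at zero) within
1.5× radius, iterated three times. Because the deficit vanishes
outside the BB disc, the centroid window introduces no truncation bias;
noiseless recovery is at the 10⁻³-pixel level. The BB is treated as an
attenuation deficit (darker); a polarity flag supports inverted exports.
The Hough/refinement parameters are engineering choices validated by the
simulator-recovery tests, not physical constants.

**Field detection.** Baseline = median of out-of-field pixels, plateau
= two-pass median of a central in-field patch (robust to the BB
deficit). The field edge is defined at 50% of (plateau − baseline), the
standard radiological field-edge definition. For each of the four MLC
edges, 48 profiles are sampled perpendicular to the expected edge
orientation — seeded from the metadata collimator angle, which removes
the 90° ambiguity of blind orientation estimation (a gradient-histogram
blind mode exists for metadata-free images) — using bilinear
interpolation at 0.25-pixel steps. Each profile's 50% crossing is
linearly interpolated; a straight line is fit per edge with 2·MAD
outlier rejection; an edge with crossings in fewer than 75% of its
profiles fails the image. The field center is the intersection of the
two bisectors of the opposing-edge pairs, which makes it first-order
insensitive to symmetric penumbra changes and to field-size errors.
Non-orthogonality of the fitted edge pairs beyond 2° warns but does not
fail. All thresholds are relative to the plateau/baseline estimates, so
the analysis is invariant to affine intensity transforms.

An image is rejected (contamination error) when the detected BB center
lies within BB-radius + 2 pixels of a fitted 50% edge, where the deficit
and penumbra overlap and both detectors are biased.

## Simulator

Each image is an open-field plateau bounded by separable erf penumbras
at ±L/2 in the collimator frame (rotated by C), multiplied by the
transmission exp(−μ·chord) of the perspective-projected 6.5 mm sphere,
plus optional additive Gaussian noise (Poisson mode available) and
16-bit quantization. μ = 0.141/mm gives a ≈60% central deficit; contrast
affects only detector SNR, never geometry. Secondary jaws (15 cm for
standard tests, 25 cm in the field-size study) are rendered as a second,
softer aperture only when they fit inside the image; the default image
size is auto-chosen to cover the MLC field plus a 12 mm iso-plane
margin, so jaws are normally outside the frame and irrelevant to MLC
edge detection.

The field-center misalignment model is

    fc(G, C) = R(C)·c + a_g · (ĝ·x̂_leaf(G, C)) · x̂_leaf_img(C) + wobble

* `c` — collimator-axis offset, fixed in the collimator frame; rotates
  with C and cancels exactly between opposed collimator angles.
* Sag term — gravitational MLC-leaf sag along the leaf-travel direction
  x̂_leaf (the collimator-frame u axis); its gravity projection is
  sin G · cos C: maximal at lateral gantry angles with collimator 0,
  zero at collimator 90/270, and *identical* for C and C+180, so it is
  not cancelled by opposed collimators. This realizes the hypothesized
  sag mechanism as a one-parameter model; the amplitude a_g is a free
  configuration choice (≈0.2 mm reproduces the group separation seen on
  clinical TrueBeams), not a constant of the package.
* Wobble — isotropic per-image N(0, σ²) field-placement jitter, the
  random component of the machine's isocenter size.

Defaults describe a well-tuned machine under study conditions:
c = 0, a_g = 0, wobble σ = 0.1 mm (consistent with ≈0.015/0.045 mm
isocenter scatter at N_BCR = 56/8), penumbra σ = 3 px, relative noise
1%, 10 cm MLC field, BB within ±2 mm of the isocenter. Determinism:
every image's random stream is derived from (config seed, gantry,
collimator), so identical configs are bitwise reproducible while
per-image wobble draws stay independent.

### What the simulator does and does not emulate

It emulates the geometry, projection scaling, penumbra, BB contrast,
noise, and the three misalignment mechanisms above. It does **not**
model MLC tongue-and-groove edge structure, imager sag or flood-field
artifacts, scatter, the BB support stem, or couch rotation. Passing
closed-loop tests therefore demonstrates the correctness and precision
of the *algorithms* under controlled conditions; they do not certify
performance on a specific clinical image chain, and the benchmark
deviation tables in `reference_data` (measured on four clinical
TrueBeams) are reproduced only as report arithmetic, never as simulator
output.

## Studies

**Subset study.** The 31 subsets and their four collimator groups are a
fixed transcription (3 single-C0, 4 single-90/270, 3 opposed-90&270, 21
mixed). Solves reuse the per-image measurements of one long test
(retrospective sampling, no re-imaging), all rays weighted equally. The
reference isocenter is the componentwise mean of the 21 mixed-group
solutions; deviations are reported to 3 decimals in mm. Note the
reference itself inherits a small bias when `c ≠ 0`, because mixed
subsets with unpaired collimators do not fully cancel — visible in the
cancellation tests, and part of the method being studied.

**Shift study.** Positions: initial, 11 fresh uniform draws in ±2.5 mm
per axis added to the initial couch position (fresh relative to T₀, as
specified by the protocol, not cumulative), and a return to start — 13
WL tests. Couch motion is simulated as an exact BB translation by
default; a `couch_error_sigma_mm` knob adds motion error when the couch
itself is under study. The per-axis fit Δ(BB−Iso) = a + k·ΔT uses
ordinary least squares. Uniform draws were chosen because only the
range of the random shifts is prescribed. Wobble σ = 0.05 mm calibrates
the simulated short-test error to the empirically observed shift-recovery
scale (≈0.03–0.07 mm), under which every |Δ(BB−Iso) − ΔT| stays inside
the 0.1 mm envelope.

**Field-size study.** Sizes 2, 3, 5, 6, 10, 15, 20 cm, five repeats
each, jaws at 25 cm; per-axis one-way ANOVA across sizes at the 5%
level, no multiple-testing correction across the three axes (none is
applied in the protocol being implemented). The BB-margin precondition
(BB radius + 2 px clearance inside the smallest field, including a 3σ
wobble allowance) is enforced before any rendering. The null criterion
is evaluated per axis: each axis should fail to reject in ≥90% of
replicates (≈95% expected for a 5%-level test); demanding all three
axes jointly would have an expected pass rate of 0.95³ ≈ 0.86 and is
not a property of a correct implementation.

**Two modes.** `mode="image"` renders and analyzes every portal image.
`mode="analytic"` works at measurement level: exact perspective BB
projections (solved in perspective mode, so noiseless mechanics are
exact to machine precision) and model field centers with wobble, no
pixels. Analytic mode exists because the statistical claims
(replicate-averaged slopes, ANOVA operating characteristics, 1/√N
scaling) are about the geometry and the solver, not about pixel-level
detection — and because they require thousands of WL solves, which at
image level would add nothing but the detector's separately-tested
~0.005 mm noise floor. Problem sizes in the shipped tests and the
acceptance script (50-replicate ANOVA study, 100-replicate slope check,
60-replicate subset-shrinkage check, single rendered long test at a
5 cm field) were chosen so the statistical assertions are stable at the
stated thresholds while the whole suite stays fast on one CPU.

## Numerical choices and degenerate inputs

* Rank-deficiency threshold 1e−9 (relative eigenvalue) in the solver;
  flagged, not fatal.
* Angles wrapped to [0, 360); all trig in degrees at interfaces.
* Edge-crossing search width: max(6 px, 3 mm), capped at 45% of the
  field half-size so opposing edges never enter one profile.
* ANOVA on groups with zero variance everywhere, fits with constant x,
  plans with fewer than 2 distinct gantry angles, images with no
  contrast: explicit errors, never NaN propagation.
* Reported tables round to 3 decimals (mm); internal math is double
  precision throughout.

## Known limitations

* Couch-rotation axes are out of scope; plans enforce couch 0°.
* The sag model is a deliberately minimal one-parameter realization of
  the gravity mechanism; real leaf banks have leaf-pair structure.
* Subpixel accuracy claims (≈0.005 mm noiseless, <0.03 mm bias at
  SNR 50) hold for the simulated image chain; vendor image
  post-processing may degrade them.
* The DICOM reader ingests RT images with standard angle/geometry tags
  only; vendor private tags are ignored.
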