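# Methods

`onhoffset` measures the misalignment among the three openings of the optic
nerve head (ONH) canal on the enface plane: the Bruch's membrane opening
(BMO) at the retinal level, the anterior scleral opening (ASCO) at the
anterior scleral surface, and the lamina cribrosa level, proxied by the
emergence of the central retinal vascular trunk (CRVT). This note documents
the measurement model, the synthetic data generator that stands in for
patient data, the numerical choices, and the limits of what the validation
shows.

## Measurement model

**Input geometry.** Each eye contributes landmark points demarcated on 24
radial OCT scans taken in 15° increments, centered on the BMO: two BMO and
(where discernible) two ASCO margin points per scan, plus the CRVT position
and, when the externally oblique border (EOB) exceeds 100 µm, the meridian
of its longest extent. Coordinates are pixels on the enface plane. All
angular quantities use the canonical right-eye frame (+x nasal, +y
superior); left eyes are mirrored at ingestion so a single convention
serves both lateralities.

**Center estimation.** An opening's boundary is modeled as an ellipse. For
a point set P the fitted ellipse minimizes the cost

    C(E) = sum over p in P of d(p, E)^2

where `d(p, E)` is the orthogonal (geometric) Euclidean distance from `p`
to the ellipse curve — not the algebraic conic residual, which is
scale-ambiguous. Minimization uses Nelder–Mead over the 5-parameter
geometric form `(cx, cy, log a, log b, theta)`; the log-axes guarantee a
valid ellipse at every iterate (raw conic coefficients can wander into
hyperbolae). The opening center is the fitted ellipse center. The
arithmetic centroid of the same points is computed as the biased
comparator: when an arc is missing, the centroid is pulled toward the
observed points, while the fit extrapolates the boundary (no imputation of
missing arcs is performed).

**Derived metrics per eye.**

- *ASCO offset*: vector from fitted BMO center to fitted ASCO center;
  reported as an angular deviation (nasal horizontal midline = 0°, positive
  superior, range (−180°, 180°]) and an extent in px.
- *CRVT offset*: same convention for the CRVT landmark.
- *Shift index* `a/b`: CRVT distance from the BMO center (`a`) over the
  distance from the BMO center to the BMO margin in that direction (`b`).
  When the CRVT is not visible within the BMO, the index is 1.0 by
  definition and the CRVT angle is undefined. A CRVT exactly at the center
  gives 0 with no direction.
- *Offset ratio*: CRVT offset extent over ASCO offset extent. Undefined
  when the shift index is 1.0 (the CRVT extent cannot be measured) or when
  the ASCO offset extent is below ε (default 0.5 px; a near-zero
  denominator has no meaningful direction or ratio).
- *Direction class* of the ASCO offset: nasal (−45°, 45°), superior
  [45°, 135°], temporal |θ| > 135°, inferior [−135°, −45°]. Boundary ties
  are assigned to the vertical classes; the choice is measure-zero and made
  only for determinism.
- *Completeness class*: the longest circular run of unmarked ASCO
  half-directions, times the angular spacing of the unique scan directions
  (15° at defaults), is the maximal indiscernible gap. Gaps ≤ 30° are
  `complete`, 30–90° `incomplete`, > 90° `excluded` (such eyes are dropped
  from cohort summaries). The gap is measured from the BMO center — the
  scan center — which is also the only center defined for every eye.
- *ASCO area*: device-reported BMO area times the fitted ASCO/BMO ellipse
  area ratio; invariant to the pixel scale.

**Cohort statistics.** Summaries report mean, SD and t-based 95% CIs
(offset ratio overall and per direction class). Angular deviations are
correlated with Pearson's r, treating angles as linear quantities on their
stated reference conventions; note a reference-meridian flip (nasal vs
temporal zero) flips the sign of r, and angles wrapping across ±180° can
attenuate a linear correlation — circular statistics are deliberately out
of scope. Two dependent correlations sharing a variable are compared with
Williams' test in the Steiger t2 form,

    t = (r12 − r13) * sqrt( (n−1)(1+r23) /
        ( 2((n−1)/(n−3))|R| + rbar^2 (1−r23)^3 ) ),  df = n − 3,

with `|R|` the determinant of the 3×3 correlation matrix and
`rbar = (r12+r13)/2`; the older Hotelling t form is available behind a
flag. The exact published variant behind this test's common citation is
ambiguous, so the implementation is validated by Monte-Carlo null
calibration (empirical size ≈ 0.048–0.052 at α = 0.05, n = 100) rather
than by a printed worked example. Interobserver variability uses the
one-way random-effects ANOVA coefficient of variation: within-subject SD
(root of the within mean square) over the grand mean.

## Synthetic eye generator

No annotated patient data ship with this package; every downstream stage
is exercised on synthetic eyes whose ground truth is known exactly.

**Population model** (defaults, all configurable):

| parameter | default | basis |
| --- | --- | --- |
| BMO area | N(2.62, 0.89²) mm², truncated > 0.5 | cohort means of the morphometry emulated |
| ASCO/BMO area ratio | N(1.0, 0.10²), clipped to [1/3, 3] | ASCO ≈ BMO area |
| axis ratio (minor/major) | N(0.87, 0.05²), clipped [0.6, 1] | near-elliptical openings |
| offset direction | Gaussian mixture at 0°/90°/180° (weights 0.55/0.30/0.15), SD 18°, truncated 15° clear of the inferior sector | nasal > superior > temporal preference; inferior ASCO offsets are not generated |
| offset extent | Gamma(shape 3, mean 0.15) × BMO effective radius, floor 0.05 × radius | mean offset ≈ 14 px ≈ 140 µm; a tiny offset has no meaningful direction |
| true offset ratio | N(2.0, 0.5²), floor 0.2 | CRVT displaced about twice the ASCO offset |
| CRVT jitter | isotropic 3 px | landmark placement variability |
| CRVT outside BMO | probability 0.09 | ~1 in 10 eyes has no visible CRVT emergence |
| pixel scale | 10 µm/px | typical enface sampling |

The CRVT is constructed as BMO center + (true ratio) × (offset vector) +
jitter; eyes drawn with the "outside" flag place it beyond the BMO margin
and mark it invisible. The longest-EOB meridian is the direction
maximizing the radial ASCO-minus-BMO margin distance, reported (with 8°
observer noise, temporal-reference) only when the maximal EOB exceeds
100 µm.

**Radial-scan sampler.** For each of the 24 scan angles (15° increments)
and each half-direction θ and θ+180°, the BMO point is the exact
ray–ellipse intersection from the BMO center plus isotropic Gaussian noise
(default σ = 2 px). The ASCO point is generated the same way — rays
emanate from the *BMO* center, which is what makes the sampling uneven for
a shifted ASCO — but is marked only if

1. the true ASCO radius along the ray exceeds the true BMO radius by more
   than `visibility_threshold`, and
2. an independent Bernoulli(1 − dropout) draw succeeds (default dropout
   0.02).

The 24 × 15° fan spans 360° of scan angles, so each geometric diameter is
covered by two scans; records are keyed by (scan, half) and completeness
is evaluated on the unique direction angles. Whether the physical device
spaces scans 15° or 7.5° apart cannot be settled from the protocol
wording; the fan is configurable and the default follows the wording
literally.

**Visibility threshold calibration.** With ASCO area ≈ BMO area, the
radial ASCO-minus-BMO distance along a ray is approximately
δ·cos(φ − θ₀) for offset extent δ — negative on the half-circle opposite
the offset. A nonnegative threshold would therefore unmark half of every
offset eye's circumference, which is not what demarcation of real scans
shows: graders can trace the scleral termination well into the internally
oblique region. The default threshold is −20 px (−200 µm at 10 µm/px):
the ASCO margin becomes unmarkable once it is buried more than ~200 µm
radially inside the BMO margin. Closed-form consequence: an eye develops a
gap only when δ > 20 px, an incomplete-class gap (> 30°) when δ ≳ 20.7 px,
and an excluded-class gap (> 90°) when δ ≳ 28.3 px — which at the default
offset distribution yields roughly 70–80% complete, ~20% incomplete and
~5% excluded eyes, and makes missingness mechanically monotone in the true
offset. These completeness proportions emerge from the geometry; they are
not targets the sampler reads.

**Seeding.** One master seed; per-eye generation and per-eye scan-noise
streams are split with counter-based `SeedSequence` spawn keys, so cohorts
are reproducible and order-independent, and no noise is shared across
eyes.

**What the generator does not emulate.** OCT image formation, manual
segmentation behavior (missingness is deterministic geometry + dropout,
not grader psychology), axial (z) canal obliqueness, layered
border-tissue anatomy, and correlations between eye size and offset
beyond those implied by the scale-free construction. Passing recovery
tests therefore demonstrates correctness of the measurement machinery
under a faithful sampling geometry — not clinical validity on real scans.

## Numerical choices

- **Point-to-ellipse distance**: points are mapped into the ellipse frame
  and folded to the first quadrant, where the squared distance to the
  boundary is unimodal in the parametric angle; a fixed-iteration
  golden-section search (64 steps for the public distance, 40 inside the
  fit cost) brackets the minimum. Distance error is linear in the final
  bracket near a zero minimum and quadratic otherwise; both regimes sit
  far below the 1e−5 px oracle tolerance. The kernel is JIT-compiled with
  numba (pure-numpy fallback retained).
- **Fit initialization**: a numerically conditioned direct algebraic
  least-squares ellipse fit (quadratic-constraint formulation on
  centered/scaled coordinates); fallback to (centroid, 2 × coordinate SDs,
  axis-aligned) when the algebraic system is degenerate.
- **Convergence**: simplex tolerances 1e−10 (cost) and 1e−8 (parameters),
  max 2000 iterations; up to 3 deterministic seeded restarts attempted
  only while unconverged; the reported cost never exceeds the
  initialization's.
- **Degeneracy**: fewer than 5 points, or a centered-coordinate singular
  value ratio above 1e10 (collinearity), is rejected as unfittable.
- **Ties and ranges**: semi-axes ordered major ≥ minor (rotation shifted
  90° when swapped); rotation reduced mod 180°; angles reported in
  (−180°, 180°] with −180° mapped to +180°.
- **Degenerate metric inputs**: CRVT at the BMO center → shift index 0,
  no direction; ASCO offset below ε → angle, direction class and offset
  ratio undefined rather than noise-dominated.
- **File contract**: CSVs store image-space coordinates (y down, 0-based
  pixel centers) with `repr`-formatted floats, so write→read round-trips
  are bit-exact; the canonical frame exists only in memory. A visible CRVT
  landmark that noise places outside the *fitted* BMO is folded into the
  shift-index-1.0 convention with a reason code instead of failing the eye.

## Validation sizes

The test and acceptance suites use: 1000 random ellipse/point pairs
against a 10^6-sample parametric oracle; 8 ellipses for noiseless
full-coverage and 90°-missing-arc recovery; a 500-eye default-condition
cohort for end-to-end recovery of the offset ratio and directions; 4 × 80
eyes across offset strata for the incompleteness mechanism; 20,000
replicates at n = 100 for Williams-test calibration; and all 2^12 mark
patterns on a reduced 12-direction fan for the completeness classifier.
These sizes were chosen to make the checks statistically decisive while
keeping a full run in the minutes range on one CPU.

## Known limitations

- Enface-plane only; no 3-D neural-canal obliqueness.
- Angles are treated linearly in correlations; wrap-around near ±180°
  attenuates r for temporal-offset-rich cohorts.
- The ASCO fit for heavily incomplete eyes extrapolates from under half
  the boundary; its center uncertainty grows accordingly and is not
  propagated into the cohort statistics.
- The exact distance formulation of the original MATLAB cost function is
  not published; the orthogonal-distance reading is validated by parameter
  recovery, not coefficient-level comparison.
- Regression/logistic modeling of cohort covariates is out of scope; only
  the qualitative directions the generator reproduces are checked.
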