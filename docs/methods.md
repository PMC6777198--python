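# Methods

## Dose calculator

The calculator is a deterministic four-component formula: BSA × 45
ml/m², plus a piecewise-constant heart-rate correction, plus a linear
concentration correction around 350 mg I/ml, rounded half-up to whole
ml and clamped to the 40–150 ml protocol window. The dilution arm
halves the clamped dose (half-up) with a 20 ml floor.

Three choices deserve explanation:

* **BSA reading.** The device documentation prints
  `((length × weight)/3600) × 0.5`, which is the Mosteller formula with
  the square root replaced by a factor 0.5 — plausibly a typesetting
  corruption of `^0.5`. Both readings are first-class
  (`bsa_mode="literal" | "mosteller"`), but the default is the literal
  one because only it reproduces the documented worked example
  (115 kg, 185 cm, 122 bpm → 163 ml pre-clamp). For typical adults the
  two readings differ by ~1–3%.
* **55 bpm.** The printed correction table runs "<55" then "56–65",
  leaving exactly 55 bpm unassigned. Bands are implemented as ≤55,
  56–65, …, so the table is total; 55 falls in the −10 ml band.
* **Order of operations.** All corrections are applied before rounding,
  rounding before clamping, and dilution after clamping. The clamp
  limits are stated as properties of the administered dose, and
  clamp-then-dilute is the only order consistent with the dilution
  arm's observed 72 ml maximum (= 144/2, ≤ 150/2).

Two printed doses (126 ml at 97 kg/175 cm/69 bpm; 134 ml at
100 kg/182 cm/65 bpm) match neither BSA reading at any stocked
concentration; the protocol allowed technicians to adjust or confirm
the calculated dose, so these are treated as manual adjustments and not
used as tests.

## Synthetic cohorts

Study arms are sampled attribute-wise from normal distributions
truncated to the published min–max ranges, with the published mean and
SD used as the parameters of the *parent* normal. Sampling is
inverse-CDF (uniform draws through the truncated-normal quantile
function), so cohorts are bit-reproducible for a seed across platforms.
Heart rate is rounded to whole bpm.

Two systematic consequences are accepted rather than corrected, because
the published summaries describe post-truncation data while the
generator treats them as pre-truncation parameters:

* truncation shrinks the simulated SD slightly below the published SD;
* asymmetric ranges shift the simulated mean away from the published
  location (e.g. dilution-arm weight 60–109 kg about 79.9 kg gives a
  truncated mean ≈ 81.5 kg).

Tests therefore compare empirical moments against the *analytic
truncated-normal* values, not the raw published numbers. Attributes are
sampled independently by default (no covariance is published); a
Gaussian-copula weight–height correlation hook exists for BMI-realism
experiments (default 0).

## Enhancement and reader-score generator

No enhancement model is published, so enhancement is generated
distributionally: a patient-level mean drawn from the arm's truncated
normal (published mean ± SD, min–max), plus independent N(0, 15 HU)
noise at each of the five aortic measurement levels (suprarenal, renal,
infrarenal, both common iliacs). The 15 HU level noise is a chosen
default for ROI-to-ROI variation along a well-opacified aorta; the
published data constrain only the five-level mean. A `mechanistic` mode
(enhancement ∝ injected iodine mass / BSA with an optional heart-rate
power factor) is provided for sensitivity experiments only; the study
defaults do not use it.

Dissection physiology is reduced to a single knob: a true-lumen
enhancement fraction multiplying the patient mean (default 1.0, i.e.
off, because the published arm distributions already include the
dissection cases; lowering it emulates flow redistribution into the
false lumen).

Visual scores use a latent-variable threshold model: latent quality
q = a + b·(mean HU) plus N(0, 0.5²) reader noise,
rounded at half-integers and clipped to 1–5. Reader 2 adds the arm's
published bias (+0.45, +0.45, +1.1) to the latent before thresholding;
reader 1's second session re-thresholds the session-1 latent perturbed
by N(0, 0.35²). The map (a, b) is calibrated once — by minimizing the
squared error between the analytic reader-averaged expected scores and
the published arm means 4.5/4.6/3.7 — and frozen
(a = −0.6156, b = 0.019585 per HU; `analysis/00_calibrate_scores.py`
reproduces the fit). Arms 1 and 2 have nearly identical enhancement
distributions, so any monotone HU→quality map places both near 4.55;
they cannot be separated further by construction.

What passing tests show: the generator reproduces its own calibrated
group means and the published dose means, monotonicity and bias
structures behave as designed. What they do not show: anything about
real reader behaviour. The published agreement coefficients
(inter-observer ICC 0.472, intra-observer 0.601) derive from clinical
images and human judgment and are deliberately not calibration targets;
the simulated readers are more consistent than the real ones.

## Phantom and ROI measurement

Slices are flat 2-D grids (default 129×129 at 0.7 mm isotropic
spacing, 0-based row/col indices, pixel-center convention): circular
lumen at the specified HU, optional mural-thrombus annulus, optional
straight intimal flap whose chord offset is solved (Brent root-finding
on the circular-segment area) so the true lumen occupies a requested
area fraction. Noise is additive white Gaussian. Membership tests are
pixel-center-in-disc with no partial-volume weighting — simple and
deterministic; the measured mean is then exactly the specified HU at
zero noise, which the tests exploit as a round-trip oracle.

Automatic ROI placement mimics the protocol's "carefully placed in the
center" instruction: the ROI centre is the (true-)lumen centroid and
its radius 0.6 × the largest circle inscribed at that centre (Euclidean
distance transform). The 0.6 fraction and the 2 mm minimum radius are
package defaults — the clinical ROI diameter is not published. A true
lumen too small for the minimum is flagged on the returned spec, never
silently shrunk.

## Statistics

* Descriptives: mean, sample SD (n−1), median (midpoint rule), range.
* Pairwise contrasts: the published analysis names a "paired Student's
  t-test" but compares independent arms; the study default here is the
  pooled two-sample Student t (Welch and paired variants are one flag
  away, paired being appropriate only for intra-patient repeat scans).
  Two-tailed p; significance hard-coded at α = 0.025 (Bonferroni α/2
  for two planned comparisons against the control arm), with no further
  correction across outcome variables, mirroring the original analysis.
  Degenerate zero-variance comparisons return t = 0, p = 1 (equal
  means) rather than NaN.
* Percent differences are computed and stored unrounded, relative to
  the first-listed arm, and rounded to integer percent only for
  display. The published score differences (−19%, +1%) are consistent
  with unrounded means, not the printed 4.5/4.6/3.7, and are not
  targeted.
* Agreement: ICC, two-way ANOVA, consistency, average measures —
  ICC(C,k) = (MS_subjects − MS_error)/MS_subjects — implemented
  directly from the mean squares (an independent brute-force ANOVA
  oracle and `pingouin` cross-check it in the tests). Consistency
  deliberately ignores constant per-rater offsets, which is exactly the
  reader-2 bias structure. Zero between-subject variance is reported as
  undefined, not NaN. An absolute-agreement variant is intentionally
  not the default.

## Pipeline and reproducibility

One master seed drives everything. Substream seeds are
`SHA-256(f"{master}:{label}") mod 2³¹` per module and arm, and each
patient's imaging uses a `(stream_seed, patient_index)` spawn, so
cohorts and records are stable under reordering and module additions.
Outputs are written atomically (temp file + rename); the run log
records the full configuration and a content hash of every table.

Problem sizes: study runs use the published arm sizes (20/20/20);
convergence tests use 5,000–10,000 draws; null-calibration tests use
10,000 simulated trials; the replicated recovery check uses 20 studies.

## Known limitations

* The generator reproduces marginal summaries, not joint structure:
  dose and enhancement are independent within an arm by construction
  (distributional mode), unlike reality where both depend on habitus.
* Published means/SDs are treated as pre-truncation parameters (see
  above); all acceptance comparisons account for this explicitly.
* The phantom has no acquisition physics; it validates measurement
  geometry, not image formation.
* Ordinal scores are analysed via means and t-tests to mirror the
  original analysis, though an ordinal model would be more principled.
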