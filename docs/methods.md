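# Methods

`gazepolarity` is an in-silico reconstruction of a cross-species
gaze-discrimination experiment: it renders parametric eye stimuli for a
human-like and a chimpanzee-like morph, schedules the two behavioural tasks
under their balancing and sequencing constraints, simulates trial-level
responses from a generative logistic observer, and analyzes the resulting
binary data with binomial mixed models. This note documents the models, the
defaults and why they were chosen, and what the synthetic pipeline can and
cannot say about real data.

## Stimuli

Each stimulus is a single-eye ("cyclopean") face patch on a 400×400 px
canvas over a 50% gray background (sRGB 128,128,128). The eye opening is an
ellipse; the iris is a 16 px disc clipped to the opening with a concentric
8 px pupil; the sclera fills the rest of the opening. Geometry defaults
encode the two species morphs: the human-like opening is 48×18 px
(width/height ≈ 2.7) with a white sclera (L\* = 92) and dark iris
(L\* = 30); the chimpanzee-like opening is 36×20 px (≈ 1.8) with a dark
sclera (L\* = 22) and brighter iris (L\* = 55). A single eye rather than a
two-eye face keeps the iris-extent measurement, iris-based size
normalization, and the 4:1 eye-strip crop unambiguous; colorimetric
quantities (ROI means, ΔE) are unaffected by the number of eyes.

Averted gaze displaces the iris by `shift_px` (default 6 px, the horizontal
projection of a ~20° eyeball rotation for an eyeball radius of
6/sin 20° ≈ 17.5 px; the same geometry gives ≈ 9 px at 30° and ≈ 11 px at
38°, the eccentricities used in the training stages). Exposed areas fill
with sclera color, as the photographic stimuli were retouched.

**Polarity reversal** converts each eyeball pixel to CIELAB (D65/2°, via
scikit-image), maps L\* → 100 − L\* and leaves (a\*, b\*) untouched, then
converts back to sRGB with gamut clipping. Because the map is an isometry
of the L\* axis, any within-eye CIELAB difference — in particular the
iris–sclera ΔE — is preserved up to 8-bit quantization; the tests bound the
involution error at 1 ΔE per pixel and the iris–sclera ΔE change at 0.5.
An optional `grayscale` mode inverts BT.601 luma instead, for comparison
with pipelines that operate on gamma-encoded grayscale.

**Levels.** The seven degradation steps couple width (400, 300, 200, 150,
100, 75, 50 px) with brightness (100, 75, 50, 42, 33, 29, 25%). The printed
42% at L2.5 is used as-is although the arithmetic midpoint of 50% and 33%
is 41.5%. Brightness scales 8-bit sRGB channels multiplicatively
(image-editor semantics, the conventional reading of "% brightness");
linear-light scaling is available via `space="linear"`. Downscaling uses
area-averaging (`BOX`) resampling and requantizes to 8 bits after each
transform, so L1 is bit-exact identity.

Real photographs are supported only together with user-supplied ROI masks;
automatic segmentation and the auto-level adjustment applied to photographs
are out of scope.

## Schedules

Both task families balance conditions exactly and constrain sequences:
96-trial keypress experiments (8 alternating-species blocks of 12; level
progression L1×3…L4×3 in experiment 1; six L3 then six L4 trials with block
polarities N,N,R,R,N,N,R,R in experiment 2; 32 trials per gaze direction;
no direction three times running; no stimulus individual twice running) and
48-trial search sessions (4 alternating-species blocks; 16 trials per
target location; each of 6 individuals per species exactly 4 times; at
level ≥ 1.5 each block is 6 baseline-L1 then 6 test trials).

Randomization is a sequential constrained draw: items are placed one
position at a time with probability proportional to their remaining
multiplicity among the non-vetoed candidates, restarting on dead ends
(capped at 10,000 attempts, after which `ScheduleError` is raised rather
than any constraint being relaxed). Whole-sequence rejection sampling is
impractical here — a uniform shuffle of 96 trials over three directions
contains about ten 3-runs in expectation, so its acceptance probability is
~5·10⁻⁵. Plans are pure functions of their integer seed.

The adaptive rule raises the session level by 0.5 (capped at L4) when the
two most recent sessions at the current level both exceed 85% in the
trials the staircase evaluates (all trials of an L1 session, otherwise the
test trials), with strict inequality and history reset on increment. The
training criterion requires, separately for each stimulus species, either
one session strictly above 90% or two consecutive sessions at or above
80%. "Above"/"over" are read strictly; the two-session branch uses ≥.

## Generative observer

Each trial's success probability is

p = g + (1 − g − λ) · logistic(η),

with guessing floor g (default 1/3: both tasks are three-alternative),
lapse rate λ (default 0), and η a linear predictor with fixed effects of
stimulus species, level (categorical, reference = lowest level present) and
polarity plus all interactions, participant-level random intercepts and
slopes drawn from independent centered normals (diagonal covariance, one SD
shared across a factor's dummy columns), and stimulus-individual random
intercepts shared across participants.

The guessing floor is deliberately absent from the *fitted* model, which is
a plain binomial GLMM: this mirrors the analysis convention for such tasks.
Consequently g > 0 attenuates logit-scale effects in the upper accuracy
range, and estimator-calibration studies (type-I error, parameter recovery)
use g = 0 configurations so that the fitted model is exactly the generating
model; the g = 1/3 presets exist to generate realistic response tables, and
their attenuation is visible in any recovery exercise run against them.

The `full-threeway` preset is parameterized so that the implied condition
means follow the qualitative behavioural pattern — accuracy falls
monotonically with level everywhere; human-stimulus accuracy stays high
while chimpanzee-stimulus accuracy collapses at L3–L4 under normal
polarity; the gap flips under reversal, most strongly at L4. Preset values
are qualitative emulations chosen on the probability scale, not fitted
coefficients.

## Statistical engine

`fit_glmm` maximizes a Laplace-approximate marginal likelihood for a
logit-link Bernoulli GLMM with crossed random factors and uncorrelated
random effects:

ℓ(β, θ) = ℓ_cond(β, b̂) − ½ b̂ᵀD⁻¹b̂ − ½ log|D| − ½ log|ZᵀWZ + D⁻¹|,

where D = diag(σ²) with σ = e^θ, b̂ is the conditional mode from a damped
Newton iteration (gradient tolerance 10⁻⁹, warm-started between
evaluations), and the outer problem runs L-BFGS-B over (β, θ) jointly with
numerical gradients, θ bounded in [log 10⁻³, log 5] and σ started at 0.1.
A derivative-free restart over θ with β profiled out rescues the rare
line-search failures caused by the numerical-gradient noise floor. With no
random terms the fit reduces exactly to Newton logistic regression.
Fixed-effect covariance is the inverse profiled information
XᵀWX − XᵀWZ(ZᵀWZ+D⁻¹)⁻¹ZᵀWX. On a representative simulated dataset the
fit agrees with a widely used mixed-model implementation to four decimals
in log-likelihood and coefficients.

Design conventions: treatment contrasts with references chimpanzee
stimulus, lowest level present, normal polarity; block and within-block
trial enter as centered numeric control covariates (a categorical coding
would add ~18 nuisance parameters per fit for no benefit at these sizes —
the controls exist to absorb slow drifts, which a linear term captures).
One variance parameter is shared across the dummy columns of a multi-level
factor's random slope. Factory specs provide the study designs: the
keypress models offer the maximal uncorrelated slope set (intercept plus a
slope per test term for participants, stimulus intercepts) or a reduced
intercept+species set; the search-task model uses session and stimulus
individual as random factors and contains no level term, since the
adaptive staircase confounds level with session.

LRTs compare nested fits with identical random structure, so df counts
fixed parameters (df = 3 for a four-level factor). χ² below −10⁻⁴ flags a
refit; smaller negatives are clipped to zero. The pruning procedure tests
the highest-order interactions first, drops nonsignificant ones, stops and
flags simple effects as soon as an interaction is significant, and
otherwise proceeds to lower-order terms. Simple effects refit within each
stratum of the conditioning factors at a caller-supplied α (e.g. 0.05/3
Bonferroni across three individuals), skipping empty or all-identical
strata with a warning.

**Dispersion** is the Pearson statistic over residual df. For Bernoulli
rows this cannot exceed 1 in expectation even under strong latent
heterogeneity (the binary variance is pinned at p(1−p)), so the function
accepts a `groupby` argument that aggregates trials into binomial clusters
(e.g. sessions) first — the form that does detect beta-binomial-style
overdispersion, and the form exercised by the overdispersion test.
Trial-level dispersion ≈ 1 remains the well-specified sanity check.

**Bootstrap CIs** are percentile intervals over units resampled with
replacement — participants for the keypress task, sessions for the search
task — with 2000 resamples by default and an explicit seed. The interval is
widened to bracket the point estimate in degenerate corners.

## Calibration studies and their scales

The test suite runs three simulation studies, sized to finish in minutes on
one core:

* **Type-I error**: 1000 null replicates of a 6-participant × 96-trial
  crossed-polarity design, testing the polarity term (which varies within
  both random factors, the regime where the χ²₁ reference is accurate);
  the rejection rate must fall in the 95% binomial band around α = 0.05.
  Factors that vary only *between* levels of a random factor (species,
  which is a between-stimulus-individual effect with 6–10 individuals per
  species) are tested against the same reference but inherit the usual
  small-cluster anticonservatism of likelihood-ratio tests; this is a
  property of the method, not of the implementation.
* **Recovery**: 100 replicates of 25 participants × 96 trials from a g = 0
  observer with moderate SDs (0.5 intercept, 0.3 species slope, 0.3
  stimulus), fit with the matching model; each generating fixed effect must
  land within ±2 estimated SE in ≥ 90% of replicates.
* **Dispersion**: well-specified fits at the same scale stay within
  [0.8, 1.2].

`scripts/acceptance.py` recomputes the same quantities at reduced
replication counts (300 type-I, 40 recovery) plus the schedule counts and
colorimetric invariances, and writes them as JSON.

## What the synthetic pipeline does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
Bernoulli outcomes, crossed heterogeneity, a chance floor — but not the
perceptual process: accuracy is stipulated per condition, not computed from
pixels, so passing tests demonstrate that the schedules, transforms and
estimator behave as specified, not that any perceptual claim about real
humans or chimpanzees is reproduced. The behavioural findings themselves
(the species × level × polarity pattern) live in behavioural data from
real participants, which this package does not contain; the
`full-threeway` preset only emulates their shape for end-to-end testing.

Other known limitations: rendering is flat-shaded (no texture, eyelashes,
or shading gradients); photograph support requires externally supplied
masks; the Laplace approximation shares the usual small-cluster biases of
that family; and the fitted model's omission of the guessing floor means
logit-scale effects from g > 0 generators are attenuated by construction.
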