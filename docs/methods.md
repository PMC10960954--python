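# Methods

## The two-pathway PLR kernel

The generator treats a pupil trace as a baseline diameter minus two
additive constriction components, each linear in its retinal drive:

```
p(t) = baseline − g_rc · d_rc · h(t) − g_ip · d_mel · s(t)
```

* `h(t)` — transient rod/cone component: zero before the onset latency
  (default 0.2 s), exponential rise (τ_rise = 0.15 s), then exponential
  adaptation (τ_adapt = 1.75 s) toward a residual fraction
  `rc_residual_frac` (default 0.3).  The residual models the re-activation
  of rods and cones by stimulus refreshes (letter changes) and
  microsaccades across sharp placeholder edges; it is the reason a
  brightness effect persists over a 15 s stream even though photoreceptors
  adapt.
* `s(t)` — sustained melanopic (ipRGC) component: zero before its own
  latency (default 3 s), saturating rise with τ_ip = 4 s.  With these
  defaults the blue-minus-red difference of isoluminant full-field
  displays is zero through the first seconds and becomes prominent from
  roughly 5 s on, reaching ≈ 0.44 mm at 15 s — the sustained-constriction
  signature that identifies melanopic involvement.

Exponential rise/decay forms were chosen as the simplest shapes satisfying
the qualitative timing constraints (200 ms transient onset, adaptation
from ~1.5–2 s, sustained component emerging ~5–10 s); nothing downstream
depends on the specific functional family, only on linearity in drive and
on the timing.

Intensity maps to drive through a power law `d = gain · (I/100)^γ` per
colour (γ = 1 by default).  Defaults `color_gain_red = 1.25`,
`color_gain_blue = 1.0` make red the stronger rod/cone driver per unit
intensity, so isoluminance matching anchors blue at 100 % (bright) and
50 % (dim) and solves for red — yielding the analytic matched set
{bright blue 100 %, bright red 80 %, dim blue 50 %, dim red 40 %}.
Melanopic weights are 1.0 (blue) vs 0.1 (red).

### Effect-size anchoring

The remaining gains were set analytically (closed-form window means of
`h` and `s` over the 15 s stimulus) so that the generating window-mean
effects under the default design are:

| quantity | value |
| --- | --- |
| direct-gaze brightness effect (bright − dim) | 0.84 mm |
| direct-gaze colour effect (blue − red, isoluminant) | 0.19 mm |
| covert-attention brightness effect | 0.21 mm (¼ of direct) |
| covert-attention colour effect | 0 |

These are the values parameter-recovery tests compare estimates against;
`pupilplr.kernel.expected_window_effects` recomputes them from any
parameter set.

### Attention and placeholders

In the dual-stream task the scene drive of each pathway is

```
d = placeholder_scale · (w · d_attended + (1 − w) · d_ignored)
```

with `w ∈ [0.5, 1]` (0.5 = the two streams contribute equally, i.e. no
attentional weighting).  The placeholder scale expresses that the small
peripheral placeholder circles drive the pupil far less than the
full-field displays used for calibration and validation.  Defaults:
`attention_weight_rc = 0.75` and `placeholder_scale_rc = 0.366`, jointly
calibrated so the covert brightness effect is one quarter of the direct
one; `placeholder_scale_ip = 0`, making the covert colour contrast an
exact null — the empirically observed covert colour difference in this
paradigm is negligible, and a true null is what the type-I-error
validation of the time-series test requires.  Researchers simulating a
genuine covert melanopic effect can raise `placeholder_scale_ip` and
`attention_weight_ip`.

Note that with a non-zero melanopic placeholder scale the attended-colour
contrast is not a pure attention effect: same-colour pairs (blue/blue vs
red/red) differ physically, so the contrast mixes attentional weighting
with display differences at any `w`.  This is a property of the crossed
design itself, not of the simulator.

### Nuisance processes

Per-sample white noise (0.05 mm), a random-walk drift scaled to a 0.3 mm
standard deviation at the trace end, Poisson blinks (0.1 Hz, 0.1–0.3 s,
recorded as invalid samples with zeroed pupil), Gaussian gaze jitter
(0.5°), planted fixation breaks (default probability 0.105; amplitude
9–13°, duration 0.25–0.5 s so that at least one block of the
×10-downsampled gaze record is fully covered even at a 100 Hz acquisition
rate), planted extreme baseline offsets (±2.5 mm, probability 0.02),
participant-level baseline (SD 0.5 mm) and lognormal gain (CV 0.15)
random effects, and trial-level baseline jitter (SD 0.15 mm).  Behavioural
correctness is condition-independent at 0.8.  Everything stochastic is a
pure function of (params, design, participant, seed).

What the generator does **not** emulate: saccade kinematics and
pupil-foreshortening artifacts, luminance history beyond trial onset
(each trial starts at baseline), oscillatory hippus, asymmetric blink
artifacts (partial occlusion is represented only through the
interpolation margins), and any dependence of behaviour on condition.
Passing recovery tests therefore show that the analysis chain is correct
and calibrated for data with this covariance structure, not that it is
robust to every artifact of real recordings.

## Preprocessing

Fixed order: blink interpolation → ×10 block-mean downsampling → affine
arbitrary-units-to-mm conversion → per-trial baseline correction (mean
over the first 50 ms after stream onset) → gaze exclusion → baseline
outlier exclusion.  Choices:

* Blink interpolation uses a cubic through four anchor points placed one
  and two margins (50 ms) outside the invalid run; anchor values are
  short local means, which keeps the interpolant at the noise floor
  instead of chasing single noisy samples.  Edge-touching runs are filled
  by nearest-valid extension.  Validity flags are preserved for audit.
* Gaze exclusion removes a trial iff Euclidean deviation exceeds 6.93°
  continuously for strictly more than 10 ms within the stream interval
  (a run of exactly 10 ms is retained).  It is idempotent.
* Baseline z-scores are computed within participant — between-participant
  pupil-size differences would otherwise dominate the criterion.  This is
  an interpretation choice; the rule is |z| > 2, applied once (it is not
  idempotent, since removing trials shifts the z-scores).  Participants
  with fewer than three trials or zero variance contribute no exclusions.
* Trials that cannot be preprocessed at all (no valid samples, empty
  baseline window) are counted with their own reason code in the
  exclusion report, which partitions the input exactly.
* The second ×10 downsampling used by the time-series test is applied
  after baseline correction, on the 100 Hz grid.

## Calibration

The constriction template is `T(s) = −(s^k e^{k(1−s)})` (k = 3): zero at
onset, minimum −1 at s = 1, partial recovery after.  Any smooth unimodal
constriction profile works under the four-parameter transform
`v + a·T((t−τ)/σ)`; this parametric stand-in replaces an empirical
template.  Fitting is bounded least squares (τ ∈ [0.1, 0.6] s around the
physiological latency, σ ∈ [0.1, 3] s, a ≥ 0) over the flash + post-flash
window, with a coarse (τ, σ) grid multi-start solving the inner linear
(v, a) problem analytically before a full four-parameter polish;
non-convergence is flagged and such fits are dropped from the intensity
table rather than imputed.  The two presentations per intensity enter as
their mean.

Strength-vs-intensity is summarised per colour by an OLS quadratic
(≥ 3 distinct intensities required).  Matching solves the quadratic
`c(I) = target` analytically, keeping roots in [0, 100] on the increasing
branch (dc/dI > 0), ties toward the larger intensity; the 250 ms flash is
modelled with the same sustained kernel, a deliberate simplification —
over a 3.25 s window the response shape is dominated by the PLR dynamics,
and only linearity of strength in drive matters for matching.

Eligibility surrogates (the entry criteria are judgment calls in human
studies; here they are automated and configurable): calibration requires
both curves increasing over [0, 100] with r² ≥ 0.7; validation requires
the red-minus-blue mean over the last 5 s of the stimulus to exceed
0.05 mm in both brightness conditions (bright only, for the follow-up
variant).

## Statistics

* `WindowLME`: REML linear mixed model of the per-trial window mean with
  a two-level factor and by-participant random intercept + slope.  On a
  singular or non-converged fit the structure is relaxed (uncorrelated,
  then intercept-only) and logged.  Contrasts use treatment coding with
  dim/red as reference, and pupil coefficients are reported
  constriction-positive (the raw coefficient is negated; |statistic| and
  p are unchanged).  Wald statistics are referred to the normal
  distribution, the convention of the mixed-model tooling this field
  uses.
* `CrossValTimeSeriesTest`: trials are assigned to folds per participant,
  round-robin after a seeded shuffle, so every fold holds every
  participant when trial counts allow.  For each fold the factor's |z| is
  scanned over every sample of the window on the training folds
  (random-intercept-only fits: the scan only ranks candidate samples, the
  inference happens on held-out data; the originally intended
  intercept+uncorrelated-slope scan structure proved numerically fragile
  and much slower in statsmodels, falling back to intercept-only anyway).
  Ties localize at the earliest sample.  Each held-out trial then
  contributes its pupil value at its fold's localized sample to a single
  pooled LME with the full random intercept + slope structure.  Null
  simulations at 10 participants × 40 trials (the reproduction script
  recomputes one) put the rejection rate at or slightly below the nominal
  5 % — the procedure is calibrated to mildly conservative, never
  anticonservative.
* `AccuracyGLME`: binomial mixed model with logit link, colour ×
  brightness fixed effects and by-participant random intercepts and
  slopes per fixed effect, fitted by statsmodels' Laplace (MAP)
  approximation — its posterior SDs track likelihood-based standard
  errors, whereas the mean-field variational fit underestimates them
  substantially.  A constant outcome (e.g. all trials correct) raises a
  separation error instead of returning a degenerate fit.  Single-level
  factors (the bright-only follow-up) are dropped with a log message.

## Problem sizes

The packaged validation studies use: one noiseless participant at 1 kHz
for calibration matching and template checks; 30 participants × (28
validation + 224 main) trials at 1 kHz for effect recovery; and
scaled-down replicates at 100 Hz (10 × 40 for 200 null replicates,
30 × 40 for 50 power replicates), whose two ×10 downsampling steps give a
1 Hz analysis grid of 15 scan points over the stream.  These sizes keep a
full validation run in the tens of minutes on a single core while leaving
every statistical property measurable.

## Known limitations

* The melanopic placeholder drive defaults to zero; simulating partial
  covert melanopic effects requires choosing `placeholder_scale_ip` and
  `attention_weight_ip` yourself, and the attended-colour contrast then
  carries a physical component (see above).
* The mm conversion is a configurable affine map; real trackers need a
  lab-specific formula, so slope/intercept are data, not constants.
* The accuracy model's MAP standard errors are approximations; for
  publication-grade behavioural inference a likelihood-based GLMM (lme4)
  is the reference.
* Stimulus-offset dynamics are not modelled (validation traces hold their
  last stimulated value after offset); analyses never use the post-offset
  segment.
* Sample indices reported by the time-series test refer to the package's
  own twice-downsampled grid (seconds are reported alongside); they are
  not comparable across acquisition rates.
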