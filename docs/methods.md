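# Methods

## Stimulus model

A limited-dot-lifetime display (LDD) holds exactly `n_dots` dots visible
at every instant. Each dot lives for `lifetime_ms` (default 300 ms); on
expiry it is removed and a replacement appears at the same instant at a
fresh random position, so the alive count is conserved by construction.
The initial scatter draws each dot's *first* expiry uniformly on
[0, lifetime), which desynchronizes replacements; every subsequent life
lasts exactly one full lifetime.

Positions are uniform over the stimulus region conditional on all
pairwise center-to-center distances being at least `min_dist_deg`
(default 0.80 deg), via rejection sampling with a per-dot attempt cap
and whole-layout restarts; if the requested density is infeasible in
practice a `PackingError` names the exclusion-disc density. One-group
arrays use a single 8 × 8 deg square (64 deg²). The two-group
spatially-clustered array uses two 32 deg² squares with centers 8 deg
apart, rigidly rotated about their midpoint by an angle drawn uniformly
on [0, 2π) per trial.

Time advances on a fixed tick (default 60 ticks/s, matching common
display refresh practice); a dot expires at the first tick at or after
its scheduled expiry. Because 300 ms is an exact multiple of the
1000/60 ms tick, completed lives in the default configuration last
exactly 300 ms; with incommensurate tick rates they are accurate to one
tick.

Motion: in the two-group motion condition, group 0 moves at
`motion_speed_deg_per_s` (default 1.5 deg/s) in a uniformly random
direction and group 1 exactly antiparallel; the one-group motion
condition gives all dots one shared random direction (consistent with
the per-group coherence of the two-group condition — the original
direction scheme for this condition is not specified, and this is the
simplest coherent choice). Two boundary decisions that the task
description leaves open:

* the minimum-distance constraint is enforced at spawn only, not
  continuously under motion (moving dots may transiently approach);
* spawn positions of moving dots are inset from the square edge by the
  maximum travel per life (speed × lifetime = 0.45 deg), so no dot ever
  leaves its region — avoiding wrap/bounce artifacts at the cost of a
  slightly smaller effective spawn area.

Two-group dot counts: one group receives `n/2 + k` dots with `k`
uniform on {−2, −1, 0, 1, 2} (even totals only, as used in practice).

## Task procedure

Experiment 1 crosses four grouping features (spatial, size, color,
motion) × {one, two groups} × {16, 20} dots × 8 repetitions (128
trials, shuffled per subject). The response array is fixed: blue,
0.50-deg, stationary, one 8 × 8 deg group; the one-group spatial (=
baseline) test array is identical to it. Feature values: one-group size
1.0 deg; two-group size 0.25/1.0 deg; colors yellow/blue; motion
1.5 deg/s.

Experiment 2 fixes the test array (10/15/20 dots, 0.20 deg, 64 deg²)
and scales the *response* array's total area and dot size each by
{0.5, 1, 2} (3 × 3 × 3 × 3 repetitions = 81 trials). Half the subjects
(alternating by subject index) see yellow test/blue response dots, half
the reverse.

The initial response count is uniform on integers
[round(n/2), round(3n/2)] — reproducing the stated 8–24 and 10–30
ranges for 16 and 20 and generalizing to Experiment 2's numerosities,
whose starting rule is not stated. Adjustment is modeled as unit steps
toward the observer's internal target, clamped to [0, 50]; since only
the final setting enters any analysis, exploratory dithering is not
modeled. A 200-press cap guards against non-termination.

## Observer model

The generative observer is the simplest model producing every effect
direction the analyses are designed to detect; its functional forms are
a modeling choice, not an empirical claim.

| parameter | meaning | default |
|---|---|---|
| `weber_fraction` w | estimate noise sd = w·n (scalar variability) | 0.15 |
| `area_exponent` α | area bias (A/64 deg²)^α, larger area → more | 0.2 |
| `size_exponent` β | size bias (d/0.50 deg)^(−β), larger dots → fewer | 0.135 |
| `grouping_gains` g_f | test-side multiplier when seen as two groups | spatial 1.08, size 1.0, color 0.95, motion 0.95 |
| `lapse_sd` | response jitter (dots) | 0.5 |

Defaults are calibrated to the reported human effect magnitudes: w =
0.15 is a typical adult Weber fraction for this range; β = 0.135 makes
doubling dot diameter lower perceived numerosity by ≈9 % (the measured
one-group large-dot effect, −1.22 dots at 16 and −2.18 at 20); the
color and motion gains of 0.95 give the ≈ −4…−5 % two-group effects;
g_spatial = 1.08 carries the +1.3…+1.8-dot spatial effect (in this
model the two-group spatial region totals 64 deg², so the area power
law cannot produce it); α = 0.2 is a moderate value — only the
*direction* of the area effect is reported, not its size. Between
subjects all parameters are log-normal; the grouping-gain log-sd of
0.08 together with ρ_cm = 0.6 yields an observed (attenuated)
color–motion effect-size correlation of r ≈ 0.3–0.45 at n = 55,
bracketing the published r = 0.378.

Responses: the observer perceives the test array once per trial
(noisily), then targets `round(perceived / bias_response)`, where
`bias_response` is the response array's own area/size bias — i.e. it
equates *perceived* numerosities. Grouping gains act on the test array
only (the response array is always one group). The two-group size
array's scalar diameter is the geometric mean of its two diameters
(0.25, 1.0 → 0.50 deg = baseline). A consequence worth knowing: a
single power law then predicts a two-group-vs-one-group size effect of
+2^β − 1 ≈ +10 %, somewhat larger than the measured +5 %; the size
conditions confound feature- and grouping-driven effects and the model
makes no attempt to separate them.

Seeding: a master seed spawns one stream per subject, and each subject
stream spawns (parameters, design, trials) substreams, so adding
subjects never perturbs earlier subjects' data.

### What the generator does and does not emulate

It emulates Weber-law response noise, the four feature/grouping bias
directions, the response-side area/size manipulanda, between-subject
heterogeneity, the color–motion correlation, and the counterbalancing.
It does **not** emulate sequential effects, learning or fatigue, lapses
of attention beyond Gaussian jitter, density/crowding mechanisms, or
left/right spatial biases. Passing pipeline tests therefore shows the
analysis chain is correct and well-powered under the assumed structure
— not that human data obey that structure.

## Statistics

* **PSE**: mean final setting per subject × condition × numerosity;
  empty cells stay missing.
* **Effect size**: (M_two/M_one − 1) × 100 %, computed per set size and
  then averaged across the two set sizes, one value per subject ×
  feature.
* **JZS t-test BFs**: the standardized effect carries a Cauchy(0,
  0.707) prior (the common default; the original analyses' prior
  settings are not stated). The marginal likelihood is a 1-d adaptive
  quadrature of the noncentral-t likelihood over the prior
  (`epsabs 1e-12 / epsrel 1e-10`; non-convergence raises). Directional
  BFs reuse the same half-integrals (half-Cauchy = doubled one-sided
  piece), so (BF+0 + BF−0)/2 = BF10 holds to machine precision. Tests
  validate against an independent dense-trapezoid oracle and against
  pingouin's closed form.
* **Correlation BFs**: exact sampling density of r (via ₂F₁) integrated
  over a stretched-beta prior on ρ (width κ = 1 → uniform); one-sided
  variants truncate and renormalize the prior. |r| = 1 returns an
  infinite BF rather than an error.
* **RM-ANOVA**: balanced designs only (it raises naming the first
  missing cell). Implemented from per-subject marginal-mean projections
  — each within effect is tested against its interaction with subjects
  (nested in the between-subjects group where present) — because no
  installed package covers 3 within factors plus a between factor.
  Validated exactly against statsmodels `AnovaRM` (pure within) and
  pingouin `mixed_anova` (1 within + 1 between). Greenhouse-Geisser ε
  from the pooled covariance of the effect scores; Huynh-Feldt from the
  standard correction of ε_GG, clipped to [ε_GG, 1].
* **Inclusion BFs**: `bf_inclusion_approx` compares two fixed-effect
  OLS models (subject as a blocking factor; all effects not containing
  the target, with vs without the target) by exp(ΔBIC/2). It is a
  deliberately crude surrogate for model-averaged inclusion BFs and is
  labeled approximate everywhere; magnitudes should be read as orders
  of evidence only.
* **Evidence labels**: none (=1), anecdotal (≤3), moderate (≤10),
  strong (≤30), very strong (≤100), extreme (>100); BF < 1 is labeled
  by its reciprocal with an "(H0)" suffix.
* No multiple-comparison correction is applied anywhere, matching the
  analysis battery this package mirrors; interpret families of tests
  accordingly.

Degenerate inputs: paired tests raise on zero-variance differences
(including identical samples); correlations raise on constant input;
effect sizes raise on a non-positive one-group mean.

## Problem sizes

The test suite and the reproduction script run the study-scale designs
(55 subjects × 128 trials; recovery uses 20 replicate simulations;
stimulus checks simulate 10-s displays at 60 ticks/s and 100 seeded
5-s displays), which completes in well under a minute per component on
one CPU.

## Known limitations

* Continuous min-distance enforcement under motion (if the original
  software did it) is not modeled.
* The stated two-group spatial geometry is internally inconsistent in
  its source (32 deg² squares vs a 2 × 38 deg² total); the Methods
  value (32 deg² each) is used, and the discrepancy is absorbed into
  g_spatial.
* JASP-exact ANOVA inclusion BFs and sphericity-corrected JASP parity
  are out of scope; frequentist quantities match reference
  implementations exactly, the inclusion BF is approximate.
* The optional re-analysis of the archived human dataset requires
  downloading it separately; the loader expects the same tidy CSV
  schema the simulator emits.
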