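# Methods

## The task and its measures

In a tactile temporal-order-judgment (TOJ) task two vibrotactile stimuli
are delivered, one to each hand, separated by a signed stimulus onset
asynchrony (SOA, ms; negative = left hand first), and the participant
reports which hand was stimulated first. Judgments are collected with the
arms uncrossed and crossed over the body midline. Two quantities summarise
each participant's performance per posture:

- **PSS** (point of subjective simultaneity): the SOA at which both orders
  are reported equally often. We work on an *affected-frame* axis
  `u` = lead time of the unaffected hand (`u > 0` ⇔ unaffected hand first),
  so a positive PSS always means stimuli on the affected (painful) limb are
  prioritized, for left- and right-affected participants alike. This
  replaces the usual post-hoc sign flip for right-affected participants.
- **JND** (just noticeable difference): the interval needed for 75% correct
  order discrimination, a sensitivity measure.

## Estimation pipeline

Per participant and posture:

1. the proportion `p(u)` of affected-first reports is tabulated at each of
   the 10 SOAs (±10, ±30, ±55, ±90, ±200 ms; 12 trials each in the standard
   design);
2. proportions are converted to probits, `z = Φ⁻¹(p)`;
3. an unweighted least-squares line `z = a + b·u` is fitted;
4. `PSS = −a/b` and `JND = 0.675/b` (the constant is the conventional
   rounding of `Φ⁻¹(0.75) = 0.6745`; the magnitude `|JND|` equals half the
   distance between the line's 25% and 75% crossings to within 0.1%).

Because the probit of a cumulative normal is exactly linear, feeding the
pipeline exact lapse-free probabilities returns the generating parameters
(`PSS = pss_true`, `|JND| = 0.675·σ`) to machine precision; this closed-form
identity is a standing test.

**Extreme proportions.** Observed `p ∈ {0, 1}` have infinite probits. The
default rule clips `p` into `[1/(2n), 1 − 1/(2n)]` (n = trials per SOA);
`clip=None` disables it for exact-probability inputs. The rule is the only
consequential numerical choice in the pipeline: at σ = 100 ms the ±200 ms
points saturate (`|z| ≈ 2–2.5`) and are pulled toward `Φ⁻¹(23/24) ≈ 1.73`,
which inflates non-zero PSS estimates by roughly 5% (≈ +3 ms at a true PSS
of 50 ms, measured by Monte Carlo and by fitting the exact expected
probits) and biases JND magnitude upward. The effect grows as σ shrinks
relative to the SOA range. We keep the rule because the raw estimator is
undefined without some treatment of saturated cells and this one is simple,
standard and documented; the recovery harness quantifies its cost.

The fit is deliberately the least-squares line on probits, not a
maximum-likelihood probit GLM: it is the procedure the measures are defined
by. An ML probit fit appears only as an independent cross-check in the
test suite.

## Generative observer and cohort simulator

The simulator exists so every stage is testable without any data download,
and so estimator quality (bias, RMSE, parameter recovery) can be quantified
under the exact experimental design.

A subject is a cumulative-normal observer:
`P(affected first | u) = lapse/2 + (1 − lapse)·Φ((pss_true − u)/σ_p)`,
with `σ_p = σ·crossed_sigma_factor` when crossed. Defaults: σ = 100 ms
(subject-level log-normal spread 0.25), `crossed_sigma_factor` = 2.2
(crossing the arms roughly doubles the discrimination threshold — the
crossed-hands deficit; modelled purely as σ scaling, the simplest mechanism
that yields the posture effect on JND), lapse = 0.02.

The default cohort reproduces the study conditions: 14 CRPS, 15 shoulder
and 16 wrist-pain patients; pain duration log-normal with means 10/24/24
months; pain intensity truncated normal (mean 5, SD 2) on 0–10; hand
temperature difference normal (mean 0.3 °C, SD 1 °C) with 2 CRPS and
3 wrist records missing. Covariate effects on the true PSS use the reported
magnitudes: +12.25 ms/°C (wrist), −37.69 ms/°C temperature-by-posture
interaction (shoulder), −0.74 ms/month pain duration (wrist); residual
between-subject PSS spread 30 ms. These are generator settings, not
estimates — the study's group-level coefficients depend on its raw data and
are not reproduced here.

Missing temperatures are generated by drawing a latent value, using it
generatively, and masking it in the exported metadata; imputation then
substitutes the group median, as in the analysis pipeline.

Seeding: one master seed; subject `i` uses stream `master_seed + i`, and
the start posture alternates with subject index (even → uncrossed first) as
a deterministic counterbalance. All outputs are pure functions of
(config, seed).

**What the simulator does not emulate**: response times, experimenter
transcription errors, arm-on-top effects, drift or learning across blocks,
posture-dependent lapse rates, and any non-Gaussian shape of the underlying
psychometric function. Passing tests therefore validate the estimator and
filters under a well-specified observer model, not the clinical claims of
any particular dataset.

## Staircase intensity matching

Stimulus intensity is matched between hands by a two-part double random
staircase (16 trials per part, two interleaved staircases of 8 trials
starting high and low). The published description does not fix the update
rule, so this implementation chooses, for determinism and testability:
fixed step of 10% of the 0.21 W maximum, one step toward rating 3 after
each trial (down if rated > 3, up if < 3), no step halving, levels clamped
to (0, 0.21 W]. The selected intensity is the level whose mean rating is
exactly 3 (lowest on ties), otherwise linearly interpolated between the two
bracketing levels, falling back to the closest level when 3 is outside the
observed range. Whether the original procedure averaged per level or fitted
a curve is unstated; the interpolation rule is this package's decision.
With a deterministic monotone rating model the selection converges to
within one step of the model's anchor from any admissible start levels
(property-tested).

## Exclusion filters and statistics

Fitted values are flagged, never dropped:

- criterion 1: |PSS| < 400 ms (twice the largest SOA), per posture;
- criterion 2: > 60% correct at ±200 ms in *both* postures — read as a
  subject-level condition, so failing it in either posture flags both
  postures' values;
- sensitivity flag: |JND| ≤ 200 ms.

The difference in flagged proportions between postures is tested with a
Pearson χ² for equality of proportions *without* continuity correction
(10/45 vs 0/45 gives χ² = 11.25 only uncorrected, which fixes the variant).
Group-level PSS tests are two-sided one-sample t-tests against 0 with 95%
CIs (α = 0.05); `t_from_summary` inverts a reported (mean, CI, df) triple
to its t statistic via `SE = (CI width)/(2·t_crit)`.

The recovery harness simulates observers through the full schedule and
pipeline and reports per-condition bias, RMSE and Monte-Carlo SE of the PSS
and JND estimators. At the design scale (σ = 100 ms, 12 trials per SOA per
posture) the PSS estimator is unbiased at a true PSS of 0 by symmetry, and
carries the ≈5% clip-induced inflation at ±50 ms described above; RMSE is
≈ 13–17 ms and shrinks when repetitions per SOA are doubled.

## Problem sizes

Simulation-based checks use 500 simulated subjects per recovery condition
and 200 replicate cohorts of 45 subjects for the posture-effect check —
sizes at which Monte-Carlo error is small relative to every asserted
effect while a full run stays comfortably interactive.

## Known limitations

- The probit-line estimator is consistent but not unbiased at finite trial
  counts; users comparing small shifts near the SOA range boundary should
  prefer the recovery harness's bias estimates over a no-bias assumption.
- Criterion 2's subject-level reading is one of two defensible readings of
  "in both postures"; the per-posture alternative changes which uncrossed
  values survive.
- The staircase's update rule is a reconstruction of an under-specified
  procedure; only its qualitative behaviour (convergence to the anchor,
  determinism) should be relied on.
- Linear mixed-effects modelling of the resulting tables is out of scope;
  the analysis table is exported in a form any LMM tool consumes directly.
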