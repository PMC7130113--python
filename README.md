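# tactoj

Simulation and analysis of tactile **temporal-order-judgment (TOJ)**
experiments in unilateral chronic-pain populations (complex regional pain
syndrome and non-CRPS control groups), with the arms uncrossed or crossed
over the body midline.

In a TOJ trial two vibrotactile stimuli are delivered, one per hand,
separated by a signed onset asynchrony (SOA); the participant reports which
hand was stimulated first. Two per-subject, per-posture measures summarise
performance:

- **PSS** — the point of subjective simultaneity, the SOA at which both
  orders are reported equally often. Positive values mean stimuli on the
  affected (painful) limb are prioritized.
- **JND** — the just noticeable difference, the interval needed for 75%
  correct discrimination (a sensitivity measure; it grows sharply when the
  arms are crossed — the crossed-hands deficit).

Estimation follows the classical probit procedure: with `u` the lead time
of the unaffected hand, the affected-first proportion `p(u)` at each of the
10 SOAs (±10, ±30, ±55, ±90, ±200 ms) is transformed to a z-score
`z = Φ⁻¹(p)` and an unweighted straight line `z = a + b·u` is fitted; then

```
PSS = −a / b        JND = 0.675 / b
```

The package provides, as importable modules and a thin `tactoj` CLI:

- `design` — the 4 × 60-trial main schedule and the three practice blocks;
- `observer` — cumulative-normal observers (`P(affected first | u) =
  lapse/2 + (1−lapse)·Φ((PSS_true − u)/σ)`, with σ scaled up when crossed)
  and a 45-subject synthetic cohort generator with covariate effects
  (temperature difference, pain duration) on the true PSS;
- `staircase` — the two-part double random staircase that matches
  vibrotactile intensity between hands;
- `psychometric` — the probit pipeline above;
- `qc_stats` — exclusion filters (|PSS| < 400 ms; > 60% correct at ±200 ms
  in both postures), the χ² test on exclusion proportions, one-sample /
  paired t-tests, reconstruction of t statistics from reported (mean, CI,
  df) summaries, and a bias/RMSE parameter-recovery harness;
- `io` / `cli` — validated CSV interchange and the command-line surface.

No experimental data are required: the simulator generates cohorts with the
statistical structure the analysis assumes, so every stage is testable and
the estimators' bias and RMSE can be quantified under the exact design.

## Worked example

```
tactoj simulate --seed 1 --out demo
tactoj fit   --trials demo/trials.csv --meta demo/meta.csv --out demo_fit
tactoj qc    --trials demo/trials.csv --meta demo/meta.csv --out demo_qc
tactoj stats --table demo_qc/analysis_table.csv --out demo_stats
```

`simulate` writes a 45-subject cohort (14 CRPS, 15 shoulder pain, 16 wrist
pain; 240 trials each). `fit` estimates the probit line per subject and
posture (`demo_fit/summaries.csv`):

```
subject_id,posture,slope,intercept,r_squared,pss_ms,jnd_signed_ms,jnd_mag_ms,pct_correct_200
C01,crossed,-0.005942,-0.053141,0.731998,-8.942983,-113.594271,113.594271,0.833333
C01,uncrossed,-0.008089,-0.095227,0.842813,-11.772413,-83.446979,83.446979,1.0
```

Subject C01's PSS is −11.8 ms uncrossed (a slight prioritization of the
unaffected hand) and the JND magnitude rises from 83 ms uncrossed to 114 ms
crossed — the crossed-hands deficit the simulator builds in. `stats` then
tests the group-mean PSS against 0 per group and posture
(`demo_stats/one_sample_t.csv`):

```
group,posture,n,mean_pss_ms,ci_low,ci_high,t,df,p_value
CRPS,uncrossed,14,-1.265934,-26.675425,24.143556,-0.107632,13.0,0.915931
wrist,uncrossed,16,-22.790577,-38.113878,-7.467276,-3.170137,15.0,0.00634
```

The CRPS group shows no reliable bias (t(13) = −0.11, p = 0.92); this
simulated wrist group happens to prioritize the unaffected hand
(mean PSS ≈ −23 ms), driven by the built-in temperature and pain-duration
effects. `demo_qc/analysis_table.csv` holds the flagged per-subject ×
posture rows ready for any mixed-model tool.

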