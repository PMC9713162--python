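# Methods

## The cohort model

`surgdelay.model_core` implements a deterministic three-state cohort
state-transition model. States are preoperative, postoperative and dead;
the cycle length is one week, which represents every delay scenario
(expressed in weeks) exactly and makes the 50-week loss window an integer
number of cycles. The trace runs from the cohort's mean age to age 100;
survivors at the horizon contribute no further time. The number of cycles
is `floor(52 · (100 − age))`, rounded down so accumulated life years never
exceed the horizon.

Assumptions, all deliberate simplifications:

- **Constant hazard.** A survival probability *s* over a declared horizon
  of *h* years (default 1; the CSV schema carries `surv_horizon_years` so
  5-year oncology survival can be declared per row) converts to a constant
  weekly death probability 1 − *s*^(1/(52·h)). No age-dependence within a
  state.
- **No perioperative mortality.** The surgery transition moves all
  surviving preoperative occupancy to the postoperative state in full.
- **Step-function benefit expiry.** If the delay is at or beyond
  `t_no_effect_surv` (`t_no_effect_qol`) the postoperative death
  probability (utility) reverts to the preoperative value. The threshold
  is inclusive and the waning is all-or-nothing; no gradual shape is
  modelled.
- **No discounting, no half-cycle correction, no age weighting.** All are
  configuration-extensible in principle but deliberately absent by
  default; outcomes are undiscounted sums of weekly occupancy.

Accounting convention: occupancy alive at the *start* of week *k*
contributes 1/52 years for that week, weighted by the utility of the state
occupied during it. With a constant hazard this makes cohort QALYs a
finite geometric sum, which the tests verify against the closed form.

Losses: DALY/month = [QALY(2 wk) − QALY(52 wk)] · (52/12)/50, i.e. the
loss per 50 weeks of delay scaled to a month of 52/12 weeks; YLL/month is
the analogous life-year difference. Computing the DALY loss as a QALY
difference (disability weight = 1 − utility) over the common horizon
avoids choosing an external reference life table. Note that YLL/month may
*exceed* DALY/month: when utilities are below 1, a death forfeits more
life years than QALYs, so a procedure with a pure survival benefit at
utility *u* has DALY = *u* · YLL. The two measures agree exactly at full
health, which is tested.

Cancellation loss is reported as a *total* (QALY and LY difference between
the 2-week delay and never operating), not per month.

## Probabilistic sensitivity analysis

`psa_engine` assigns Beta distributions to probabilities and utilities and
Gamma distributions to the positive time-to-no-effect durations — the
conventional choices for these supports. Uncertainty is declared per
parameter either as 95% bounds (the Beta concentration is fitted by least
squares on the 2.5th/97.5th percentiles, mean held exact) or as a relative
standard error, default 0.1 of the mean. Mean age is held fixed unless an
uncertainty spec names it.

Numerical choices:

- For a relative-SE Beta, sd = rse·m is capped so the concentration
  α + β stays ≥ 3: for means near 1 the nominal sd is infeasible or
  implies a U-shaped density piling at the endpoints, and the cap keeps
  the draw unimodal rather than aborting. Point masses (mean exactly 0 or
  1, or zero-width bounds) bypass sampling entirely, which also makes the
  degenerate PSA reproduce the deterministic loss bit-exactly.
- Each surgery gets an independent random stream seeded from
  `SeedSequence([master_seed, sha256(surgery_id)])`, so adding or removing
  a surgery never perturbs another surgery's draws and results are
  order-invariant.
- Summaries are the draw mean and the 2.5/97.5 percentiles
  (`numpy.percentile`, linear interpolation); n_draws defaults to 1000.
- Ranks are assigned by descending mean DALY/month with ties broken
  alphabetically by `surgery_id` — deterministic and documented, since
  ties are measure-zero but must not depend on input order.
- Rankings are compared with Spearman's rho (average-rank ties).

## Delphi elicitation and panel validation

`delphi_qol` maps VAS to utility linearly (VAS/100; 0 anchors at death,
100 at best imaginable health). Per (surgery, state) item:

- the **feedback statistics** shown between rounds are the median and the
  linearly interpolated 25th/75th percentiles of the round-1 scores;
- the **panel point estimate** is the mean of final-round individual
  utilities (a rater who skipped round 2 contributes their round-1 score);
  the median is available via `aggregate="median"`. The mean is the
  conventional utility aggregate; the elicitation literature uses the
  median only for feedback display.
- the **combined estimate** pools raters of all panels with equal weight
  per rater (not an average of panel means), so a larger panel counts
  proportionally more.

Two-panel validation:

- **Bland–Altman**, per health state, on the panel-level point estimates
  (one pair per surgery): bias = mean difference (first-listed reference
  panel minus comparison), limits = bias ± 1.96 × sample (n−1) sd.
- **Mixed-effects difference**: final-round rater-level utilities are
  modelled with a fixed intercept, a fixed comparison-panel indicator and
  a random intercept per (surgery, state) item (per surgery via
  `grouping="surgery"`), fitted by REML with statsmodels' MixedLM; the
  reported effect is reference minus comparison with a Wald 95% interval.
  When the within-cell residual noise is numerically zero REML is
  singular, so the (then deterministic) per-item gap is returned exactly
  with a degenerate interval — this is what the zero-noise synthetic
  checks exercise.
- **Ranking stability**: the PSA chain is run twice, once per panel's
  utilities, and the two rankings are correlated with Spearman's rho.

## The synthetic-data generator

No registry parameters or raw panel ratings are redistributable, so
`synthetic_data` emulates their structure with known ground truth.
Default `TruthSpec`: 28 procedures; cohort ages uniform on 40–80 years;
one-year preoperative survival 0.85–0.99 with surgical survival gains of
0–0.04 (semielective conditions are not acutely lethal and surgery rarely
shifts annual survival by more than a few points); preoperative utilities
0.30–0.80 with gains 0.05–0.30 (capped at 1); a time-to-no-effect limit
on each of survival and QoL present independently with probability 8/28,
uniform on 26–104 weeks. These ranges keep most DALY/month values on the
few-hundredths scale typical of semielective surgery, with larger values
only where a time limit binds inside the 52-week window — a real feature
of such models, where the loss jumps to the whole forfeited benefit.

Default `DelphiDesign`: panels of 15 and 11 raters; rater noise sd 5 VAS
points; no systematic panel shift; round-2 scores shrink with weight
λ = 0.3 toward the item's round-1 panel median, mirroring the
median/IQR feedback mechanism qualitatively. Out-of-range draws are
clipped to [0, 100] rather than resampled — simpler, with a small,
documented bias toward the interior at the scale ends. The shrinkage
target is the rater's *own panel's* median, since each panel runs its own
Delphi.

What the generator does **not** emulate: real registry marginals and
correlations between parameters, rater-specific biases (optimists/
pessimists), attrition between rounds, and non-Gaussian rating noise.
Passing tests therefore demonstrate correctness of the computational
chain and statistical calibration under idealised noise, not agreement
with any real cohort.

`reference_case()` ships a five-cycle toy (age 99.9, weekly death
probabilities exactly 0.1/0.05, surgery at week 2) whose occupancy, life
years and QALYs are hand-computed decimals, used for exact regression
tests of the chain arithmetic.

## Problem sizes

The test suite and the acceptance script run the study at its natural
size: 28 procedures, 1000 PSA draws, 15 + 11 raters; the mixed-model
calibration check uses 100 simulation replicates at that design. A full
acceptance run takes a few seconds on one core; the whole suite well
under a minute.

## Known limitations

- Constant hazards ignore ageing within a state; for young cohorts
  followed for decades this understates late-life mortality.
- The step-function benefit expiry creates a discontinuity in the delay
  curve at the threshold, which dominates the PSA spread for procedures
  whose limit falls inside the 52-week window.
- The Bland–Altman analysis operates on panel-level estimates (n = number
  of surgeries per state); rater-level agreement is out of scope.
- Utilities from a VAS are taken at face value; no transformation to
  time-trade-off or standard-gamble scales is applied.
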