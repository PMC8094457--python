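# Methods

This note documents the models implemented in `uroecon`, the synthetic
study conditions they are exercised under, and the numerical and design
choices a user should know before trusting or changing them.

## Study design emulated

A pragmatic two-arm 1:1 randomised trial of open urethroplasty versus
endoscopic urethrotomy for recurrent bulbar urethral stricture, with a
binary minimisation stratum (time since last procedure < 12 vs ≥ 12
months), 24 months of follow-up, EQ-5D-5L collected at eleven scheduled
points (baseline; immediately pre-surgery; 1 week after catheter
removal; 3, 6, 9, 12 and 24 months post-surgery; 18 and 24 months
post-randomisation; end of study), and resource use recorded on
six-monthly recall instruments. Analysis is by intention to treat.

## Synthetic data generator

`synthdata.simulate_trial` draws, per patient:

- allocation (exactly n/arm), stratum (Bernoulli), crossover of the
  received procedure (default 5 %), and a small probability of never
  receiving the index procedure (default 5 %);
- waiting time randomisation→surgery, uniform integer days per
  procedure (urethroplasty 60–150, urethrotomy 20–80) so that
  rescaling analyses are non-trivial;
- procedure resource use: zero-rectified normal theatre and staff
  minutes and bed-days, Poisson consumable packs. Defaults place the
  urethroplasty index procedure near £4 100 and urethrotomy near
  £1 300 in 2017 GBP through the shipped unit-cost table;
- re-interventions: a per-month recurrence hazard over months 1–24
  post-surgery (geometric waiting time; urethroplasty 0.006/month,
  urethrotomy 0.02/month). Each re-intervention is micro-costed like an
  index procedure; with probability 0.5 it uses the *other* procedure,
  and the hazard thereafter follows the most recent procedure;
- follow-up contacts (Poisson per six-month period) and a gamma
  out-of-pocket amount;
- utilities: arm-level mean trajectory + a between-patient normal
  effect (SD 0.12) + within-patient noise (SD 0.08), clipped to
  [−1, 1] and snapped to the toy tariff's 0.05 grid, then expressed as
  an EQ-5D-5L profile whose tariff score equals that utility exactly.
  Default trajectories start at 0.80, dip post-operatively (deeper and
  longer for urethroplasty) and settle at 0.90, giving ≈1.75 QALYs/2
  years per arm — similar across arms by design.

**Missingness** is missing-at-random through a logistic model on the
allocated arm, the baseline utility and the *most recently observed*
utility (dropout tied to recent health). Baseline is never removed by
default. The last-observed-utility term is deliberate: missingness that
depends only on covariates already in the analysis model leaves the
covariate-adjusted complete-case estimator nearly unbiased, which would
make multiple imputation indistinguishable from complete-case analysis.
Real-trial features *not* emulated: recruitment-site clustering, the
minimisation algorithm's allocation sequence, missing resource-use
items, and informative (MNAR) dropout. Passing tests therefore say
nothing about MNAR robustness.

**Truth record.** Expected per-arm societal cost and 24-month QALY are
computed analytically from the configuration: exact enumeration over
the waiting-time support and the crossover/no-surgery mixtures, a
24-month dynamic program over the recurrence process (tracking which
procedure's hazard currently applies), rectified-normal means for
resource quantities, and the exact normal-bin expectation of the
clipped, grid-snapped utility at each time point. This makes the truth
exact under the generator's noise model, so parameter-recovery tests
compare against genuine expectations rather than a second simulation.

## Costing

Bottom-up: Σ quantity × unit cost per item, with unit costs converted
to the 2017 price year by CPI ratio at load time. Perspectives nest:
intervention (index + re-interventions) ⊆ NHS (+ follow-up contacts)
⊆ societal (+ out-of-pocket). Costs attach to recall periods, never
rescaled across calendar time. Second-year components (day ≥ 365.25)
can be discounted at 3.5 %/yr; this is applied in the analysis layer
(default on, with an off-switch) so the costing itself stays additive.

## QALYs

Profiles are scored by a tariff supplied as a file — either additive
decrements per (dimension, level) or a full 3 125-row lookup. The
shipped toy tariff (0.05 per level step) is synthetic; published value
sets are licensing-restricted inputs, not package data.

Utility series use actual completion days, time zero at the first
observation used; observations beyond 760 days from the anchor are
truncated to day 760; coincident days are merged by averaging. QALY =
trapezoidal area / 365.25. Rescaling multiplies by 730/observed-span.
Discounting splits each trapezoid at year boundaries and weights by
(1.035)^(−year of the segment midpoint), so rate 0 reproduces the
plain area exactly.

Complete-case rules (three sets): patients without an index procedure
need baseline + 18 m + 24 m post-randomisation; the base case needs
baseline + 24 m post-randomisation + one of {3, 6, 9, 12 m
post-surgery, 18 m post-randomisation}; the post-surgery window needs
pre-surgery + 24 m post-surgery + one mid-range point (the 24 m
post-randomisation assessment also counts there). Within-trial
analyses additionally require a non-missing baseline utility (it is a
covariate) and a computable QALY; complete cost data hold by
construction of the generator.

## Within-trial analysis

Cost and QALY equations share regressors (arm, stratum, baseline
utility), so the seemingly-unrelated-regression point estimates equal
per-equation OLS (Kruskal's theorem); the joint coefficient covariance
is Σ ⊗ (XᵀX)⁻¹ with Σ the residual cross-equation covariance. Adjusted
arm means are predictions at grand covariate means, so they differ by
exactly the arm coefficient. Increments are urethroplasty −
urethrotomy throughout.

Classification: costlier & less effective → dominated; cheaper & more
effective → dominant; same sign → ICER = Δc/Δe; Δe = 0 falls back to
cost minimisation (flagged by the label itself). Uncertainty: 1 000
arm-stratified bootstrap resamples (sizes preserved; percentile 95 %
CIs); CEAC probabilities count draws with positive incremental net
monetary benefit, ties to the comparator.

Multiple imputation: chained equations at the utility-time-point level
with predictive-mean matching (k = 3 donors, chosen for minimal
imputed-value bias and RMSE in generator-based calibration; 10 sweeps;
m = 25 default). Predictors per time point: arm, stratum, baseline
utility, the adjacent scheduled utilities and the observed total cost.
QALYs are recomputed per completed dataset at the patients' actual
observation days and increments pooled by Rubin's rules
(total variance = within + (1 + 1/m)·between, t reference with
Rubin–Satterthwaite degrees of freedom).

## Markov model

States: symptom-free, symptomatic, deceased; 6-month cycles (matching
the trial's follow-up rhythm; configurable), 10-year horizon, both
discount rates 3.5 %/yr, rewards at cycle-start times, no half-cycle
correction by default (optional flag). Competing risks apply
multiplicatively — death (flat background rate) first, then recurrence
among survivors — so rows are stochastic without renormalisation.
Symptomatic survivors are re-treated after one cycle and return to
symptom-free; the re-treatment procedure follows the recurrence policy
(observed mix with switch probability, always-same, always-other), and
because the recurrence probability depends on the last procedure the
engine tracks symptom states crossed with last procedure (five
sub-states) internally. Repeat recurrences are allowed (no absorbing
cure). A transient utility decrement at recurrence exists as a
parameter but defaults to 0.

The shipped parameter file is **synthetic**: initial costs at the
generator's intervention-cost scale, state utilities (0.925 / 0.905)
giving ≈7.6 discounted QALYs per strategy per decade, per-cycle
recurrence 0.035 (urethroplasty) vs 0.10 (urethrotomy). Under these
defaults urethroplasty costs £1 429 more for +0.006 QALYs — an ICER of
≈£251 000/QALY, i.e. a dominance-free but clearly not cost-effective
regime.

PSA: beta (probabilities, utilities) and gamma (costs) distributions,
hyperparameters by method of moments from (mean, SE); SE = 0 pins a
parameter; infeasible SEs (e.g. SE² ≥ m(1−m) for a beta) raise naming
the parameter. CEACs from PSA draws reuse the within-trial CEAC code.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng`; orchestrated
  runs split one root seed per stage via `SeedSequence`.
- Transition rows are validated to sum to 1 within 1e−12; cohort
  occupancy conservation is asserted per cycle in tests.
- Test problem sizes: truth-consistency re-simulation at 50 000
  patients/arm; micro-simulation oracle at 10⁵ trajectories; parameter
  recovery at 5 000/arm; CI coverage over 200 replicates of 200/arm;
  the MI-versus-complete-case comparison over 100 replicates of
  110/arm with m = 25 imputations.
- Whole-percent table cells round half-up; costs print to £1, QALYs to
  0.01.

## Known limitations

- The complete-case-versus-MI contrast is intentionally mild: with
  baseline utility in the analysis model and inclusion rules that
  tolerate missing interior points, the complete-case estimator stays
  close to unbiased under the generator's MAR mechanisms, and the MI
  advantage is mostly a variance reduction. In repeated-sampling
  experiments MI's pooled incremental QALY beats complete case in
  ≈58–62 % of replicates — materially better than a coin flip only in
  precision terms, and sensitive to the replicate set.
- Flat background mortality (no life-table ageing); no recruitment-site
  effects; two-strategy frontier logic only (the CEAC code itself is
  written generically).
- The toy tariff compresses utilities onto a 0.05 grid; analyses with a
  real value set will show smoother utility distributions.
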