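# uroecon

Trial-based economic evaluation of surgery for recurrent bulbar urethral
stricture: open **urethroplasty** versus endoscopic **urethrotomy**.

Recurrent bulbar stricture is a common cause of voiding symptoms in men.
Urethrotomy is cheap and minimally invasive but recurs often;
urethroplasty is costlier and more invasive but recurs less. `uroecon`
implements the full health-economic pipeline used to compare them in a
two-arm randomised trial setting, exercised end-to-end on a synthetic
trial generator with a known ground truth:

- **Micro-costing** — per-patient bottom-up costing of the index
  procedure, re-interventions, follow-up NHS service use and patients'
  out-of-pocket expenses, with CPI conversion to 2017 GBP and nested
  perspectives (intervention ⊆ NHS ⊆ societal).
- **QALYs** — EQ-5D-5L profiles scored through a pluggable tariff
  (value set), utilities integrated over 24 months of follow-up by the
  trapezoidal AUC method, with the trial's complete-case inclusion
  rules, optional rescaling to the nominal 730-day window and optional
  3.5 %/yr discounting.
- **Within-trial cost-utility analysis** — incremental cost Δc and QALY
  Δe from seemingly unrelated regression (cost and QALY equations on
  allocated arm, dichotomised time since last procedure, baseline
  utility), ICER / dominance classification, arm-stratified bootstrap
  with cost-effectiveness acceptability curves
  (probability that a strategy has the highest net monetary benefit
  λ·E − C over a £0–£50 000 willingness-to-pay grid), and multiple
  imputation by chained equations with predictive-mean matching pooled
  by Rubin's rules.
- **Markov model** — three-state cohort model (symptom-free,
  symptomatic, deceased) over a 10-year horizon with 6-month cycles,
  strategy-specific recurrence, re-intervention costing, 3.5 %/yr
  discounting, deterministic scenarios for the re-intervention choice
  (observed mix / always same / always other; allocation-based or
  treatment-received parameters) and probabilistic sensitivity analysis
  (beta draws for probabilities and utilities, gamma for costs).

The shipped tariff is a documented synthetic toy value set (each level
above 1 subtracts 0.05 per dimension); real value sets can be supplied
as `tariff.csv`.

## Worked example

Run the whole pipeline on a small synthetic trial (40 patients/arm,
200 bootstrap resamples, 100 PSA draws):

```sh
uroecon all --seed 3 --n 40 --out demo -B 200 -N 100
```

`demo/table3.csv` (within-trial analysis, first block):

```
analysis,strategy,n,cost,incremental_cost,qaly,incremental_effect,icer,p_0k,p_10k,p_20k,p_30k,p_50k
randomisation,urethroplasty,24,4603,"2146 (1498, 2845)",1.79,"-0.01 (-0.07, 0.04)",Dominated,0,0,0,0,3
randomisation,urethrotomy,29,2457,,1.80,,Dominant,100,100,100,100,97
```

Urethroplasty costs £2146 more per patient (95 % bootstrap CI 1498–2845)
for 0.01 *fewer* QALYs over two years, so it is dominated: at every
willingness-to-pay threshold the probability that urethrotomy is
cost-effective is ≈100 %.

`demo/table4.csv` (10-year Markov model, base case):

```
analysis,strategy,cost,qaly,icer,p_0k,p_10k,p_20k,p_30k,p_50k
base_case,urethroplasty,6525,7.61,251427,3,3,4,6,13
base_case,urethrotomy,5096,7.61,,97,97,96,94,87
```

Over a decade the lower recurrence after urethroplasty buys a small QALY
gain (both strategies round to 7.61), but at £251 427 per QALY it
remains far above conventional thresholds.

The run also writes `patients.csv`, `observations.csv`, `costs.csv`,
`qalys.csv`, CEAC/CE-plane point series and a `manifest.json` recording
the configuration and per-stage seeds; re-running with the same seed
reproduces every file byte-for-byte.

## Layout

```
src/uroecon/
  synthdata.py   synthetic trial generator + analytic truth record
  costing.py     unit costs, CPI conversion, per-patient costing
  qaly.py        tariffs, utility series, inclusion rules, AUC QALYs
  cea.py         SUR increments, ICER, bootstrap, CEAC, MI, Rubin
  markov.py      cohort engine, scenarios, PSA
  report.py      CLI, result tables, manifest
  data/          unit_costs.csv, cpi.csv, tariff.csv (toy),
                 markov_params.yaml, psa.yaml
```

See `docs/methods.md` for the model details, parameter defaults and
limitations.
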