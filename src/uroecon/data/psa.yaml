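# Probabilistic sensitivity analysis distributions.
# Probabilities and utilities: beta; costs: gamma.  Hyperparameters are
# matched to (mean, se) by method of moments.
n_draws: 1000
seed: 0
params:
  procedures.urethroplasty.initial_cost:
    {family: gamma, mean: 4320.0, se: 430.0}
  procedures.urethroplasty.recurrence_prob:
    {family: beta, mean: 0.035, se: 0.010}
  procedures.urethroplasty.reintervention_cost:
    {family: gamma, mean: 4320.0, se: 430.0}
  procedures.urethrotomy.initial_cost:
    {family: gamma, mean: 1300.0, se: 130.0}
  procedures.urethrotomy.recurrence_prob:
    {family: beta, mean: 0.10, se: 0.020}
  procedures.urethrotomy.reintervention_cost:
    {family: gamma, mean: 1300.0, se: 130.0}
  death_prob:
    {family: beta, mean: 0.004, se: 0.001}
  u_symptom_free:
    {family: beta, mean: 0.925, se: 0.015}
  u_symptomatic:
    {family: beta, mean: 0.905, se: 0.020}
  followup_cost_per_cycle:
    {family: gamma, mean: 30.0, se: 6.0}
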