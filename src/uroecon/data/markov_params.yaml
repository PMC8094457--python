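# Default 10-year Markov model parameters (2017 GBP).
#
# SYNTHETIC defaults: these values are NOT a published parameter set.
# They are chosen to be consistent with the within-trial scale of the
# synthetic generator (initial procedure costs near the per-arm
# intervention cost means; state utilities implying roughly 7.6
# discounted QALYs per strategy over the decade) so the shipped model
# runs in a realistic regime.  Replace this file to parameterise the
# model from your own estimates.
procedures:
  urethroplasty:
    initial_cost: 4320.0
    recurrence_prob: 0.035      # per 6-month cycle, after urethroplasty
    reintervention_cost: 4320.0
  urethrotomy:
    initial_cost: 1300.0
    recurrence_prob: 0.10
    reintervention_cost: 1300.0
# "treatment received" parameterisation (deterministic sensitivity analysis)
received_procedures:
  urethroplasty:
    initial_cost: 4250.0
    recurrence_prob: 0.037
    reintervention_cost: 4250.0
  urethrotomy:
    initial_cost: 1350.0
    recurrence_prob: 0.095
    reintervention_cost: 1350.0
death_prob: 0.004               # flat background mortality per cycle
u_symptom_free: 0.925
u_symptomatic: 0.905
followup_cost_per_cycle: 30.0
recurrence_utility_decrement: 0.0
cycle_length: 0.5               # years
horizon: 10.0                   # years
discount_rate_costs: 0.035      # per annum
discount_rate_qalys: 0.035
recurrence_policy: observed_mix
p_switch: 0.5
half_cycle_correction: false
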