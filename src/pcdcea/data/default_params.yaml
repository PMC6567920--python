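# Default model parameters: annual EU referral cohort, per-test diagnostic
# accuracy and per-test cost inputs, each with its uncertainty distribution.
#
# Every block follows the same schema:
#   {family: beta|gamma|normal|lognormal|point, best, ci_low, ci_high,
#    sd (normal), median+gsd (lognormal), mean (fit-target override)}
#
# Notes:
# - hsvm sensitivity has a best estimate of 1.00, which a beta distribution
#   cannot take as its mean; `mean: 0.99` sets the sampling mean while the
#   deterministic model keeps the best estimate of 1.00.
# - conditional (post-positive-screen) accuracies for confirmatory tests were
#   not published; the optional conditional_sensitivity/conditional_specificity
#   blocks are left unset so marginal values are used.

cohort:
  n_referrals: 1000
  prevalence: {family: normal, best: 0.32, ci_low: 0.25, ci_high: 0.39, sd: 0.028}

tests:
  nno:
    sensitivity: {family: beta, best: 0.95, ci_low: 0.91, ci_high: 0.97}
    specificity: {family: beta, best: 0.94, ci_low: 0.88, ci_high: 0.97}
  hsvm:
    sensitivity: {family: beta, best: 1.00, ci_low: 0.89, ci_high: 1.00, mean: 0.99}
    specificity: {family: beta, best: 0.92, ci_low: 0.86, ci_high: 0.96}
  tem:
    sensitivity: {family: beta, best: 0.74, ci_low: 0.66, ci_high: 0.83}
    specificity: {family: beta, best: 0.91, ci_low: 0.86, ci_high: 0.96}

costs:
  nno:
    capital_cost: {family: gamma, best: 40000, ci_low: 36000, ci_high: 44000}
    equipment_lifespan: {family: normal, best: 15, ci_low: 13, ci_high: 17, sd: 1}
    annual_maintenance: {family: gamma, best: 1300, ci_low: 1100, ci_high: 1500}
    consumables: {family: gamma, best: 15, ci_low: 9, ci_high: 21}
    operator_rate: {family: gamma, best: 25, ci_low: 10, ci_high: 35}
    test_duration: {family: normal, best: 0.5, ci_low: 0.3, ci_high: 0.7, sd: 0.1}
    physician_rate: {family: point, best: 0}          # no physician step
    sampling_time: {family: point, best: 0}           # no brushing
  hsvm:
    capital_cost: {family: gamma, best: 5000, ci_low: 3000, ci_high: 7000}
    equipment_lifespan: {family: normal, best: 15, ci_low: 10, ci_high: 20, sd: 2}
    annual_maintenance: {family: point, best: 0}      # none published
    consumables: {family: gamma, best: 30, ci_low: 26, ci_high: 34}
    operator_rate: {family: gamma, best: 25, ci_low: 10, ci_high: 35}
    test_duration: {family: normal, best: 2, ci_low: 1.6, ci_high: 2.4, sd: 0.2}
    physician_rate: {family: gamma, best: 50, ci_low: 30, ci_high: 70}
    sampling_time: {family: point, best: 0.2}         # brushing, constant
  tem:
    capital_cost: {family: gamma, best: 100000, ci_low: 90000, ci_high: 110000}
    equipment_lifespan: {family: normal, best: 30, ci_low: 20, ci_high: 40, sd: 5}
    annual_maintenance: {family: gamma, best: 2000, ci_low: 1300, ci_high: 2600}
    consumables: {family: gamma, best: 120, ci_low: 90, ci_high: 140}
    operator_rate: {family: gamma, best: 25, ci_low: 10, ci_high: 35}
    test_duration: {family: lognormal, best: 10, median: 10, gsd: 1.3, ci_low: 6, ci_high: 18}
    physician_rate: {family: gamma, best: 50, ci_low: 30, ci_high: 70}
    sampling_time: {family: point, best: 0.2}         # brushing, constant

# calibration knob for aggregate-cost comparisons; 0 = pure micro-costing
overhead_per_patient: {family: point, best: 0}

n_iterations: 3000
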