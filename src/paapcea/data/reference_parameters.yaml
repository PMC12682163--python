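# Reference model parameters for the penicillin allergy assessment pathway
# (PAAP) economic model: point estimates and uncertainty SDs from the
# ALABAMA trial primary-analysis cohort (PAAP n=401, usual care n=410).
# Probabilities and annual QALYs are Beta-distributed, first-year costs
# Lognormal, both parameterised by method of moments; sd 0 marks structural
# constants excluded from probabilistic analysis.  Substitution entries
# carry externally supplied payoffs for tree branches with no trial members.
schema: 1
meta:
  source: ALABAMA trial estimates (PAAP vs usual care, GBP 2022-23 prices)
  uncertainty: sample_sd
arms:
  paap:
    n: 401
    event_probabilities:
      receive_test: {family: beta, mean: 0.910, sd: 0.082}
      test_positive: {family: beta, mean: 0.082, sd: 0.075}
      pal_removed_after_positive_test: {family: fixed, mean: 0.0, sd: 0.0}
      pal_removed_after_negative_test: {family: beta, mean: 0.973, sd: 0.026}
      tf_after_test_positive_pal_not_removed: {family: beta, mean: 0.033, sd: 0.032}
      tf_after_test_negative_pal_not_removed: {family: beta, mean: 0.111, sd: 0.099}
      tf_after_test_negative_pal_removed: {family: beta, mean: 0.089, sd: 0.081}
      tf_with_no_test: {family: beta, mean: 0.083, sd: 0.076}
    first_year_costs:
      pos_label_tf: {family: lognormal, mean: 510.23, sd: 0.0}
      pos_label_no_tf: {family: lognormal, mean: 1176.55, sd: 1587.10}
      neg_label_tf: {family: lognormal, mean: 3565.61, sd: 0.0}
      neg_label_no_tf: {family: lognormal, mean: 501.37, sd: 399.85}
      neg_nolabel_tf: {family: lognormal, mean: 1868.20, sd: 2249.55}
      neg_nolabel_no_tf: {family: lognormal, mean: 1481.03, sd: 2694.72}
      no_test_tf: {family: lognormal, mean: 432.47, sd: 333.95}
      no_test_no_tf: {family: lognormal, mean: 604.89, sd: 1063.40}
    annual_qalys:
      pos_label_tf: {family: beta, mean: 0.924, sd: 0.0}
      pos_label_no_tf: {family: beta, mean: 0.828, sd: 0.226}
      neg_label_tf: {family: beta, mean: 0.776, sd: 0.0}
      neg_label_no_tf: {family: beta, mean: 0.837, sd: 0.132}
      neg_nolabel_tf: {family: beta, mean: 0.808, sd: 0.146}
      neg_nolabel_no_tf: {family: beta, mean: 0.880, sd: 0.137}
      no_test_tf: {family: beta, mean: 0.689, sd: 0.060}
      no_test_no_tf: {family: beta, mean: 0.902, sd: 0.082}
    substitutions: {}
  usual_care:
    n: 410
    event_probabilities:
      receive_test: {family: beta, mean: 0.012, sd: 0.012}
      test_positive: {family: beta, mean: 0.200, sd: 0.160}
      pal_removed_after_positive_test: {family: fixed, mean: 0.0, sd: 0.0}
      pal_removed_after_negative_test: {family: fixed, mean: 1.0, sd: 0.0}
      tf_after_test_positive_pal_not_removed: {family: fixed, mean: 0.0, sd: 0.0}
      tf_after_test_negative_pal_not_removed: {family: fixed, mean: 0.0, sd: 0.0}
      tf_after_test_negative_pal_removed: {family: fixed, mean: 0.0, sd: 0.0}
      tf_with_no_test: {family: beta, mean: 0.114, sd: 0.101}
    first_year_costs:
      pos_label_tf: {family: fixed, mean: 0.0, sd: 0.0}
      pos_label_no_tf: null
      neg_label_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_label_no_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_nolabel_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_nolabel_no_tf: {family: lognormal, mean: 409.14, sd: 724.91}
      no_test_tf: {family: lognormal, mean: 2077.52, sd: 2760.80}
      no_test_no_tf: {family: lognormal, mean: 1208.45, sd: 3038.71}
    annual_qalys:
      pos_label_tf: {family: fixed, mean: 0.0, sd: 0.0}
      pos_label_no_tf: null
      neg_label_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_label_no_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_nolabel_tf: {family: fixed, mean: 0.0, sd: 0.0}
      neg_nolabel_no_tf: {family: beta, mean: 0.888, sd: 0.091}
      no_test_tf: {family: beta, mean: 0.755, sd: 0.249}
      no_test_no_tf: {family: beta, mean: 0.850, sd: 0.175}
    substitutions:
      "cost:pos_label_no_tf": {value: 839.63}
      "qaly:pos_label_no_tf": {value: 0.980}
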