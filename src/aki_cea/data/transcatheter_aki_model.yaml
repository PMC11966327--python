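# Canonical model inputs: trial-derived AKI probabilities per implementation
# strategy, 30-day dispositions by AKI status, annual transition probabilities
# stratified by AKI history, and economic inputs.  All probabilities are
# fractions; all money amounts are 2020 US dollars.
#
# The AKI episode cost carries a +/-25% sensitivity range (its published
# interval is inconsistent with its published base case, so the conservative
# +/-25% convention used for the other cost inputs is applied).
units: fraction

strategies:
  assistance:
    name: assistance
    p_aki: {mean: 0.133, ci_low: 0.110, ci_high: 0.156}
    upfront_cost: {mean: 2.69, low: 2.02, high: 3.36}
  assistance_surveillance:
    name: assistance_surveillance
    p_aki: {mean: 0.114, ci_low: 0.095, ci_high: 0.133}
    upfront_cost: {mean: 3.36, low: 2.52, high: 4.20}
  collaborative:
    name: collaborative
    p_aki: {mean: 0.127, ci_low: 0.111, ci_high: 0.144}
    upfront_cost: {mean: 3.97, low: 2.98, high: 4.96}
  collaborative_surveillance:
    name: collaborative_surveillance
    p_aki: {mean: 0.079, ci_low: 0.064, ci_high: 0.095}
    upfront_cost: {mean: 12.74, low: 9.56, high: 15.93}

transitions:
  thirty_day:
    aki:
      NORMAL: {mean: 0.869, ci_low: 0.863, ci_high: 0.874}
      CKD: {mean: 0.036, ci_low: 0.033, ci_high: 0.039}
      ESRD: {mean: 0.004, ci_low: 0.003, ci_high: 0.005}
      DEATH: {mean: 0.091, ci_low: 0.087, ci_high: 0.097}
    no_aki:
      # Row sums to 0.999 as printed; renormalized proportionally at load.
      NORMAL: {mean: 0.973, ci_low: 0.972, ci_high: 0.974}
      CKD: {mean: 0.012, ci_low: 0.011, ci_high: 0.013}
      ESRD: {mean: 0.0, ci_low: 0.0, ci_high: 0.0}
      DEATH: {mean: 0.014, ci_low: 0.014, ci_high: 0.015}
  annual:
    after_aki:
      NORMAL:
        CKD: {mean: 0.028, ci_low: 0.021, ci_high: 0.035}
        ESRD: {mean: 0.003, ci_low: 0.002, ci_high: 0.004}
        DEATH: {mean: 0.123, ci_low: 0.092, ci_high: 0.154}
      CKD:
        ESRD: {mean: 0.047, ci_low: 0.035, ci_high: 0.059}
        DEATH: {mean: 0.297, ci_low: 0.223, ci_high: 0.371}
      ESRD:
        DEATH: {mean: 0.345, ci_low: 0.259, ci_high: 0.431}
    no_aki:
      NORMAL:
        CKD: {mean: 0.010, ci_low: 0.008, ci_high: 0.013}
        ESRD: {mean: 0.0005, ci_low: 0.0004, ci_high: 0.0006}
        DEATH: {mean: 0.067, ci_low: 0.050, ci_high: 0.084}
      CKD:
        ESRD: {mean: 0.018, ci_low: 0.014, ci_high: 0.023}
        DEATH: {mean: 0.273, ci_low: 0.205, ci_high: 0.341}
      ESRD:
        DEATH: {mean: 0.275, ci_low: 0.206, ci_high: 0.344}

economics:
  utilities:
    NORMAL: {mean: 0.85, ci_low: 0.83, ci_high: 0.87}
    CKD: {mean: 0.80, ci_low: 0.70, ci_high: 1.00}
    ESRD: {mean: 0.70, ci_low: 0.60, ci_high: 0.80}
  aki_episode_cost: {mean: 14000.0, low: 10500.0, high: 17500.0}
  annual_state_costs:
    CKD: {mean: 25322.0, low: 18992.0, high: 31653.0}
    ESRD: {mean: 78537.0, low: 58903.0, high: 98171.0}
  discount_rate: 0.03
  horizon_years: 3
  wtp: 100000.0
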