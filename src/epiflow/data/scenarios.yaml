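# Bundled treatment-flow scenarios for the Japanese epilepsy referral model.
#
# "current" is the present treatment flow (non-specialized escalation
# probabilities estimated from an outpatient prescription database;
# specialized-care and referral probabilities calibrated to the 2019 annual
# surgery count of the Nagano prefecture).  "optimized" is the
# expert-defined ideal community-based integrated care flow.
#
# All probabilities are per-entry or annual probabilities as documented in
# epiflow.parameters.ParameterSet.  counter_referral_window_total is the
# cumulative counter-referral probability over the 5-year window (converted
# to a uniform annual hazard, annual = total / window, on load).  Costs are
# JPY: pharma_3mo per 3 months (by care setting, state row, and age band),
# surgery per operation.
#
# reduction_inflow_annual (difficult-to-treat -> seizure reduction under
# specialized care) is not printed in the source tables; the values below
# were calibrated with epiflow.calibration so that each flow reproduces its
# published annual number of surgeries (372 current / 701 optimized).

costs:
  pharma_3mo:
    non-specialized:
      mono:      {ped_le6: 26996, ped_gt6: 66662, adult: 70833}
      two:       {ped_le6: 45444, ped_gt6: 92464, adult: 100224}
      three:     {ped_le6: 68014, ped_gt6: 121571, adult: 131913}
      four:      {ped_le6: 94728, ped_gt6: 157249, adult: 168288}
    specialized:
      mono:      {ped_le6: 35623, ped_gt6: 79938, adult: 88609}
      two:       {ped_le6: 53635, ped_gt6: 103440, adult: 116485}
      three:     {ped_le6: 70018, ped_gt6: 128743, adult: 149759}
      reduction: {ped_le6: 85151, ped_gt6: 140941, adult: 150628}
      difficult: {ped_le6: 85151, ped_gt6: 140941, adult: 150628}
  surgery:
    "le9": 2023280
    "10_14": 2001008
    "15_19": 2079145
    "adult": 2102324
  adult_age_threshold: 15

scenarios:
  current:
    parameters:
      incident_cohort_size: 7117
      esc_ns: [0.386, 0.271, 0.235]
      esc_sc: [0.27, 0.57, 0.77]
      referral: [0.064, 0.279, 0.415]
      surg_at_transition: [0.03, 0.03, 0.03]
      late_referral_annual: 0.015
      late_surgery_annual: 0.015
      # Calibrated so the current flow reproduces its published annual
      # surgery count of 372 (epiflow.calibration, tol 0.01).
      reduction_inflow_annual: 0.002479
      # Published counter-referral column reads 1.0% per line; for the
      # current flow this reproduces the published cross-section as an
      # ANNUAL probability (see docs/methods.md on the mixed convention).
      counter_referral_annual: [0.01, 0.01, 0.01]
      surgery_type_split: [0.49, 0.49, 0.49]
      postsurgery_outcome:
        curative:   {freedom: 0.53, reduction: 0.73}
        palliative: {freedom: 0.075, reduction: 0.20}
      late_window_years: 40
      counter_referral_window_years: 5
      horizon_years: 79.3982
  optimized:
    parameters:
      incident_cohort_size: 7117
      esc_ns: [0.20, 0.14, 0.0]
      esc_sc: [0.40, 0.48, 0.48]
      referral: [0.20, 0.56, 0.90]
      surg_at_transition: [0.10, 0.12, 0.32]
      late_referral_annual: 0.0
      late_surgery_annual: 0.015
      # Calibrated so the optimized flow reproduces its published annual
      # surgery count of 701 (epiflow.calibration, tol 0.01).
      reduction_inflow_annual: 0.021563
      # Published 80/50/20% only reproduce the published cross-section as
      # CUMULATIVE probabilities over the 5-year window (annual = total/5).
      counter_referral_window_total: [0.80, 0.50, 0.20]
      surgery_type_split: [0.90, 0.70, 0.30]
      postsurgery_outcome:
        curative:   {freedom: 0.53, reduction: 0.73}
        palliative: {freedom: 0.075, reduction: 0.20}
      late_window_years: 40
      counter_referral_window_years: 5
      horizon_years: 79.3982
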