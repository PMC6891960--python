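# Published clinical inputs per patient group: observed glargine U100 doses
# (units/day), degludec/glargine dose ratios, annual hypoglycaemia event rates
# on glargine (events/patient/year) and degludec/glargine rate ratios.
# A ratio reported without statistical significance is stored as 1.0 with
# significant: false (its point estimate is not published).
groups:
  T1DM_BB:
    regimen:
      basal_dose_glargine: 28.11
      basal_dose_ratio: 0.87
      basal_ratio_significant: true
      bolus_dose_glargine: 37.13
      bolus_dose_ratio: 0.88
      bolus_ratio_significant: true
    glargine_rates:
      daytime_nonsevere: 30.42
      nocturnal_nonsevere: 8.52
      severe: 3.20
    rate_ratios:
      daytime: {ratio: 1.0, significant: false}
      nocturnal: {ratio: 0.83, significant: true}
      severe: {ratio: 1.0, significant: false}
  T2DM_BOT:
    regimen:
      basal_dose_glargine: 28.11
      basal_dose_ratio: 0.90
      basal_ratio_significant: true
    glargine_rates:
      daytime_nonsevere: 23.12
      nocturnal_nonsevere: 13.38
      severe: 0.10
    rate_ratios:
      daytime: {ratio: 1.0, significant: false}
      nocturnal: {ratio: 0.64, significant: true}
      severe: {ratio: 0.14, significant: true}
  T2DM_BB:
    regimen:
      basal_dose_glargine: 28.11
      basal_dose_ratio: 1.08
      basal_ratio_significant: true
      bolus_dose_glargine: 37.13
      bolus_dose_ratio: 1.0
      bolus_ratio_significant: false
    glargine_rates:
      daytime_nonsevere: 30.42
      nocturnal_nonsevere: 8.52
      severe: 0.70
    rate_ratios:
      daytime: {ratio: 0.83, significant: true}
      nocturnal: {ratio: 0.75, significant: true}
      severe: {ratio: 1.0, significant: false}

# Per-event hypoglycaemia treatment costs, BGN/event, as published at the 2014
# price level and inflated to 2018 (the model's price year).
event_costs_2014: {daytime: 0.66, nocturnal: 33.60, severe: 514.36}
event_costs_2018: {daytime: 0.65, nocturnal: 33.19, severe: 508.10}
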