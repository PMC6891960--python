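# Published per-arm annual results (BGN/patient/year and QALYs/patient/year)
# used as calibration targets: pharmacy unit prices, per-event costs, baseline
# utilities and per-event disutilities are not published and are back-solved
# from these aggregates.
wtp_threshold: 39619.0
flexible_dosing_utility: 0.006
mortality_risk_severe: 0.0112
groups:
  T1DM_BB:
    degludec:  {insulin: 1296.67, daytime: 19.42, nocturnal: 230.41, severe: 1596.78, total: 3143.28, qalys: 0.5722}
    glargine:  {insulin: 1180.11, daytime: 19.42, nocturnal: 277.60, severe: 1596.78, total: 3073.92, qalys: 0.5568}
    incremental: {cost: 69.37, qalys: 0.0154, icer: 4498.68}
  T2DM_BOT:
    degludec:  {insulin: 794.93, daytime: 15.02, nocturnal: 284.26, severe: 7.11, total: 1101.32, qalys: 0.7490}
    glargine:  {insulin: 574.23, daytime: 15.02, nocturnal: 443.94, severe: 50.78, total: 1083.97, qalys: 0.7055}
    incremental: {cost: 17.35, qalys: 0.0435, icer: 399.11}
  T2DM_BB:
    degludec:  {insulin: 1574.88, daytime: 16.35, nocturnal: 211.17, severe: 354.28, total: 2156.67, qalys: 0.6893}
    glargine:  {insulin: 1196.94, daytime: 19.69, nocturnal: 281.56, severe: 354.28, total: 1852.47, qalys: 0.6480}
    incremental: {cost: 304.21, qalys: 0.0413, icer: 7365.22}
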