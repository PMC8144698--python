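# Concentration-response parameters for the short-term burden calculation.
#
# Illustrative defaults in the range of published Chinese time-series
# meta-analyses; NOT authoritative epidemiology. Edit for real analyses.
# ER values are excess log relative risk per 10 ug/m3 increment (er_units:
# per_10); bounds are 95% confidence limits. y0_annual is the cause-specific
# annual baseline mortality rate (deaths per person per year). C0 is the
# no-risk threshold in ug/m3 (NO2: 40, 8-h O3: 100).
er_units: per_10
parameters:
  - {cause: all_cause, pollutant: NO2, ER_central: 0.0090, ER_low: 0.0070, ER_high: 0.0110, C0: 40.0, y0_annual: 0.00707}
  - {cause: CVD,       pollutant: NO2, ER_central: 0.0090, ER_low: 0.0066, ER_high: 0.0114, C0: 40.0, y0_annual: 0.00310}
  - {cause: RD,        pollutant: NO2, ER_central: 0.0120, ER_low: 0.0090, ER_high: 0.0150, C0: 40.0, y0_annual: 0.00068}
  - {cause: COPD,      pollutant: NO2, ER_central: 0.0140, ER_low: 0.0099, ER_high: 0.0181, C0: 40.0, y0_annual: 0.00090}
  - {cause: all_cause, pollutant: O3_8h, ER_central: 0.0048, ER_low: 0.0026, ER_high: 0.0070, C0: 100.0, y0_annual: 0.00707}
  - {cause: CVD,       pollutant: O3_8h, ER_central: 0.0045, ER_low: 0.0016, ER_high: 0.0074, C0: 100.0, y0_annual: 0.00310}
  # RD and COPD ozone coefficients are statistically uncertain: their 95%
  # intervals straddle zero, so the burden bounds can change sign.
  - {cause: RD,        pollutant: O3_8h, ER_central: 0.0047, ER_low: -0.0030, ER_high: 0.0124, C0: 100.0, y0_annual: 0.00068}
  - {cause: COPD,      pollutant: O3_8h, ER_central: 0.0050, ER_low: -0.0033, ER_high: 0.0133, C0: 100.0, y0_annual: 0.00090}
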