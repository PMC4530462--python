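# Reference configuration: the published code sets and thresholds of the
# refined (V2) phenotyping algorithm, plus the candidate-SNP panel used in
# the association stage. Human-editable; keys documented in docs/methods.md.
algorithm:
  version: V2
  amd_dx_codes:                # ICD-9, ophthalmologist-entered
    exact: ["362.50", "362.51", "362.52", "362.16", "362.57"]
  wet_proc_codes:              # HCPCS J-codes for anti-VEGF injection
    exact: ["J2778", "J9035", "J3490", "J3590"]
  wet_med_names: [ranibizumab, lucentis, bevacizumab, avastin, aflibercept, eylea]
  wet_same_date_dx:
    prefix: ["362.5"]
  min_amd_dx_dates: 2          # distinct diagnosis dates (V1 pilot used 1)
  min_age_years: 60
  control_lookback_years: 2
  # controls may not carry any of these diagnoses, ever; the non-specific
  # codes "362" and "377.21" are deliberately NOT in this set
  control_exclusion_codes:
    exact: ["362.50", "362.51", "362.52", "362.16", "362.57"]
    prefix: ["362.5"]
  require_ophthalmologist_dx: true

simulation:
  n_patients: 2000
  index_date: 2014-01-01
  age_distribution: [70.0, 12.0, 40.0, 95.0]   # mean, sd, min, max (years)
  prevalence: {true_dry: 0.05, true_wet: 0.03, mimicker: 0.07, healthy: 0.85}
  p_miscode_amd: 0.10
  p_missed_second_visit: 0.05
  p_injection_coded_same_date: 0.90
  visit_rate: 1.5
  p_specialty_other: 0.05

association:
  covariates: [age, sex, bmi, smoking_ever]
  alpha: 0.05
  m_tests: 11                  # candidate panel size -> threshold ~4.5e-3
  method: regression           # or allelic_2x2

genotype_simulation:
  raf_population: 0.363        # planted control-population risk-allele freq
  or_per_allele: 2.43          # planted additive odds ratio
  prevalence: 0.10
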