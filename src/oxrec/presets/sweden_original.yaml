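# Original (Swedish) parameterisation of the violent-reoffending risk score.
#
# Published values: the baseline survival pair (S_12, S_24), the education,
# disposable-income and severe-mental-disorder betas, and the identity
# recalibration slope. All other betas are PLACEHOLDERS: the development-study
# weights are not reproduced here, so the values below are clearly-flagged
# stand-ins of plausible sign and magnitude. Edit this file (or supply your
# own) to score with real development weights.
betas:
  gender:
    male: 0.30          # placeholder
  age_at_release:
    per_unit: -0.02     # placeholder (per year, centred)
  immigrant_status:
    "yes": 0.10         # placeholder
  incarceration_length:
    6-12m: 0.10         # placeholder
    12-24m: 0.20        # placeholder
    ">=24m": 0.30       # placeholder
  violent_index_offence:
    "yes": 0.20         # placeholder
  previous_violent_crime:
    "yes": 0.50         # placeholder
  civil_status:
    other: -0.10        # placeholder
  education:
    9-11y: -0.1838      # published
    ">=12y": -0.4282    # published
  employment:
    "yes": -0.30        # placeholder
  disposable_income:
    zero: 0.5251        # published
    low: 0.5176         # published
    medium: 0.3712      # published
    high: 0.4509        # published
  neighbourhood_deprivation:
    per_unit: 0.15      # placeholder (standardised score)
  alcohol_use_disorder:
    "yes": 0.30         # placeholder
  drug_use_disorder:
    "yes": 0.40         # placeholder
  any_mental_disorder:
    "yes": 0.20         # placeholder
  any_severe_mental_disorder:
    "yes": 0.0953       # published
reference_levels:
  gender: female
  immigrant_status: "no"
  incarceration_length: "<6m"
  violent_index_offence: "no"
  previous_violent_crime: "no"
  civil_status: unmarried
  education: "<9y"
  employment: "no"
  disposable_income: negative
  alcohol_use_disorder: "no"
  drug_use_disorder: "no"
  any_mental_disorder: "no"
  any_severe_mental_disorder: "no"
absent_prevalences: {}
centers:
  age_at_release: 35.0
  neighbourhood_deprivation: 0.0
baseline_survival:
  12: 0.7992
  24: 0.6775
recalibration_slopes:
  12: 1.0
  24: 1.0
category_cutoffs: [0.3, 0.6]
metadata:
  preset: sweden_original
  placeholder_betas:
    - gender
    - age_at_release
    - immigrant_status
    - incarceration_length
    - violent_index_offence
    - previous_violent_crime
    - civil_status
    - employment
    - neighbourhood_deprivation
    - alcohol_use_disorder
    - drug_use_disorder
    - any_mental_disorder
  note: >-
    Betas listed under placeholder_betas are stand-ins; consult the
    development study for the published weights before any real-world use.
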