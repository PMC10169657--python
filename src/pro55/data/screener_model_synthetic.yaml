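# Synthetic stand-in scoring equation for the Protein Screener 55+.
#
# Structure mirrors the published Pro55+ instrument (Wijnhoven et al. 2018):
# ten food items coded to ordinal numeric values plus age, sex, height and
# weight covariates entering a logistic model for P(protein intake
# < 1.0 g/kg adjusted body weight/day). The COEFFICIENT VALUES BELOW ARE
# SYNTHETIC PLACEHOLDERS, not the published ones: they carry the plausible
# sign structure (more of a protein-rich food -> lower predicted risk) and a
# graded magnitude ladder, and are intended for simulation, testing and
# pipeline development only. Do not use this file for clinical screening.
intercept: 3.6
weight_term: raw   # the weight covariate uses measured (raw) body weight
metadata:
  name: pro55-synthetic
  version: "0.1"
  source: synthetic stand-in; structure after the Pro55+ scoring equation (Wijnhoven et al. 2018)
  sex_reference: male
items:
  bread_slices:
    coefficient: -0.50
    codes:
      "0": 0
      "1": 1
      "2": 2
      "3": 3
      "4": 4
      "5-6": 5
      "7 or more": 6
  milk_glasses:
    coefficient: -0.65
    codes:
      "0": 0
      "1": 1
      "2": 2
      "3": 3
      "4 or more": 4
  meat_portion:
    coefficient: -0.85
    codes:
      "none": 0
      "small": 1
      "medium": 2
      "large": 3
      "very large": 4
  cheese_amount:
    coefficient: -0.32
    codes:
      "none": 0
      "20 g (1 slice)": 1
      "40 g (2 slices)": 2
      "60 g (3 slices)": 3
      "80 g or more": 4
  cheese_frequency:
    coefficient: -0.20
    codes:
      "never": 0
      "less than once a week": 1
      "1-2 days a week": 2
      "3-4 days a week": 3
      "5-6 days a week": 4
      "every day": 5
  dairy_frequency:
    coefficient: -0.10
    codes:
      "never": 0
      "less than once a week": 1
      "1-2 days a week": 2
      "3-4 days a week": 3
      "5-6 days a week": 4
      "every day": 5
  egg_frequency:
    coefficient: -0.07
    codes:
      "never": 0
      "less than once a week": 1
      "1-2 days a week": 2
      "3-4 days a week": 3
      "5-6 days a week": 4
      "every day": 5
  pasta_frequency:
    coefficient: -0.16
    codes:
      "never": 0
      "less than once a week": 1
      "1-2 days a week": 2
      "3-4 days a week": 3
      "5-6 days a week": 4
      "every day": 5
  fish_frequency:
    coefficient: -0.24
    codes:
      "never": 0
      "less than once a week": 1
      "once a week": 2
      "twice a week": 3
      "3 or more days a week": 4
  nuts_frequency:
    coefficient: -0.04
    codes:
      "never": 0
      "less than once a week": 1
      "1-2 days a week": 2
      "3-4 days a week": 3
      "5-6 days a week": 4
      "every day": 5
covariates:
  age_years: 0.015
  sex_female: 0.30
  weight_kg: 0.012
  height_cm: -0.005
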