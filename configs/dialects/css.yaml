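# Column mapping for a CSS-style extract. All expenditures are annual.
survey_id: css
column_map:
  id: household_id
  survey: survey_id
  year: wave_year
  is_urban: urban
  province: province
  family_size: family_size
  hh_income: income_total
  hh_consumption: consumption_total
  hh_food: food_expenditure
  hh_health_oop: oop_health_expenditure
  hh_weight: weight
monthly_fields: []
notes: >-
  Pure out-of-pocket healthcare expenditure (outpatient and inpatient). Food
  includes eating out and the market value of home-grown farm products.
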