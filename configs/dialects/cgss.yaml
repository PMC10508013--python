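# Column mapping for a CGSS-style extract. All expenditures are annual.
survey_id: cgss
column_map:
  hh_id: household_id
  survey: survey_id
  wave: wave_year
  urban_dummy: urban
  province_code: province
  hh_size: family_size
  total_income: income_total
  total_consumption: consumption_total
  food_spending: food_expenditure
  health_oop: oop_health_expenditure
  weight: weight
monthly_fields: []
notes: >-
  Pure out-of-pocket healthcare expenditure. Food includes the market value of
  home-grown farm products. Expenditure items are often missing, so the usable
  sample shrinks substantially under complete-case loading.
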