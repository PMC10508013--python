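# Column mapping for a CFPS-style extract. Food expenditure is collected as a
# monthly average and is annualized (x12) on load. Income is net income.
survey_id: cfps
column_map:
  fid: household_id
  survey: survey_id
  year: wave_year
  urban: urban
  provcd: province
  familysize: family_size
  net_income: income_total
  total_expense: consumption_total
  monthly_food_expense: food_expenditure
  oop_health_expense: oop_health_expenditure
  cross_weight: weight
monthly_fields:
  - food_expenditure
notes: >-
  Out-of-pocket healthcare expenditure includes spending on exercising and
  dietary supplements; food includes snacks, beverages, cigarettes, and
  alcohol, eating at home and out. Household income is net income.
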