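# Column mapping for a CHFS-style extract. Food expenditure is collected as a
# monthly average and is annualized (x12) on load.
survey_id: chfs
column_map:
  hhid: household_id
  survey: survey_id
  year: wave_year
  urban: urban
  prov: province
  fsize: family_size
  income: income_total
  consumption: consumption_total
  food_month: food_expenditure
  health_expense: oop_health_expenditure
  swgt: weight
monthly_fields:
  - food_expenditure
notes: >-
  Healthcare expenditure includes exercising-related spending (healthcare
  products, physical therapy, gym membership, fitness equipment and food,
  personal trainer). Food includes eating out, cigarettes, alcohol, beverages,
  and home-grown farm products.
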