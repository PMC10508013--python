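# Consumer price index on a common base, used to rebase all monetary fields
# to reference-year prices (factor = index[reference_year] / index[wave_year]).
# Replace with the official series for the years actually analyzed.
reference_year: 2017
index:
  2010: 87.2
  2012: 92.4
  2014: 96.2
  2016: 98.4
  2017: 100.0
  2018: 102.1
  2020: 106.2
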