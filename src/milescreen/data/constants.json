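{
  "total_assessments": 270,
  "distinct_children": 218,
  "total_questions": 108,
  "accepted": 263,
  "declined": 7,
  "month18_alarms": 9,
  "month18_evaluations": 11,
  "month24_alarms": 4,
  "month24_evaluations": 10,
  "mean_assessments": 1.24,
  "sample_size_population": 150000,
  "sample_size_prevalence": 0.07,
  "sample_size_z": 1.96,
  "sample_size_margin": 0.05,
  "sample_size_required": 100
}
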