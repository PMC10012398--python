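# Five-category ovarian-tumour diagnosis example: sizing a multinomial model
# for tumour type (1 benign, 2 borderline, 3 stage I invasive,
# 4 stage II-IV invasive, 5 metastatic) from published category counts and
# temporal-validation pairwise C-statistics.  Pairwise Cox-Snell R2 values
# are derived from the C-statistics by simulation; the overall R2 uses the
# conservative Nagelkerke-0.15 assumption.
outcome:
  counts: [2557, 186, 176, 467, 120]
predictors:
  Q: 17
criteria:
  S_target: 0.9
  delta_r2: 0.05
  delta_precision: 0.05
  alpha: 0.05
evidence:
  pairwise_cstat:
    "2,1": 0.85
    "3,1": 0.92
    "4,1": 0.99
    "5,1": 0.95
    "3,2": 0.75
    "4,2": 0.95
    "5,2": 0.87
    "4,3": 0.87
    "5,3": 0.71
    "5,4": 0.82
  nagelkerke_fallback: 0.15
epv: [10, 20]
seed: 2023
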