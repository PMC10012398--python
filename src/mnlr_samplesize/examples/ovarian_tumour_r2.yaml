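# Same ovarian-tumour example with the pairwise Cox-Snell R2 values supplied
# directly (to 3 decimal places), skipping the C-statistic simulation step.
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
  pairwise_r2:
    "2,1": 0.116
    "3,1": 0.179
    "4,1": 0.497
    "5,1": 0.170
    "3,2": 0.185
    "4,2": 0.499
    "5,2": 0.374
    "4,3": 0.328
    "5,3": 0.129
    "5,4": 0.210
  nagelkerke_fallback: 0.15
epv: [10, 20]
seed: 2023
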