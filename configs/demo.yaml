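# Demo study replica: 200 synthetic samples, half with planted chromothripsis.
seed: 0
simulate:
  n_samples: 200
  chromothripsis_fraction: 0.5
cps:
  n_signatures: 3
  folds: 10
survival:
  time_grid: [6, 12, 18, 24, 30, 36]
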