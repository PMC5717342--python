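# Demo pipeline configuration: a small synthetic family cohort run end to end.
outdir: results/demo
seed: 7
simulate: true
twin_n_families: 30
cohort:
  n_families: 60
  n_probes: 150
  n_true_eqtl: 25
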