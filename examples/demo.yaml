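# Demo pipeline run: simulate a mid-size cohort and analyze it end to end.
seed: 1
out_dir: results/demo
cohort:
  n_sites: 1500
  n_proteins: 300
  n_metabolites: 80
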