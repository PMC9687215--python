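# End-to-end demo on simulated data: 2000 probes, 15 planted transcripts
# at +1.5 log2 units in disease samples. Swap the `simulation` block for
#   input: {matrix: expr.tsv, labels: labels.tsv}
# to run on a real cohort.
simulation:
  n_control: 150
  n_disease: 150
  n_probes: 2000
  n_informative: 15
  effect_size: 1.5
  noise_sd: 1.0
seed: 11
test_fraction: 0.2
normalize: true
reference_probe_id: GUSB
lda_mode: holdout
output_dir: bloodpanel_demo
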