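# Desk-scale study: trains the full pipeline on one CPU in a few minutes.
# Corpus shape (codes per visit, visits per patient) follows the statistics
# the generator emulates; vocabulary and population sizes are scaled down.
synthetic:
  n_diag_leaves: 50
  n_drug_leaves: 100
  n_symptoms: 40
  n_single_visit_patients: 2000
  n_multi_visit_patients: 300
  profile_sparsity: 0.05
  chronic_persistence: 0.7
  seed: 11

experiment:
  width: 32
  layers: 2
  heads: 4
  gat_heads: 4
  learning_rate: 0.0005
  pretrain_learning_rate: 0.001
  mask_rate: 0.15
  epsilon: 1.0
  threshold: 0.5
  cycles: 3
  pretrain_epochs: 8
  finetune_epochs: 8
  pretrain_batch: 64
  finetune_batch: 8
  max_len: {d: 8, m: 28, s: 4}
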