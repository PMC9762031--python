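# Full-size defaults: a corpus roughly one tenth of the motivating dataset
# and the method's stated architecture (2 encoder layers, 4 heads, 4
# ontology-attention heads, fine-tune learning rate 5e-4, width 64).
# Expect hours on one CPU.
synthetic:
  n_diag_leaves: 400
  n_drug_leaves: 1000
  n_symptoms: 150
  n_single_visit_patients: 20000
  n_multi_visit_patients: 1000
  profile_sparsity: 0.05
  chronic_persistence: 0.7
  seed: 0

experiment:
  width: 64
  layers: 2
  heads: 4
  gat_heads: 4
  learning_rate: 0.0005
  pretrain_learning_rate: 0.001
  mask_rate: 0.15
  epsilon: 1.0
  threshold: 0.5
  cycles: 3
  pretrain_epochs: 5
  finetune_epochs: 10
  pretrain_batch: 64
  finetune_batch: 32
  max_len: {d: 32, m: 72, s: 8}
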