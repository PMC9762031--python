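# medrec

Medication recommendation from **small-scale longitudinal electronic medical
records**, for clinical-informatics researchers who have plenty of
single-visit records but few multi-visit patients.

Given a patient's visit history and the current visit's diagnoses (ICD-10
style codes) and symptoms, the model scores every drug code (14-digit
NDC-style) and recommends the set above a threshold. Three ideas are
combined to make this work in the scarce-longitudinal regime:

1. **Ontology-knowledge-enhanced embeddings** — a diagnosis or drug code
   *c* is embedded by multi-head graph attention over the code and its
   ancestors N_c in the coding tree,

   o_c = ∥ₖ σ( Σ_{j∈N_c} a^k_{c,j} W^k h_j ),

   so codes sharing classification ancestry share representation.
2. **Pretraining on single-visit records** — a per-field transformer visit
   encoder (v_d, v_m, v_s from the `[CLS]` state) is trained with a
   masked-field recovery task and a cross-field correlation task (predict
   each field's code set from the other fields' embeddings), both as
   multi-label binary cross entropy.
3. **Adversarially regularized fine-tuning** — drug probabilities
   y_t = σ(W[mean v_d, mean v_s, mean v_m, v_d^t, v_s^t] + b) are trained
   from the second visit onward with BCE, each step augmented by a fast
   gradient method (FGM) pass that perturbs the code embeddings by
   r_adv = −ε g/‖g‖₂ and accumulates both passes' gradients. Pretraining
   and fine-tuning alternate in cycles to prevent the encoder from
   forgetting the pretrained representation.

Real corpora of this kind are private, so the package includes a
first-class synthetic-EMR generator: code ontologies with the right label
grammar, per-diagnosis disease profiles whose drug support concentrates on
one ontology branch, and single-/multi-visit corpora matching published
shape statistics (≈2.23 diagnoses, 16.8 drugs, 1 symptom per single visit;
≈1.4 diagnoses, 3.9 drugs and 2.27 visits per multi-visit patient).
Evaluation is per-visit Jaccard, average F1 and PR-AUC, with
logistic-regression and label-frequency baselines and an eight-variant
ablation harness.

## Worked example

The desk-scale study (three minutes on one CPU):

```python
from medrec import (SyntheticConfig, generate_dataset,
                    ExperimentConfig, MedicationRecommender)

dataset = generate_dataset(SyntheticConfig(
    n_diag_leaves=50, n_drug_leaves=100, n_symptoms=40,
    n_single_visit_patients=2000, n_multi_visit_patients=300, seed=11))

config = ExperimentConfig(width=32, layers=2, heads=4, gat_heads=4,
                          cycles=3, pretrain_epochs=8, finetune_epochs=8,
                          pretrain_learning_rate=1e-3, finetune_batch=8,
                          max_len={"d": 8, "m": 28, "s": 4})
results = MedicationRecommender.from_dataset(dataset, config).fit(seed=0)
print(results.summary())
```

```
Medication recommendation results
=================================================
seed                                            0
single-visit records                         2000
multi-visit patients                          300
train/val/test patients                 200/50/50
cycles x (pretrain, finetune)          3 x (8, 8)
knowledge / pretrain / FGM     True / True / True
-------------------------------------------------
test Jaccard                               0.1964
test average F1                            0.2585
test PR-AUC                                0.4041
evaluated visits                               65
best validation loss                      11.9096
=================================================
```

The test Jaccard is the mean over held-out patients' visits (from the
second visit on) of |Y∩Ŷ|/|Y∪Ŷ| between the true and recommended drug
sets; PR-AUC is micro-averaged average precision over every (visit, drug)
pair. For calibration: on the same splits a per-drug logistic-regression
baseline reaches Jaccard ≈ 0.22 while a label-frequency recommender scores
0, and stripping pretraining from the model drops it to ≈ 0.13 — the
planted diagnosis→drug structure is what the encoder is recovering. `results.predict(history)` returns per-visit drug probabilities and
the recommended set; `results.save(path)` writes a checkpoint.

The same pipeline is scriptable from the shell:

```sh
medrec simulate --config configs/tiny.yaml --out data/ --seed 1
medrec train    --data data/ --config configs/tiny.yaml --out model.ckpt --seed 1
medrec evaluate --model model.ckpt --data data/ --seed 1
medrec ablate   --config configs/tiny.yaml --seeds 3 --out ablation/
```

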