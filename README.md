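# lymphgraph

Patient-similarity graph convolutional networks for predicting **axillary
lymph node metastasis (ALNM)** in breast cancer from ultrasound-derived deep
features.

Deciding whether breast cancer has spread to the axillary lymph nodes today
requires sentinel-node biopsy or axillary dissection — invasive procedures
with real morbidity. This package implements a noninvasive alternative that
has been studied on multicenter B-mode ultrasound: extract a deep-feature
vector from each patient's lesion image, select a compact informative
subset, connect similar patients into a graph, and classify every patient
(node) with a graph convolutional network, so each prediction borrows
strength from similar patients.

The pipeline, end to end:

1. **Preprocess** each B-mode image: grayscale, crop the annotated lesion
   bounding box with a small margin, resize/pad to 224 × 224 preserving
   aspect ratio (seeded augmentation on the training cohort only).
2. **Extract features** with a 50-layer bottleneck residual network whose
   classification head is removed — 2048 features per image (a NumPy,
   forward-only reference implementation; any extractor can be plugged in
   through `BackboneContract`).
3. **Select features**: z-score with training statistics, drop one member
   of every pair with |Spearman ρ| > 0.85, then recursive feature
   elimination under a linear SVM (C = 1) with 10-fold stratified
   cross-validation.
4. **Build one graph per cohort**: nodes are patients, and an edge joins
   patients *i*, *j* when cos(xᵢ, xⱼ) ≥ τ for a similarity threshold
   τ ∈ {0.60, 0.70, 0.80, 0.95} (one model per threshold).
5. **Classify nodes** with a two-layer GCN,

       H⁽ˡ⁺¹⁾ = ReLU( D̃^(−1/2) Ã D̃^(−1/2) H⁽ˡ⁾ W⁽ˡ⁾ ),   Ã = A + I,
       Z = softmax( H⁽²⁾ W^fc ),

   trained with Adam (lr 1e-4, ≤ 500 epochs, loss mini-batches of 32
   nodes, dropout 0.5, early stopping on an internal stratified mask).
6. **Evaluate**: accuracy / sensitivity / specificity / PPV / NPV with
   bootstrap 95% CIs, ROC-AUC, pairwise DeLong tests, Pearson inter-model
   agreement, repeated-measures ANOVA, and decision-curve analysis against
   treat-all / treat-none.

The hospital cohorts such studies use are private, so the package ships a
first-class synthetic generator (`lymphgraph.synthetic`) that reproduces
the study skeleton — three cohorts of 621/112/87 patients at metastasis
prevalences 0.346/0.402/0.402, 2048-dimensional features with a planted
informative subspace, high-correlation redundant columns, and a
closed-form Bayes AUC Φ(Δ/√2) — so every stage is testable offline.
See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from lymphgraph import (
    make_study_cohorts, FeatureSelector, SelectionConfig,
    GCNNodeClassifier, roc_auc,
)

train, val1, val2 = make_study_cohorts(seed=7, n_features=2048)

selector = FeatureSelector(SelectionConfig(seed=7, n_features=22))
selector.fit(train.features, train.labels)
print(f"features: 2048 -> {selector.result_.kept_after_spearman.size} after "
      f"redundancy filter -> {selector.result_.selected.size} selected")

model = GCNNodeClassifier(threshold=0.95, seed=7)
model.fit(selector.transform(train.features), train.labels, ids=train.ids)

for name, cohort in (("validation 1", val1), ("validation 2", val2)):
    prob = model.predict_proba(selector.transform(cohort.features))[:, 1]
    _, auc = roc_auc(prob, cohort.labels)
    print(f"{name}: n={cohort.n_patients}  AUC={auc:.3f}  "
          f"(generative Bayes AUC {train.truth.bayes_auc:.3f})")
```

Output:

```
features: 2048 -> 1987 after redundancy filter -> 22 selected
validation 1: n=112  AUC=0.838  (generative Bayes AUC 0.921)
validation 2: n=87  AUC=0.914  (generative Bayes AUC 0.921)
```

Reading it: the Spearman filter removes the planted redundant columns
(2048 → 1987), elimination keeps a 22-feature table (the 24-column node
table: features + id + label), and the threshold-0.95 model recovers most
of the generative model's attainable discrimination (Bayes AUC 0.921) on
both held-out cohorts — external AUCs in the mid-0.8s to low-0.9s, the
regime the method reports on real data. `GCNNodeClassifier`,
`FeatureSelector` and `SpearmanRedundancyFilter` follow the scikit-learn
estimator protocol (`get_params`/`set_params`, `fit`/`transform`/
`predict_proba`), so they compose with sklearn model selection.

The same experiment is scriptable from a shell:

```bash
lymphgraph simulate --seed 7 --out runs/sim            # three cohort CSVs
lymphgraph run-all --seed 7 --out runs/full            # whole experiment
```

`run-all` writes, per threshold: graph exports (edge TSV, components,
summary), a training-history CSV, a parameter checkpoint, per-cohort
probability vectors, ROC tables and metric reports with CIs; plus
cross-model Pearson/DeLong/ANOVA comparisons, decision curves, and a
manifest of SHA-256 digests (re-running a config reproduces every artifact
byte for byte).

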