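# sarftex

Texture-image classification for medical imaging with **pyramid gray-level
co-occurrence (PGLCM) features** and a **self-attention random forest
(SARF)**.

## The problem

Histopathology slides and mammograms are often distinguished less by shape
than by *texture* — the local statistical structure of gray-level
variation.  Classical Haralick features summarize that structure through
the gray-level co-occurrence matrix (GLCM): the joint distribution
p(i, j) of gray levels of pixel pairs at a fixed offset (distance d,
direction θ).  This package implements a multi-scale version of that idea
plus a hybrid attention/forest classifier, aimed at tumor-subtype
classification of breast histopathology and mammogram triage, and at any
other problem where class identity lives in texture.

## The method

**Features (PGLCM).**  Each image is reduced to a Gaussian pyramid
(smoothed, 2×-downsampled levels).  At every level, for every distance
d ∈ {1, 2, 4} and direction θ ∈ {0°, 45°, 90°, 135°}, a symmetric
normalized GLCM is computed on the 16-level quantized image, and reduced
to four Haralick statistics:

- contrast  Σᵢⱼ p(i,j)(i−j)²
- correlation  Σᵢⱼ p(i,j)(i−μₓ)(j−μᵧ)/(σₓσᵧ)
- energy (angular second moment)  Σᵢⱼ p(i,j)²
- homogeneity  Σᵢⱼ p(i,j)/(1+(i−j)²)

Each statistic is fused across pyramid levels by its mean and standard
deviation, yielding a named feature vector of length
2 × 4 × |distances| × |angles| (96 by default), with names like
`i=1, 0° std contrast`.

**Classifier (SARF).**  A small self-attention network (SAN) is trained on
the features: its first layer reweights the input elementwise,
Ω(X) = (1/k) Σₕ X ⊗ softmax(W⁽ʰ⁾X + b⁽ʰ⁾), followed by a SELU dense
layer, dropout, a sigmoid dense layer and a softmax head, optimized with
Adam on cross-entropy.  After training, the *global attention*
R_G = (1/k) Σₕ softmax(diag W⁽ʰ⁾) is a probability distribution over
features that doubles as a feature-importance ranking.  The features are
then residually reweighted, F′ = F + F ⊗ (|F|·R_G), and a bagged forest
of depth-bounded decision trees is fitted on F′ with majority-vote
prediction.  The forest's per-tree bootstrap records support out-of-bag
permutation importance, J(xⱼ) = (1/T) Σₖ (1/|Bₖ|) [errₖ(permute xⱼ) −
errₖ], a second, classifier-side importance measure.  Grid search over
(tree depth, tree count) by stratified cross-validation is built in.

The evaluation suite provides confusion matrices, overall accuracy,
one-vs-rest sensitivity / specificity / positive and negative prediction
rates, ROC curves with trapezoidal AUC, and micro-averaged multiclass AUC.

No external image dataset is required: `sarftex.synthetic` generates
seeded textured images (oriented gratings, Gaussian random fields,
checkerboards) whose classes are separable by GLCM statistics by
construction, plus tabular benchmarks with a known informative/noise
feature split.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from sarftex import (SARF, SANConfig, ForestConfig, TextureClassSpec,
                     gen_texture_dataset, extract_dataset, confusion_matrix,
                     overall_accuracy, per_class_metrics)

specs = [TextureClassSpec(name="horizontal", orientation=0, n_images=60),
         TextureClassSpec(name="vertical", orientation=90, n_images=60)]
entries = gen_texture_dataset(specs, seed=0)
table = extract_dataset(entries)          # 120 rows x 96 features + label

train_df, test_df = train_test_split(table, test_size=0.3, random_state=0,
                                     stratify=table["label"])
res = SARF.from_dataframe(train_df,
                          san_config=SANConfig(seed=0),
                          forest_config=ForestConfig(seed=0)).fit()
print(res.summary(top=5))
```

```
Self-Attention Random Forest Results
======================================================
N observations:     84
N features:         96
Classes:            horizontal, vertical
Attention heads:    1   epochs: 20   batch: 16
Forest:             200 trees, max depth 20
Final SAN loss:     0.0083
Training accuracy:  100.00%
------------------------------------------------------
Top 5 features by global attention R_G:
  i=1, 0° mean correlation         0.0118
  i=1, 90° mean correlation        0.0118
  i=2, 0° mean homogeneity         0.0118
  i=2, 0° std contrast             0.0117
  i=2, 0° std correlation          0.0117
======================================================
```

The two grating classes differ in the orientation of their stripes, so the
attention concentrates on direction-sensitive co-occurrence features
(uniform attention would be 1/96 ≈ 0.0104).  Held-out evaluation:

```python
pred = res.predict(test_df.drop(columns=["label"]))
cm = confusion_matrix(test_df["label"], pred, res.classes)
print(f"held-out accuracy: {overall_accuracy(cm):.2f}%")
m = per_class_metrics(cm, "vertical")
print(f"vertical: Sen {m.sen:.2f}%  Spe {m.spe:.2f}%  PPR {m.ppr:.2f}%")
```

```
held-out accuracy: 100.00%
vertical: Sen 100.00%  Spe 100.00%  PPR 100.00%
```

The same workflow is available from the shell:

```bash
sarftex augment  --manifest data/manifest.csv --out-dir work/augmented
sarftex extract  --manifest work/augmented/manifest.csv --out work/features.csv
sarftex train    --features work/features.csv --out-dir work/run --seed 0
sarftex tune     --features work/features.csv --out-dir work/tuned \
                 --d-min 10 --d-max 30 --n-min 190 --n-max 230
sarftex evaluate --model work/run/model.pkl --features work/features.csv \
                 --out work/metrics.json
sarftex explain  --model work/run/model.pkl --out work/importance.csv
```

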