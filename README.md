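# scpatch

Supervised cell-type annotation for single-cell RNA-seq using a
patch-embedding transformer, implemented in pure numpy (including training
via a compact reverse-mode autodiff), with a synthetic-data generator and
the evaluation/experiment protocols needed to exercise everything offline.

## Who it is for

Computational biologists who have a labelled scRNA-seq reference (cells ×
genes counts plus per-cell type labels) and want to train a classifier that
annotates new cells of the same tissue, plus a reproducible harness for
studying how such a model behaves under class imbalance, input gene
ordering, and patch-size choices.

## The model

A cell's G log-normalised expression values are laid into a 2D grid and cut
into N = ⌈G/P²⌉ flattened patches of P² values. Each patch is linearly
projected to a D-dimensional token; a learnable class token is prepended
and learned position embeddings are added. The sequence passes through
`depth` pre-norm transformer encoder blocks,

    h ← h + MHSA(LN(h));   h ← h + MLP(LN(h)),

with exact-erf GELU activations, and a three-layer MLP head maps the pooled
representation to K softmax class confidences. Training minimises sparse
categorical cross-entropy, L = −(1/n) Σᵢ ln p̂ᵢ[yᵢ], with momentum SGD,
decoupled weight decay, and a cosine learning-rate decline
r_t = 0.5·r₀·(1 + cos(tπ/T)) floored at `end_lr`. Evaluation reports
accuracy, macro precision/recall/F1 and mean per-class one-vs-rest MCC from
the confusion matrix. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from scpatch import (ModelConfig, TrainConfig, LabelMap, build_confusion,
                     compute_metrics, generate, log_normalize, PRESETS,
                     predict_labels, split_train_test, train_model)

m = log_normalize(generate(PRESETS["separable"]))   # 400 cells x 1024 genes
train, test = split_train_test(m, train_fraction=0.8, seed=7)

state, history = train_model(train,
                             ModelConfig.desk_preset(n_classes=4),
                             TrainConfig.desk_preset(seed=1))
print(f"final epoch loss {history.loss.iloc[-1]:.4f}, "
      f"train accuracy {history.train_acc.iloc[-1]:.4f}")

preds = predict_labels(test, state)                  # (cell_id, type, conf)
label_map = LabelMap(sorted(set(m.labels)))
report = compute_metrics(build_confusion(test.labels,
                                         [p[1] for p in preds], label_map))
print(f"test accuracy {report.accuracy:.4f}, macro F1 {report.macro_f1:.4f}")
```

Output:

```
final epoch loss 0.0065, train accuracy 1.0000
test accuracy 1.0000, macro F1 1.0000
```

The fixture is a zero-inflated negative-binomial simulation of four cell
types with disjoint 100-gene marker programs (~82% zeros); the desk-preset
model (2 encoder blocks, D=32) separates the held-out 80 cells essentially
perfectly, and `history` records per-epoch loss, training accuracy and
learning rate.

The same pipeline is available from the shell:

```bash
scpatch simulate --preset separable --out counts.csv --labels-out labels.csv
scpatch train --matrix counts.csv --labels labels.csv --checkpoint ckpt/
scpatch predict --matrix counts.csv --checkpoint ckpt/ --out pred.csv
scpatch evaluate --truth labels.csv --predictions pred.csv
scpatch replicate --matrix counts.csv --labels labels.csv --replicates 5
scpatch permute-test --matrix counts.csv --labels labels.csv
scpatch ablate-patch --matrix counts.csv --labels labels.csv --sizes 4,8,16
```

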