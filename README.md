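# tumorcnn

A compact, fully auditable convolutional network for multi-class brain-tumor
classification on contrast-enhanced T1-weighted MRI slices (meningioma vs
glioma vs pituitary tumor), together with the cross-validation
transfer-learning protocols used to train and evaluate it.

The package is aimed at researchers who want to (a) account exactly for what
a small CNN costs — trainable parameters and multiply-accumulate (MAC)
operations, layer by layer — and (b) study how weight carry-over between
cross-validation folds and iterations changes measured performance,
including the train/test contamination such carry-over introduces.

## The model

The classifier is a sequential 13-layer CNN for 256×256×1 inputs:
3×3 convolutions (32 filters, ReLU) interleaved with 1×1 "bottleneck"
convolutions (10 filters, ReLU) and 2×2 average pooling, closed by a
64-unit dense layer and a 3-way softmax. All convolutions use valid padding
and stride 1; pool stride equals the pool size. Spatial shapes follow

    h_out = floor((h_in − f + 2P) / s) + 1

and the MAC cost of a convolution is counted as

    C = f · f · c_in · h_out · w_out · n_f

(multiplications only). The 1×1 layers shrink the channel count before each
spatial convolution: on a (256, 256, 32) input a plain 3×3×32 convolution
costs 594,579,456 MACs, while a 10-filter 1×1 bottleneck followed by the
same 3×3 layer costs 206,451,200 — about a third. The full network audits
to **583,613 trainable parameters**.

Training uses Adam with sparse-categorical cross-entropy, batch size 25,
initial learning rate 0.01, up to 10 epochs with early stopping on
validation loss (see `docs/methods.md` for the desk-scale variant used with
small synthetic studies).

## Protocols

Three five-fold cross-validation designs, mirroring how lightweight tumor
classifiers are trained in practice:

* **case 1** — plain CV: fresh weights per fold (leak-free baseline);
* **case 2** — iterated transfer learning: repeated CV passes, each seeded
  with a model carried from the previous pass;
* **case 3** — fold-to-fold internal transfer learning: each fold resumes
  from the previous fold's trained weights within a single CV pass.

Cases 2 and 3 deliberately re-train on data that earlier served as test
folds; every run produces a **leakage audit** listing, per fold, the
earlier-fold test samples present in its training set — the contamination is
quantified, never hidden. A `stability_pass` re-runs CV where each fold
independently fine-tunes one trained checkpoint.

Because the real 3,064-slice collection requires a download, the package
ships a seeded phantom generator (`tumorcnn.synth`) whose three lesion
classes are separable by construction, so every protocol and metric is
exercisable offline end-to-end.

## Worked example

```python
from tumorcnn import audit, fast_tumor_cnn_spec, conv2d, layer_cost

rep = audit(fast_tumor_cnn_spec(True))
print(rep.total_params, rep.depth)
# 583613 13

plain = layer_cost(conv2d(3, 32), (256, 256, 32))
pair = layer_cost(conv2d(1, 10), (254, 254, 32)) + layer_cost(conv2d(3, 32), (256, 256, 10))
print(plain, pair)
# 594579456 206451200
```

Evaluating a fold from its confusion matrix (counts reconstructed from the
published first-fold report; rows = true class, columns = predicted):

```python
import numpy as np
from tumorcnn import ConfusionMatrix, report

cm = ConfusionMatrix(np.array([[145, 4, 0], [5, 277, 0], [0, 0, 182]]),
                     ("meningioma", "glioma", "pituitary"))
rep = report(cm)
print(f"{rep.accuracy:.2f}")                                  # 98.53
print({k: round(v, 2) for k, v in rep.per_class["meningioma"].items()})
# {'precision': 96.67, 'recall': 97.32, 'f1': 96.99, 'specificity': 98.92}
```

604 of 613 slices are correct (98.53% accuracy); per-class values are
one-vs-rest percentages and `rep.macro` averages them without class weights.

The `examples/` directory holds short narrative scripts for each
capability: `audit_architecture.py`, `generate_phantoms.py`,
`evaluate_metrics.py` and `train_protocols.py` (the last one trains the
model on phantoms under cases 1 and 3 and prints the leakage audit). A thin
CLI exposes the same steps: `tumorcnn audit`, `tumorcnn synth`,
`tumorcnn train`, `tumorcnn evaluate`.

## Layout

```
src/tumorcnn/arch.py       layer/model specs, shape inference, param + MAC audit
src/tumorcnn/runtime.py    numpy CNN runtime: forward/backward, Adam, early stopping
src/tumorcnn/protocols.py  fold plans, cases 1-3, stability pass, leakage audit
src/tumorcnn/metrics.py    confusion matrix, per-class and macro metrics
src/tumorcnn/data_io.py    .mat (HDF5 cjdata) and image-directory loaders
src/tumorcnn/synth.py      seeded phantom generator + .mat fixture writer
src/tumorcnn/cli.py        thin command-line surface
```
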