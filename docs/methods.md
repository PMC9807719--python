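# Methods

This note documents the model conventions, the numerical choices, and the
design decisions behind `tumorcnn`, in the spirit of a model-description
appendix. It states nothing the test suite or the acceptance script does
not itself compute.

## Architecture accounting

A `ModelSpec` is a purely declarative object; all auditing is closed-form
arithmetic on it, independent of the tensor runtime.

* **Shape rule.** Convolution and pooling both follow
  `out = floor((in − f + 2P)/s) + 1` per spatial axis. Published
  descriptions of this architecture print a pooling rule dividing by
  `s + 1`; that rule is inconsistent with every shape in the published
  configuration table (it would map width 254 to 84 rather than 127), so the
  standard rule above — which reproduces every cell — is used for pooling
  as well.
* **Padding and strides.** Valid padding (P = 0) everywhere; convolution
  stride 1; pool stride = pool size 2. These are the only values consistent
  with the 256→254 and 127→125 transitions in the configuration table.
* **Parameter counting.** Conv: `(f_h·f_w·c_in + 1)·n_filters`; dense:
  `(len_in + 1)·n_units`; biases are included (the table's first-layer count
  320 = (9·1+1)·32 forces this); pooling and flatten hold no parameters.
* **MAC cost.** `C = f_h·f_w·c_in·h_out·w_out·n_f` for convolutions —
  multiplications only, no bias or accumulation adds (forced by the
  published worked examples). Dense cost is defined as `len_in·n_units` and
  pool/flatten as 0; these two are package conventions for completeness of
  the totals column, not published values. Note the published
  bottleneck-pair example costs *both* members of the (1×1, 3×3) pair on the
  final 254×254 grid; the acceptance computation follows that accounting.
* **Depth convention.** "13 layers" counts 8 convolutions, 3 pools and
  2 dense layers; flatten is a reshape and is not counted. This is the only
  reading that makes the canonical stack 13 deep; `CostReport.depth`
  documents it.
* **Bottleneck economics.** Inserting a k-filter 1×1 layer before a 3×3
  convolution reduces the pair's MAC cost whenever k is small relative to
  the channel counts; it is *not* a free lunch for k close to c_in. The
  property test asserts the reduction under the sufficient condition
  k ≤ c_in/2, k ≤ n_f, spatial dims ≥ 8, which is provable from the cost
  formula.

## Runtime

No differentiable-tensor library is part of the dependency set; the runtime
is a self-contained numpy implementation: im2col convolution (stride-tricks
window views), average pooling, dense layers, manual backpropagation, and
Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7). Weight init is Glorot-uniform from a
seeded generator; biases start at zero. The realized parameter count always
equals the static audit — asserted in tests for the canonical model at both
64×64 and 256×256.

* **Loss.** Sparse-categorical cross-entropy, mean over the batch, with the
  probability at the true class clamped to ≥ 1e−7 so a confident wrong
  prediction is large but finite. The softmax/cross-entropy pair is fused in
  the backward pass (gradient `p − onehot`).
* **Activations.** ReLU, sigmoid, tanh, softmax. The package exposes the
  standard tanh; one printed formulation circulating for this model,
  `2/(1 + e^(−2x))`, equals `1 + tanh(x)` and is not a sigmoid-family
  activation — the canonical model uses only ReLU and softmax, so nothing
  downstream depends on the choice.
* **Early stopping.** Monitors validation loss with patience 2 by default
  and restores the best epoch's weights; training history never extends a
  promise past `max_epochs`. The validation set is a stratified 10% of each
  fold's training portion — the 80% training share is "training and
  validation", and the 10% split is this package's convention.
* **Determinism.** Initialization and epoch shuffling derive from explicit
  integer seeds. Bit-reproducibility is promised in single-threaded BLAS
  mode; otherwise reproducibility is statistical.
* **Divergence.** A non-finite batch loss or network output aborts training
  with a diagnostic rather than continuing on NaNs.

## Training recipes

The production recipe is Adam, learning rate 0.01, batch 25, ≤ 10 epochs
with early stopping — the configuration used with the full 3,064-slice
dataset at 256×256, where an epoch is ~98 optimizer steps.

The **desk-scale recipe** (`TrainConfig.desk_scale()`: learning rate 0.001,
≤ 30 epochs, patience 3) exists because scaled-down studies change the
optimization geometry: with 300 phantoms at 64×64 an epoch is ~10 Adam
steps, and at rate 0.01 the narrow 10-channel bottleneck layers collapse
into all-zero ReLUs within the first epochs, leaving the network at chance.
Lowering the rate one decade and letting early stopping govern a larger
epoch cap keeps the total step budget comparable to the production setting.
The synthetic acceptance study (300 phantoms, 64×64, five-fold case-1 CV,
seed 0) uses this recipe and reaches a mean held-out accuracy above 99% in
roughly three minutes on one CPU; the test asserts the ≥ 90% bound.

## Protocols

Folds are stratified by class (this reproduces the 613/612 test-fold sizes
that the class totals 708/1426/930 imply); a group-aware option exists for
patient-disjoint splits, but slice-level splitting is the default because
the published protocol gives no indication of patient grouping.

* **Case 1.** Every fold builds a fresh model from the same base seed
  (identical initial weights, no carry-over); per-(iteration, fold) shuffle
  seeds are derived deterministically. This reading makes case 2 with one
  iteration bit-identical to case 1, which the tests assert.
* **Case 2.** After each full CV pass the last fold's trained model seeds
  every fold of the next pass (`carry_rule` makes the fold configurable —
  the published description only says the trained model is saved and
  retrained). The carried model accumulates one lineage event per
  iteration.
* **Case 3.** Fold j > 0 resumes from fold j−1's weights. The leakage audit
  records, for each fold, the earlier folds' test samples inside its
  training set — for fold j this is exactly the union of test folds < j,
  and the test suite asserts that set identity.
* **Stability pass.** Interpreted as independent fine-tuning: each fold
  fine-tunes an isolated copy of the source checkpoint (default: the fourth
  fold's case-3 model). The alternative reading — continued carrying — is
  run_case3 restarted from the checkpoint and needs no separate operation.
* **Summaries.** Mean and *sample* standard deviation (n−1 denominator) per
  metric; this is the convention under which the published per-fold
  accuracy rows recompute to their printed Mean/SD cells at 2 dp. About one
  printed summary cell in seven differs by exactly one unit in its last
  digit when recomputed from the printed (2-dp) fold values — those summary
  rows were evidently computed from unrounded fold metrics, so recomputation
  from printed inputs carries a ±0.01 rounding limit, which the acceptance
  test enforces as the agreement bound.

## Metrics

Rows = true class, columns = predicted (the orientation is a package
convention; published figures are images). Per-class precision, recall, F1
and specificity come from one-vs-rest counts; macro averages are unweighted;
overall accuracy is trace/total. A metric with a zero denominator is
reported as 0 and the class is flagged in `EvalReport.degenerate` —
conservative and never silent. Percentages are reported to full precision
and rounded to 2 dp only at the serialization boundary.

## Phantom generator

Phantoms emulate only what the protocols need: a head-like ellipse with a
mild intensity gradient plus one class-dependent lesion (rim-adjacent bright
disc / off-center textured mid-intensity blob / small central-inferior
bright disc), with additive Gaussian noise (σ = 0.05 by default) and
clipping to [0, 1]. Class counts follow the configured proportions by
largest-remainder allocation; everything is reproducible from the seed.
Defaults: 300 samples, equal proportions, lesion radius 5–12% of the image
width; 64×64 for studies, 256×256 available.

The classes are separable by construction — a nearest-centroid rule on
three scalar lesion features (radial distance, blob area, blob peak
intensity) exceeds 95% accuracy at default noise — so a CNN failing to
learn them indicates a runtime defect, not an impossible task. The
phantoms deliberately do **not** model MR physics, anatomy, patient
structure, scanner variation, or class imbalance; passing the synthetic
studies therefore demonstrates that the training machinery and protocols
work, not that the architecture reaches any particular accuracy on real
MRI data.

## Problem sizes used by the test suite

Unit and protocol tests run a minimal conv net on 16×16 phantoms; the one
full training study uses the canonical architecture at 64×64 on 300
phantoms (about three minutes); the architecture audit, cost calculus,
confusion arithmetic and summary-convention checks are closed-form and run
in milliseconds. The acceptance script performs no training: the cost
figures it recomputes are exact integer arithmetic.

## Known limitations

* Sequential topologies only — no branches, residuals, batch norm, dropout
  or augmentation (none are part of this design).
* The numpy runtime targets clarity and small models; it is single-threaded
  NumPy-BLAS speed, not a deep-learning framework.
* Real-data reproduction of the published headline accuracies requires the
  external MRI collection and stochastic training, and is out of scope; the
  package reproduces the architecture accounting, the metric arithmetic and
  the protocol semantics exactly, and demonstrates training end-to-end on
  synthetic data.
* Patient-disjoint cross-validation is available but not the default, to
  match the published slice-level protocol.
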