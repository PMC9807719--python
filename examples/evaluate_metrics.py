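"""Evaluation metrics from a confusion matrix.

Builds the first-fold confusion matrix of the published final model (604 of
613 test slices correct) and derives accuracy, per-class precision/recall/
F1/specificity and their macro averages from it.
"""

import numpy as np

from tumorcnn import ConfusionMatrix, one_vs_rest, report

cm = ConfusionMatrix(
    np.array([[145, 4, 0],
              [5, 277, 0],
              [0, 0, 182]]),
    ("meningioma", "glioma", "pituitary"))

rep = report(cm, loss=0.05)
print(f"scored slices: {cm.total}, correct: {int(np.trace(cm.counts))}")
print(f"overall accuracy: {rep.accuracy:.2f}%")
print(f"{'class':<12} {'TP':>4} {'FP':>4} {'FN':>4} {'TN':>4} "
      f"{'prec':>7} {'recall':>7} {'F1':>7} {'spec':>7}")
for i, name in enumerate(cm.class_names):
    tp, fp, fn, tn = one_vs_rest(cm, i)
    pc = rep.per_class[name]
    print(f"{name:<12} {tp:>4} {fp:>4} {fn:>4} {tn:>4} "
          f"{pc['precision']:>7.2f} {pc['recall']:>7.2f} {pc['f1']:>7.2f} "
          f"{pc['specificity']:>7.2f}")
print("macro: " + "  ".join(f"{k}={v:.2f}" for k, v in rep.macro.items()))
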