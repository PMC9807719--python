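"""Cross-validation training protocols with and without transfer learning.

Three experimental designs over stratified k-fold cross-validation:

* **case 1** — plain k-fold CV: every fold trains a freshly initialized
  model and is scored on its held-out fold.
* **case 2** — iterated transfer learning: repeated full CV passes where
  each iteration's folds all start from a model carried over from the
  previous iteration (iteration 1 starts fresh, so a single iteration is
  behaviorally identical to case 1 under the same seeds).
* **case 3** — fold-to-fold internal transfer learning: fold 1 trains from
  scratch and each later fold resumes from the previous fold's trained
  weights.  This carries knowledge of earlier folds' *test* samples into
  later training sets; the resulting train/test contamination is quantified
  per fold in a leakage audit rather than hidden.

A post-hoc :func:`stability_pass` re-runs CV where every fold independently
fine-tunes a copy of one trained checkpoint (by default the fourth fold's
model from a case-3 run).

Fold indices are 0-based throughout.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .arch import ModelSpec
from .metrics import EvalReport, confusion_matrix, report
from .runtime import ModelState, TrainConfig, build_model, loss as ce_loss, predict, train

__all__ = [
    "FoldPlan",
    "ProtocolConfig",
    "FoldReport",
    "ProtocolResult",
    "make_folds",
    "run_case1",
    "run_case2",
    "run_case3",
    "stability_pass",
    "summarize",
]

SUMMARY_METRICS = ("accuracy", "loss", "f1", "precision", "recall", "specificity")


@dataclass(frozen=True)
class FoldPlan:
    """Per-sample fold assignment for k-fold cross-validation."""

    n_folds: int
    assignment: np.ndarray  # fold index per sample
    stratified: bool
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class ProtocolConfig:
    """Which case to run and how.

    ``carry_rule`` (case 2): which fold's trained model seeds every fold of
    the next iteration — ``"last"`` or an explicit 0-based fold index.
    ``source_fold`` (stability pass): 0-based index of the checkpoint fold;
    the default 3 is the fourth fold.
    """

    case: str = "case1"
    n_iterations: int = 5
    carry_rule: str | int = "last"
    source_fold: int = 3
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.case not in ("case1", "case2", "case3"):
            raise ValueError(f"unknown case {self.case!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FoldReport:
    """Evaluation of one (iteration, fold) training unit."""

    iteration: int
    fold: int
    report: EvalReport
    stopped_epoch: int
    best_epoch: int
    n_train: int
    n_test: int
    leaked_test_samples: tuple[int, ...]  # earlier-fold test samples in this training set

    def metric(self, name: str) -> float:
        if name == "accuracy":
            return self.report.accuracy
        if name == "loss":
            return self.report.loss
        return self.report.macro[name]


@dataclass
class ProtocolResult:
    per_unit: list[FoldReport]
    summary: dict[str, tuple[float, float]]
    per_iteration_summaries: dict[int, dict[str, tuple[float, float]]]
    final_state: ModelState
    leakage_audit: dict[tuple[int, int], tuple[int, ...]]

    def to_json(self) -> str:
        doc = {
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary.items()},
            "per_iteration_summaries": {
                str(it): {k: {"mean": m, "sd": s} for k, (m, s) in summ.items()}
                for it, summ in self.per_iteration_summaries.items()},
            "per_unit": [
                {"iteration": u.iteration, "fold": u.fold,
                 "accuracy": u.report.accuracy, "loss": u.report.loss,
                 "macro": u.report.macro, "stopped_epoch": u.stopped_epoch,
                 "best_epoch": u.best_epoch, "n_train": u.n_train,
                 "n_test": u.n_test,
                 "n_leaked": len(u.leaked_test_samples)}
                for u in self.per_unit],
        }
        return json.dumps(doc, indent=2)

    def folds_csv(self, stream: IO[str]) -> None:
        w = csv.writer(stream)
        w.writerow(["iteration", "fold", "accuracy", "loss", "f1", "precision",
                    "recall", "specificity", "n_train", "n_test", "n_leaked"])
        for u in self.per_unit:
            w.writerow([u.iteration, u.fold,
                        f"{u.report.accuracy:.2f}", f"{u.report.loss:.4f}",
                        *(f"{u.report.macro[k]:.2f}" for k in
                          ("f1", "precision", "recall", "specificity")),
                        u.n_train, u.n_test, len(u.leaked_test_samples)])

    def leakage_csv(self, stream: IO[str]) -> None:
        w = csv.writer(stream)
        w.writerow(["iteration", "fold", "leaked_test_sample_indices"])
        for (it, f), idx in sorted(self.leakage_audit.items()):
            w.writerow([it, f, " ".join(map(str, idx))])


def make_folds(labels, k: int = 5, seed: int = 0, stratified: bool = True,
               groups=None) -> FoldPlan:
    """Deterministic (stratified) k-fold assignment.

    With ``stratified`` every class is spread across folds so fold sizes per
    class differ by at most one; pass ``groups`` (e.g. patient ids) for a
    group-disjoint split instead.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if groups is not None:
        from sklearn.model_selection import GroupKFold
        splitter = GroupKFold(n_splits=k)
        split = splitter.split(np.zeros(len(y)), y, groups)
    elif stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(f"stratified {k}-fold needs >= {k} samples per class")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)))
    assignment = np.full(len(y), -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold
    assert (assignment >= 0).all()
    return FoldPlan(n_folds=k, assignment=assignment,
                    stratified=stratified and groups is None, seed=seed)


def summarize(values_per_fold: Sequence) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n-1 denominator) per metric over fold reports.

    Accepts a sequence of :class:`FoldReport`/:class:`EvalReport`, or of
    plain numbers (summarized under the key ``"value"``).
    """
    if len(values_per_fold) < 2:
        raise ValueError("need >= 2 reports for a mean/SD summary")
    first = values_per_fold[0]
    if isinstance(first, (int, float, np.floating)):
        v = np.asarray(values_per_fold, dtype=np.float64)
        return {"value": (float(v.mean()), float(v.std(ddof=1)))}
    out = {}
    for name in SUMMARY_METRICS:
        if isinstance(first, FoldReport):
            v = np.array([u.metric(name) for u in values_per_fold])
        else:  # EvalReport
            v = np.array([
                r.accuracy if name == "accuracy" else
                r.loss if name == "loss" else r.macro[name]
                for r in values_per_fold])
        out[name] = (float(v.mean()), float(v.std(ddof=1)))
    return out


def _derive_seed(base: int, iteration: int, fold: int) -> int:
    return (base * 100003 + iteration * 1009 + fold * 101 + 7) % (2 ** 31)


def _unit(data, plan: FoldPlan, state: ModelState, config: ProtocolConfig,
          iteration: int, fold: int, protocol: str) -> FoldReport:
    """Train ``state`` in place on one fold's training portion and score it
    on the fold's test portion."""
    images, labels = data
    tr_idx = plan.train_indices(fold)
    te_idx = plan.test_indices(fold)
    seed = _derive_seed(config.train_config.seed, iteration, fold)

    # leakage: test samples of folds trained on earlier in this state's lineage
    prior_folds = {(ev.get("iteration"), ev.get("fold")) for ev in state.lineage
                   if ev.get("protocol") in ("case2", "case3", "stability")}
    leaked: set[int] = set()
    for (it_prev, f_prev) in prior_folds:
        if f_prev is None:
            continue
        leaked.update(plan.test_indices(f_prev).tolist())
    leaked_now = tuple(sorted(leaked.intersection(tr_idx.tolist())))

    x_tr, x_va, y_tr, y_va = train_test_split(
        images[tr_idx], labels[tr_idx],
        test_size=config.train_config.val_fraction,
        stratify=labels[tr_idx], random_state=seed % (2 ** 32 - 1))
    tc = TrainConfig(**{**config.train_config.to_dict(), "seed": seed})
    result = train(state, (x_tr, y_tr), (x_va, y_va), tc,
                   lineage_event={"protocol": protocol, "iteration": iteration,
                                  "fold": fold})
    probs, pred = predict(state, images[te_idx])
    n_classes = probs.shape[1]
    cm = confusion_matrix(labels[te_idx], pred, n_classes)
    test_loss = ce_loss(labels[te_idx], probs)
    return FoldReport(iteration=iteration, fold=fold,
                      report=report(cm, test_loss),
                      stopped_epoch=result.stopped_epoch,
                      best_epoch=result.best_epoch,
                      n_train=len(tr_idx), n_test=len(te_idx),
                      leaked_test_samples=leaked_now)


def _result(per_unit, final_state) -> ProtocolResult:
    iterations = sorted({u.iteration for u in per_unit})
    per_iter = {it: summarize([u for u in per_unit if u.iteration == it])
                for it in iterations}
    return ProtocolResult(
        per_unit=per_unit,
        summary=per_iter[iterations[-1]],
        per_iteration_summaries=per_iter,
        final_state=final_state,
        leakage_audit={(u.iteration, u.fold): u.leaked_test_samples
                       for u in per_unit},
    )


def run_case1(data, plan: FoldPlan, config: ProtocolConfig,
              spec: ModelSpec) -> ProtocolResult:
    """Plain k-fold CV: a fresh model per fold, no weight carry-over.

    The leakage audit is empty by construction.
    """
    per_unit = []
    state = None
    for fold in range(plan.n_folds):
        state = build_model(spec, seed=config.train_config.seed)
        per_unit.append(_unit(data, plan, state, config, iteration=1,
                              fold=fold, protocol="case1"))
    return _result(per_unit, state)


def run_case2(data, plan: FoldPlan, config: ProtocolConfig,
              spec: ModelSpec) -> ProtocolResult:
    """Iterated transfer learning: each CV pass seeds the next.

    Iteration 1 starts from a fresh initialization (so with
    ``n_iterations=1`` the per-fold reports coincide with case 1 under the
    same seeds).  After each iteration the model selected by ``carry_rule``
    is carried into every fold of the next iteration; from iteration 2
    onward the carried weights have seen earlier folds' test samples, which
    the leakage audit records.
    """
    per_unit = []
    inherited = build_model(spec, seed=config.train_config.seed)
    final_state = inherited
    for it in range(1, config.n_iterations + 1):
        fold_states = []
        for fold in range(plan.n_folds):
            state = inherited.copy()
            per_unit.append(_unit(data, plan, state, config, iteration=it,
                                  fold=fold, protocol="case2"))
            fold_states.append(state)
        carry = plan.n_folds - 1 if config.carry_rule == "last" else int(config.carry_rule)
        inherited = fold_states[carry]
        final_state = inherited
    return _result(per_unit, final_state)


def run_case3(data, plan: FoldPlan, config: ProtocolConfig,
              spec: ModelSpec) -> ProtocolResult:
    """Fold-to-fold internal transfer learning within one CV pass.

    Fold 0 trains from scratch; fold j > 0 resumes from fold j-1's trained
    weights.  The leakage audit for fold j is exactly the union of the test
    sets of folds < j (all of which lie inside fold j's training set).
    """
    per_unit = []
    state = build_model(spec, seed=config.train_config.seed)
    for fold in range(plan.n_folds):
        per_unit.append(_unit(data, plan, state, config, iteration=1,
                              fold=fold, protocol="case3"))
    return _result(per_unit, state)


def stability_pass(state: ModelState, data, plan: FoldPlan,
                   config: ProtocolConfig) -> ProtocolResult:
    """Re-run CV where every fold fine-tunes an independent copy of ``state``.

    Measures how stable a trained checkpoint's performance is across folds;
    the copies are isolated (no weight sharing between folds).
    """
    if not any(ev.get("protocol") == "case3" for ev in state.lineage):
        raise ValueError("stability_pass expects a state with case-3 lineage")
    per_unit = []
    last = None
    for fold in range(plan.n_folds):
        clone = state.copy()
        per_unit.append(_unit(data, plan, clone, config, iteration=1,
                              fold=fold, protocol="stability"))
        last = clone
    return _result(per_unit, last)
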