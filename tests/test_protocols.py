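"""Cross-validation protocol semantics: folds, carries, leakage, summaries."""

import numpy as np
import pytest

from tumorcnn import (ProtocolConfig, TrainConfig, make_folds, run_case1,
                      run_case2, run_case3, stability_pass, summarize)

TABLE4_ACCURACIES = (92.82, 93.64, 92.82, 92.66, 93.46)


def _fast_config(case="case1", n_iterations=1, seed=11):
    return ProtocolConfig(
        case=case, n_iterations=n_iterations,
        train_config=TrainConfig(learning_rate=0.002, max_epochs=2,
                                 batch_size=16, seed=seed))


class TestMakeFolds:
    def test_even_split(self):
        plan = make_folds([0, 1, 2] * 3 + [0], k=5, seed=0, stratified=False)
        sizes = [len(plan.test_indices(f)) for f in range(5)]
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_figshare_class_counts_give_612_or_613(self):
        labels = np.repeat([0, 1, 2], [708, 1426, 930])
        plan = make_folds(labels, k=5, seed=0)
        sizes = {len(plan.test_indices(f)) for f in range(5)}
        assert sizes <= {612, 613}
        # stratification: per-class fold sizes differ by at most one
        for c, total in zip(range(3), (708, 1426, 930)):
            per_fold = [int(np.sum(labels[plan.test_indices(f)] == c))
                        for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == total

    def test_deterministic_for_fixed_seed(self):
        labels = np.tile([0, 1, 2], 20)
        a = make_folds(labels, k=5, seed=9)
        b = make_folds(labels, k=5, seed=9)
        assert np.array_equal(a.assignment, b.assignment)
        c = make_folds(labels, k=5, seed=10)
        assert not np.array_equal(a.assignment, c.assignment)

    def test_every_sample_assigned_once(self):
        labels = np.tile([0, 1, 2], 10)
        plan = make_folds(labels, k=3, seed=0)
        all_test = np.concatenate([plan.test_indices(f) for f in range(3)])
        assert sorted(all_test.tolist()) == list(range(30))

    def test_small_class_rejected_under_stratification(self):
        with pytest.raises(ValueError, match="per class"):
            make_folds([0, 0, 0, 1], k=3, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds([0, 1] * 5, k=1, seed=0)


class TestSummarize:
    def test_published_fold_accuracies(self):
        mean, sd = summarize(TABLE4_ACCURACIES)["value"]
        assert round(mean, 2) == 93.08
        assert round(sd, 2) == 0.44

    def test_identical_values_have_zero_sd(self):
        assert summarize([5.0, 5.0, 5.0])["value"][1] == 0.0

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(90, 3, rng.integers(2, 9))
            mean, sd = summarize(v.tolist())["value"]
            mu = sum(v) / len(v)
            var = sum((x - mu) ** 2 for x in v) / (len(v) - 1)
            assert mean == pytest.approx(mu)
            assert sd == pytest.approx(var ** 0.5)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize([1.0])


class TestCase1:
    def test_reports_disjoint_and_leakage_empty(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=1)
        res = run_case1((images, labels), plan, _fast_config(), tiny_spec)
        assert len(res.per_unit) == 3
        for u in res.per_unit:
            tr = set(plan.train_indices(u.fold).tolist())
            te = set(plan.test_indices(u.fold).tolist())
            assert tr.isdisjoint(te)
            assert u.leaked_test_samples == ()
        assert all(v == () for v in res.leakage_audit.values())

    def test_summary_mean_is_arithmetic_mean_of_folds(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=1)
        res = run_case1((images, labels), plan, _fast_config(), tiny_spec)
        accs = [u.report.accuracy for u in res.per_unit]
        assert res.summary["accuracy"][0] == pytest.approx(np.mean(accs))
        assert res.summary["accuracy"][1] == pytest.approx(np.std(accs, ddof=1))


class TestCase2:
    def test_single_iteration_equals_case1(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=2)
        r1 = run_case1((images, labels), plan, _fast_config("case1"), tiny_spec)
        r2 = run_case2((images, labels), plan,
                       _fast_config("case2", n_iterations=1), tiny_spec)
        for u1, u2 in zip(r1.per_unit, r2.per_unit):
            assert u1.report == u2.report
            assert u1.stopped_epoch == u2.stopped_epoch

    def test_carry_lineage_and_leakage(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=2)
        res = run_case2((images, labels), plan,
                        _fast_config("case2", n_iterations=3), tiny_spec)
        # the carried model accumulates one training event per iteration
        lineage = res.final_state.lineage
        assert [ev["iteration"] for ev in lineage] == [1, 2, 3]
        # iteration 1 is leak-free; later iterations inherit exposure
        for u in res.per_unit:
            if u.iteration == 1:
                assert u.leaked_test_samples == ()
        it2 = [u for u in res.per_unit if u.iteration == 2]
        assert any(u.leaked_test_samples for u in it2)
        assert set(res.per_iteration_summaries) == {1, 2, 3}


class TestCase3:
    def test_carry_and_leakage_set_identity(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=3)
        res = run_case3((images, labels), plan, _fast_config("case3"), tiny_spec)
        lineage = res.final_state.lineage
        assert [ev["fold"] for ev in lineage] == [0, 1, 2]
        assert res.per_unit[0].leaked_test_samples == ()
        for u in res.per_unit:
            earlier = set()
            for f in range(u.fold):
                earlier.update(plan.test_indices(f).tolist())
            expected = tuple(sorted(
                earlier & set(plan.train_indices(u.fold).tolist())))
            assert u.leaked_test_samples == expected
            if u.fold > 0:
                # earlier test folds lie wholly inside this training set
                assert set(u.leaked_test_samples) == earlier


class TestStabilityPass:
    def test_requires_case3_lineage_and_isolates_folds(self, tiny_spec, small_phantoms):
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=4)
        cfg = _fast_config("case3")
        base = run_case3((images, labels), plan, cfg, tiny_spec)
        n_events = len(base.final_state.lineage)
        stab = stability_pass(base.final_state, (images, labels), plan, cfg)
        # source state untouched; each fold fine-tuned an isolated copy
        assert len(base.final_state.lineage) == n_events
        assert len(stab.per_unit) == 3
        assert len(stab.final_state.lineage) == n_events + 1
        assert stab.summary["accuracy"][0] == pytest.approx(
            np.mean([u.report.accuracy for u in stab.per_unit]))

    def test_fresh_state_rejected(self, tiny_spec, small_phantoms):
        from tumorcnn import build_model
        images, labels = small_phantoms
        plan = make_folds(labels, k=3, seed=4)
        with pytest.raises(ValueError, match="case-3"):
            stability_pass(build_model(tiny_spec, 0), (images, labels),
                           plan, _fast_config("case3"))
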