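import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from cyclogait import evaluation as ev
from cyclogait.synthetic import ValidationError


def labels_for(n, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    labs = ["P"] * n_pos + ["NP"] * (n - n_pos)
    rng.shuffle(labs)
    return {f"S{i:03d}": l for i, l in enumerate(labs)}


class TestFoldPlan:
    def test_balanced_sizes_38_subjects_k10(self):
        plan = ev.make_fold_plan(labels_for(38, 14), k=10, seed=0)
        sizes = np.bincount(list(plan.assignment.values()), minlength=10)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 38

    def test_deterministic_under_seed(self):
        a = ev.make_fold_plan(labels_for(20, 8), k=5, seed=3)
        b = ev.make_fold_plan(labels_for(20, 8), k=5, seed=3)
        assert a.assignment == b.assignment

    def test_stratification_within_one(self):
        labs = labels_for(40, 16)
        plan = ev.make_fold_plan(labs, k=5, seed=1)
        for fold in range(5):
            test = plan.test_subjects(fold)
            n_pos = sum(labs[s] == "P" for s in test)
            assert abs(n_pos - 16 / 5) <= 1

    def test_partition_exhaustive_disjoint(self):
        labs = labels_for(23, 9)
        plan = ev.make_fold_plan(labs, k=7, seed=2)
        all_test = [s for f in range(7) for s in plan.test_subjects(f)]
        assert sorted(all_test) == sorted(labs)
        for f in range(7):
            assert not set(plan.test_subjects(f)) & set(plan.train_subjects(f))

    def test_k_exceeding_subjects_rejected(self):
        with pytest.raises(ValidationError):
            ev.make_fold_plan(labels_for(5, 2), k=10)

    def test_audit_catches_leak(self):
        labs = labels_for(6, 3)
        plan = ev.make_fold_plan(labs, k=3, seed=0)
        sid = plan.test_subjects(0)[0]
        bad = pd.DataFrame(
            {"subject_id": [sid, sid], "fold": [0, 1], "score": [0.5, 0.5],
             "pred": ["P", "P"], "label": ["P", "P"]}
        )
        with pytest.raises(ValidationError, match=str(sid)):
            ev.audit_fold_plan(plan, bad)


class TestMajorityVote:
    def test_simple_majority(self):
        assert ev.majority_vote(["P", "P", "NP"]) == "P"
        assert ev.majority_vote(["NP", "NP", "P"]) == "NP"

    def test_tie_broken_by_mean_probability(self):
        assert ev.majority_vote(["P", "NP"], scores=[0.9, 0.3]) == "P"
        assert ev.majority_vote(["P", "NP"], scores=[0.1, 0.3]) == "NP"

    def test_tie_without_scores_favours_positive(self):
        assert ev.majority_vote(["P", "NP"]) == "P"
        assert ev.majority_vote(["P", "NP"], scores=[0.5, 0.5]) == "P"

    def test_single_prediction(self):
        assert ev.majority_vote(["NP"]) == "NP"

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ev.majority_vote([])


class TestComputeMetrics:
    def test_worked_example(self):
        m = ev.compute_metrics(ev.ConfusionMatrix(tp=3, tn=2, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(0.625)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionMatrix(tp=5, tn=7, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_precision_reported_none(self):
        m = ev.compute_metrics(ev.ConfusionMatrix(tp=0, tn=4, fp=0, fn=2))
        assert m["precision"] is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            ev.compute_metrics(ev.ConfusionMatrix(0, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            ev.ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)

    def test_against_sklearn_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            y = [1] * (tp + fn) + [0] * (tn + fp)
            p = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            m = ev.compute_metrics(ev.ConfusionMatrix(tp, tn, fp, fn))
            assert m["accuracy"] == pytest.approx(accuracy_score(y, p), abs=1e-12)
            if m["precision"] is not None:
                assert m["precision"] == pytest.approx(
                    precision_score(y, p, zero_division=0), abs=1e-12)
            if m["recall"] is not None:
                assert m["recall"] == pytest.approx(recall_score(y, p), abs=1e-12)
            if m["f1"] is not None:
                assert m["f1"] == pytest.approx(f1_score(y, p), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = ["P", "P", "NP", "NP"]
        *_, auc = ev.roc_auc(scores, labels)
        assert auc == 1.0

    def test_constant_scores_diagonal(self):
        *_, auc = ev.roc_auc(np.full(10, 0.5), ["P"] * 5 + ["NP"] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ev.roc_auc(np.arange(4.0), ["P"] * 4)

    def test_mann_whitney_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n1, n0 = rng.integers(2, 20, 2)
            labels = ["P"] * n1 + ["NP"] * n0
            # discrete scores force ties
            scores = rng.integers(0, 8, n1 + n0).astype(float)
            *_, auc = ev.roc_auc(scores, labels)
            u = mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided").statistic
            assert abs(auc - u / (n1 * n0)) < 1e-12

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)
        labels = list(np.where(rng.random(12) < 0.5, "P", "NP"))
        if len(set(labels)) < 2:
            return
        *_, a = ev.roc_auc(scores, labels)
        *_, b = ev.roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestEvaluateAll:
    def _preds(self, plan, labs, correct=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sid, lab in labs.items():
            for c in range(3):
                pred = lab if correct else ("P" if rng.random() < 0.5 else "NP")
                score = 0.9 if pred == "P" else 0.1
                rows.append({"subject_id": sid, "cycle_id": c,
                             "fold": plan.assignment[sid], "score": score,
                             "pred": pred, "label": lab})
        return pd.DataFrame(rows)

    def test_perfect_predictions_all_ones(self):
        labs = labels_for(12, 5)
        plan = ev.make_fold_plan(labs, k=3, seed=0)
        report = ev.evaluate_all({"m": self._preds(plan, labs)}, plan)
        for level in ("sample_wise", "subject_wise"):
            res = report.models["m"][level]
            assert res["macro"]["accuracy"] == 1.0
            assert res["auc"] == 1.0

    def test_voting_matches_manual_recomputation(self):
        labs = {"S1": "P", "S2": "NP", "S3": "P", "S4": "NP"}
        plan = ev.make_fold_plan(labs, k=2, seed=0)
        rows = []
        per_subject = {
            "S1": ["P", "P", "NP"],   # votes P (correct)
            "S2": ["P", "P", "NP"],   # votes P (wrong)
            "S3": ["NP", "NP", "P"],  # votes NP (wrong)
            "S4": ["NP", "NP", "NP"],  # votes NP (correct)
        }
        for sid, preds in per_subject.items():
            for c, p in enumerate(preds):
                rows.append({"subject_id": sid, "cycle_id": c,
                             "fold": plan.assignment[sid],
                             "score": 0.8 if p == "P" else 0.2,
                             "pred": p, "label": labs[sid]})
        report = ev.evaluate_all({"m": pd.DataFrame(rows)}, plan)
        cm = report.models["m"]["subject_wise"]["confusion"]
        assert (cm["tp"], cm["tn"], cm["fp"], cm["fn"]) == (1, 1, 1, 1)

    def test_missing_subject_rejected(self):
        labs = labels_for(6, 3)
        plan = ev.make_fold_plan(labs, k=2, seed=0)
        preds = self._preds(plan, labs).query("subject_id != 'S000'")
        with pytest.raises(ValidationError, match="S000"):
            ev.evaluate_all({"m": preds}, plan)

    def test_report_roundtrip(self):
        labs = labels_for(8, 4)
        plan = ev.make_fold_plan(labs, k=2, seed=0)
        report = ev.evaluate_all({"m": self._preds(plan, labs, correct=False, seed=5)}, plan)
        again = ev.EvaluationReport.from_json(report.to_json())
        assert json.loads(again.to_json()) == json.loads(report.to_json())

    def test_markdown_has_table_rows(self):
        labs = labels_for(8, 4)
        plan = ev.make_fold_plan(labs, k=2, seed=0)
        report = ev.evaluate_all({"svm": self._preds(plan, labs)}, plan)
        md = report.markdown_tables()
        assert "| svm |" in md and "Accuracy" in md
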