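"""Subject-wise cross-validation, majority voting and performance metrics.

Folds are assigned at the subject level so no individual contributes
cycles to both the training and test side of any fold. Per-cycle
predictions are aggregated to one prediction per subject by majority
vote. Metrics follow the standard confusion-matrix definitions with the
progression class ("P") as positive; AUC is the trapezoid area under the
empirical ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .synthetic import ValidationError

POSITIVE = "P"
NEGATIVE = "NP"


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: dict[str, int]  # subject_id -> fold index
    seed: int
    stratified: bool = True

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)


def make_fold_plan(
    subject_labels: dict[str, str],
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> FoldPlan:
    """Deterministic subject-wise k-fold partition.

    With ``stratified`` each class is shuffled separately and dealt
    round-robin, keeping every fold's class ratio within one subject of
    the global ratio; fold sizes differ by at most one.
    """
    subjects = sorted(subject_labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(subjects):
        raise ValidationError(f"k={k} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    if stratified:
        offset = 0
        for label in sorted(set(subject_labels.values())):
            members = [s for s in subjects if subject_labels[s] == label]
            rng.shuffle(members)
            for i, s in enumerate(members):
                assignment[s] = (i + offset) % k
            offset += len(members)
    else:
        order = list(subjects)
        rng.shuffle(order)
        for i, s in enumerate(order):
            assignment[s] = i % k
    counts = np.bincount(list(assignment.values()), minlength=k)
    if counts.min() == 0:
        raise ValidationError("fold plan produced an empty fold")
    return FoldPlan(k=k, assignment=assignment, seed=seed, stratified=stratified)


def audit_fold_plan(plan: FoldPlan, predictions: pd.DataFrame) -> None:
    """Raise if any subject's rows appear in a fold they were trained in."""
    for sid, grp in predictions.groupby("subject_id"):
        folds = set(grp["fold"])
        if folds != {plan.assignment[str(sid)]}:
            raise ValidationError(
                f"subject {sid} predicted in folds {sorted(folds)} but assigned "
                f"to fold {plan.assignment[str(sid)]}"
            )


def majority_vote(pred_labels: list[str], scores: list[float] | None = None) -> str:
    """Most frequent predicted label over a subject's cycles.

    Ties are broken by the higher mean probability of the positive class,
    then in favour of the positive class.
    """
    if len(pred_labels) == 0:
        raise ValidationError("no cycle predictions to vote over")
    n_pos = sum(1 for p in pred_labels if p == POSITIVE)
    n_neg = len(pred_labels) - n_pos
    if n_pos > n_neg:
        return POSITIVE
    if n_neg > n_pos:
        return NEGATIVE
    if scores is not None and len(scores):
        m = float(np.mean(scores))
        if m > 0.5:
            return POSITIVE
        if m < 0.5:
            return NEGATIVE
    return POSITIVE


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, pred: list[str], label: list[str]) -> "ConfusionMatrix":
        p = np.asarray(pred)
        y = np.asarray(label)
        return cls(
            tp=int(np.sum((p == POSITIVE) & (y == POSITIVE))),
            tn=int(np.sum((p == NEGATIVE) & (y == NEGATIVE))),
            fp=int(np.sum((p == POSITIVE) & (y == NEGATIVE))),
            fn=int(np.sum((p == NEGATIVE) & (y == POSITIVE))),
        )

    def swapped(self) -> "ConfusionMatrix":
        """Counts with the class roles exchanged (for macro averaging)."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1 from a confusion matrix.

    Undefined ratios (zero denominators) are reported as None.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def macro_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Metrics averaged over both classes treated as positive in turn."""
    a = compute_metrics(cm)
    b = compute_metrics(cm.swapped())
    out: dict[str, float | None] = {"accuracy": a["accuracy"]}
    for key in ("precision", "recall", "f1"):
        vals = [v for v in (a[key], b[key]) if v is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def roc_auc(scores: np.ndarray, labels: list[str] | np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC points and trapezoid AUC, positive class = "P".

    Tied scores cross their threshold simultaneously (standard empirical
    ROC), which makes the trapezoid AUC equal to the Mann-Whitney
    U-statistic divided by n_pos * n_neg.
    """
    y = (np.asarray(labels) == POSITIVE).astype(int)
    if y.min() == y.max():
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvaluationReport:
    """Sample-wise and subject-wise evaluation for one or more models."""

    models: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.models, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(models=json.loads(text))

    def markdown_tables(self) -> str:
        lines = []
        for level in ("subject_wise", "sample_wise"):
            lines.append(f"### {level.replace('_', '-').capitalize()} performance\n")
            lines.append("| Method | Accuracy | Precision | Recall | F1 Score | AUC |")
            lines.append("|---|---|---|---|---|---|")
            for name, res in self.models.items():
                m = res[level]["macro"]
                def fmt(v):
                    return f"{100 * v:.0f}%" if v is not None else "-"
                auc = res[level]["auc"]
                lines.append(
                    f"| {name} | {fmt(m['accuracy'])} | {fmt(m['precision'])} "
                    f"| {fmt(m['recall'])} | {fmt(m['f1'])} "
                    f"| {auc:.2f} |"
                )
            lines.append("")
        return "\n".join(lines)


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def subject_votes(predictions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cycle predictions to one row per subject.

    Expects columns subject_id, fold, score (probability of P), pred,
    label. The subject-level score is the mean per-cycle probability of
    the positive class.
    """
    rows = []
    for sid, grp in predictions.groupby("subject_id", sort=True):
        voted = majority_vote(list(grp["pred"]), list(grp["score"]))
        rows.append(
            {
                "subject_id": sid,
                "fold": int(grp["fold"].iloc[0]),
                "score": float(grp["score"].mean()),
                "pred": voted,
                "label": grp["label"].iloc[0],
            }
        )
    return pd.DataFrame(rows)


def _level_summary(df: pd.DataFrame) -> dict:
    cm = ConfusionMatrix.from_predictions(list(df["pred"]), list(df["label"]))
    _, _, auc = roc_auc(df["score"].to_numpy(), list(df["label"]))
    per_fold = {}
    for fold, grp in df.groupby("fold"):
        fcm = ConfusionMatrix.from_predictions(list(grp["pred"]), list(grp["label"]))
        per_fold[int(fold)] = compute_metrics(fcm)
    return {
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "positive_class": compute_metrics(cm),
        "macro": macro_metrics(cm),
        "auc": auc,
        "per_fold": per_fold,
    }


def evaluate_all(
    predictions_by_model: dict[str, pd.DataFrame], plan: FoldPlan
) -> EvaluationReport:
    """Build the full report (sample- and subject-wise) for each model."""
    report = EvaluationReport()
    expected = set(plan.assignment)
    for name, preds in predictions_by_model.items():
        missing = expected - set(map(str, preds["subject_id"]))
        if missing:
            raise ValidationError(
                f"model {name!r} predictions missing subjects: {sorted(missing)}"
            )
        audit_fold_plan(plan, preds)
        report.models[name] = {
            "sample_wise": _level_summary(preds),
            "subject_wise": _level_summary(subject_votes(preds)),
        }
    return report
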