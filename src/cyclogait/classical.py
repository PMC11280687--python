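"""SVM and random-forest reference classifiers on cyclogram features.

Both models consume per-cycle rows of the 36 geometric features (plus,
optionally, the 4 clinical factors), are evaluated with subject-wise
cross-validation, and their per-cycle predictions are majority-voted per
subject downstream. SVM features are standardized with training-fold
statistics only; the SVM decision value is squashed through a logistic
so every model exposes a monotone score in [0, 1] with a 0.5 midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cyclogram import FEATURE_NAMES
from .evaluation import NEGATIVE, POSITIVE, FoldPlan
from .synthetic import CLINICAL_FIELDS, ValidationError

CLINICAL_COLUMNS = tuple(CLINICAL_FIELDS)


@dataclass(frozen=True)
class ClassicalConfig:
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    svm_gamma: str | float = "scale"
    rf_n_estimators: int = 500
    rf_max_depth: int | None = None
    use_clinical: bool = True
    seed: int = 0


def validate_dataset(data: pd.DataFrame, use_clinical: bool) -> list[str]:
    """Check the tabular dataset and return the feature column list."""
    cols = list(FEATURE_NAMES) + (list(CLINICAL_COLUMNS) if use_clinical else [])
    required = ["subject_id", "cycle_id", "label"] + cols
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValidationError(f"dataset missing columns: {missing}")
    if data[cols].isna().any().any():
        raise ValidationError("dataset contains missing feature values")
    bad = set(data["label"]) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValidationError(f"unknown labels: {sorted(bad)}")
    return cols


def _fold_split(
    data: pd.DataFrame, plan: FoldPlan, fold: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    test_ids = set(plan.test_subjects(fold))
    is_test = data["subject_id"].astype(str).isin(test_ids)
    train, test = data[~is_test], data[is_test]
    if len(test) == 0:
        raise ValidationError(f"fold {fold}: no test rows")
    if len(set(train["label"])) < 2:
        raise ValidationError(f"fold {fold}: training split has a single class")
    return train, test


def _run_cv(data, plan, cols, fit_predict) -> pd.DataFrame:
    out = []
    for fold in range(plan.k):
        train, test = _fold_split(data, plan, fold)
        scores = fit_predict(train[cols].to_numpy(), (train["label"] == POSITIVE).to_numpy(),
                             test[cols].to_numpy())
        out.append(
            pd.DataFrame(
                {
                    "subject_id": test["subject_id"].to_numpy(),
                    "cycle_id": test["cycle_id"].to_numpy(),
                    "fold": fold,
                    "score": scores,
                    "pred": np.where(scores > 0.5, POSITIVE, NEGATIVE),
                    "label": test["label"].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def train_svm(
    data: pd.DataFrame, plan: FoldPlan, config: ClassicalConfig | None = None
) -> pd.DataFrame:
    """Subject-wise cross-validated SVM; returns per-cycle predictions."""
    config = config or ClassicalConfig()
    cols = validate_dataset(data, config.use_clinical)

    def fit_predict(Xtr, ytr, Xte):
        scaler = StandardScaler().fit(Xtr)
        clf = SVC(
            C=config.svm_c, kernel=config.svm_kernel, gamma=config.svm_gamma,
            random_state=config.seed,
        )
        clf.fit(scaler.transform(Xtr), ytr)
        d = clf.decision_function(scaler.transform(Xte))
        return 1.0 / (1.0 + np.exp(-d))

    return _run_cv(data, plan, cols, fit_predict)


def train_rf(
    data: pd.DataFrame, plan: FoldPlan, config: ClassicalConfig | None = None
) -> pd.DataFrame:
    """Subject-wise cross-validated random forest; returns per-cycle predictions."""
    config = config or ClassicalConfig()
    cols = validate_dataset(data, config.use_clinical)

    def fit_predict(Xtr, ytr, Xte):
        clf = RandomForestClassifier(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
        clf.fit(Xtr, ytr)
        return clf.predict_proba(Xte)[:, list(clf.classes_).index(True)]

    return _run_cv(data, plan, cols, fit_predict)
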