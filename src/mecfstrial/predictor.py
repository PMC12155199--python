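"""Random-forest prediction of responder stratum from change scores.

The feature set mirrors the trial's model: the BAS delta, all six MFI
quantities (five domains plus the aggregate), and the SF-36 RP, VT and SF
subscale deltas plus the PCS summary delta.  Missing features are filled
by k-nearest-neighbour imputation (k = 2 by default), the cohort is split
80/20 into training and test sets, hyperparameters are tuned by
exhaustive grid search with 5-fold cross-validation, and the tuned forest
is refit on the full training set with out-of-bag scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import GridSearchCV, train_test_split

FEATURE_COLUMNS = (
    "bas",
    "mfi_general_fatigue", "mfi_physical_fatigue", "mfi_reduced_activity",
    "mfi_reduced_motivation", "mfi_mental_fatigue", "mfi_aggregate",
    "sf36_rp", "sf36_vt", "sf36_sf", "sf36_pcs",
)

CLASS_ORDER = ("responder", "partial", "non")


def default_grid() -> dict[str, list]:
    """Hyperparameter grid searched by the trial's tuning step."""
    return {
        "max_depth": [2, 3],
        "max_features": ["sqrt"],
        "min_samples_leaf": [1],
        "min_samples_split": [2],
        "n_estimators": [200],
    }


@dataclass
class ForestConfig:
    """Bundled preprocessing and model settings."""

    n_neighbors: int = 2          # KNN imputation neighbours
    test_fraction: float = 0.20
    cv_folds: int = 5
    grid: dict[str, list] = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_neighbors < 1 or self.cv_folds < 2:
            raise ValueError("n_neighbors >= 1 and cv_folds >= 2 required")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def build_feature_matrix(deltas: pd.DataFrame, calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the fixed, ordered feature matrix and stratum labels.

    Participants classified as ``excluded`` are dropped.
    """
    merged = deltas.merge(calls[["participant_id", "overall"]], on="participant_id")
    merged = merged[merged["overall"].isin(CLASS_ORDER)]
    X = merged[list(FEATURE_COLUMNS)].astype(float)
    y = merged["overall"].astype(str)
    X.index = merged["participant_id"]
    y.index = merged["participant_id"]
    return X, y


def knn_impute(X: pd.DataFrame, n_neighbors: int = 2) -> pd.DataFrame:
    """Fill missing cells with the mean of the k nearest rows.

    Distances are Euclidean over mutually observed columns, rescaled by the
    number of coordinates used (scikit-learn's ``nan_euclidean``).
    """
    arr = np.asarray(X, dtype=float)
    all_missing = np.isnan(arr).all(axis=0)
    if all_missing.any():
        cols = [X.columns[i] if hasattr(X, "columns") else i
                for i in np.where(all_missing)[0]]
        raise ValueError(f"columns missing everywhere cannot be imputed: {cols}")
    n_obs = (~np.isnan(arr)).any(axis=1).sum()
    if n_neighbors > len(arr) - 1:
        raise ValueError(f"n_neighbors={n_neighbors} exceeds available rows ({len(arr)})")
    imputer = KNNImputer(n_neighbors=n_neighbors)
    out = imputer.fit_transform(arr)
    if hasattr(X, "columns"):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return pd.DataFrame(out)


def split_train_test(
    X: pd.DataFrame,
    y: pd.Series,
    test_fraction: float = 0.20,
    seed: int = 0,
):
    """Seed-reproducible train/test split, stratified by label when possible.

    Falls back to an unstratified split (with a warning) when some class
    has a single member, which stratification cannot accommodate.
    """
    if len(X) < 5:
        raise ValueError("need at least 5 rows to split")
    stratify = y
    if y.value_counts().min() < 2:
        warnings.warn("a class has a single member; falling back to unstratified split",
                      stacklevel=2)
        stratify = None
    return train_test_split(X, y, test_size=test_fraction, random_state=seed,
                            stratify=stratify)


def tune_and_train(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    config: ForestConfig | None = None,
) -> tuple[RandomForestClassifier, dict]:
    """Exhaustive grid search by mean CV accuracy, then refit on all rows.

    Ties are broken by first-in-grid order.  The cross-validation fold
    count is capped at the smallest class count (with a warning) so that
    every fold sees every class.  The chosen forest is refit on the full
    training set with out-of-bag scoring enabled.

    Returns the fitted forest and a report dict (chosen hyperparameters,
    mean CV accuracy, OOB accuracy, training accuracy).
    """
    if config is None:
        config = ForestConfig()
    if y_train.nunique() < 2:
        raise ValueError("training set has a single class")
    folds = min(config.cv_folds, int(y_train.value_counts().min()))
    if folds < config.cv_folds:
        warnings.warn(
            f"smallest class has {y_train.value_counts().min()} members; "
            f"using {folds}-fold CV instead of {config.cv_folds}",
            stacklevel=2,
        )
    folds = max(folds, 2)
    base = RandomForestClassifier(random_state=config.seed)
    search = GridSearchCV(base, config.grid, scoring="accuracy", cv=folds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X_train, y_train)
    best = dict(search.best_params_)
    forest = RandomForestClassifier(random_state=config.seed, oob_score=True, **best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X_train, y_train)
    report = {
        "chosen_hyperparameters": best,
        "cv_accuracy": float(search.best_score_),
        "cv_folds": folds,
        "oob_accuracy": float(forest.oob_score_),
        "train_accuracy": float(forest.score(X_train, y_train)),
    }
    return forest, report


def evaluate(
    model: RandomForestClassifier,
    X_test: pd.DataFrame,
    y_test: pd.Series,
) -> dict:
    """Held-out evaluation: confusion matrix, per-class one-vs-rest AUC,
    feature importances, and test accuracy.

    Confusion-matrix rows are true classes in :data:`CLASS_ORDER`.  A class
    absent from the test set has no defined AUC and is reported as None.
    """
    if len(X_test) == 0:
        raise ValueError("test set is empty")
    labels = [c for c in CLASS_ORDER if c in model.classes_]
    y_pred = model.predict(X_test)
    cm = confusion_matrix(y_test, y_pred, labels=labels)
    proba = model.predict_proba(X_test)
    auc: dict[str, float | None] = {}
    for cls in labels:
        col = list(model.classes_).index(cls)
        truth = (y_test == cls).astype(int)
        if truth.nunique() < 2:
            auc[cls] = None
        else:
            auc[cls] = float(roc_auc_score(truth, proba[:, col]))
    importances = dict(zip(X_test.columns, (float(v) for v in model.feature_importances_)))
    return {
        "confusion_matrix": cm,
        "confusion_labels": labels,
        "auc_per_class": auc,
        "feature_importances": importances,
        "test_accuracy": float((y_pred == y_test).mean()),
    }


def run_predictor(
    deltas: pd.DataFrame,
    calls: pd.DataFrame,
    config: ForestConfig | None = None,
) -> dict:
    """Impute → split → tune → train → evaluate, fully seed-deterministic."""
    if config is None:
        config = ForestConfig()
    X, y = build_feature_matrix(deltas, calls)
    X = knn_impute(X, n_neighbors=config.n_neighbors)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, config.test_fraction, config.seed)
    model, train_report = tune_and_train(X_tr, y_tr, config)
    eval_report = evaluate(model, X_te, y_te)
    return {
        "model": model,
        "n_train": len(X_tr),
        "n_test": len(X_te),
        **train_report,
        **eval_report,
    }
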