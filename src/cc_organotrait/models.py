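"""Per-line classification and regression of adjusted organ weight.

Classification: is a mouse's percent organ weight above the 70th
percentile of the modelled population?  Four families (decision tree,
Gaussian naive Bayes, k-nearest neighbours, random forest) scored by mean
held-out ROC-AUC under stratified 4-fold cross-validation.

Regression: predict percent organ weight with linear or KNN regression,
scored by mean held-out R^2 over repeated 70-30 train-test splits.

Both produce a models-by-lines score grid; cells that fail preconditions
are flagged with a reason, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CVProtocol",
    "RegressionProtocol",
    "ClassificationResult",
    "RegressionResult",
    "ModelGrid",
    "CLASSIFIER_FAMILIES",
    "REGRESSOR_FAMILIES",
    "FEATURE_SETS",
    "label_top_percentile",
    "build_features",
    "run_classification_cv",
    "run_regression_iters",
    "model_grid",
]

# feature-set name -> trait-table columns (sex/diet are 0/1-encoded)
FEATURE_SETS = {
    "paper-text": ("sex", "diet", "bw0_g", "bw12_g", "auc_wk6", "auc_wk12"),
    "table-caption": ("sex", "diet", "bw0_g", "auc_wk6", "auc_wk12"),
}

_SEX_CODE = {"F": 0, "M": 1}
_DIET_CODE = {"CHD": 0, "HFD": 1}


@dataclass(frozen=True)
class CVProtocol:
    """k-fold cross-validation settings for classification."""

    k: int = 4
    stratified: bool = True
    seed: int = 0
    scorer: str = "roc_auc"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class RegressionProtocol:
    """Repeated train-test-split settings for regression."""

    iterations: int = 100
    train_fraction: float = 0.70
    seed: int = 0
    scorer: str = "r2"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def _make_classifier(family: str, seed: int):
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise KeyError(f"unknown classifier family {family!r}")


def _make_regressor(family: str):
    if family == "linear":
        return LinearRegression()
    if family == "knn":
        return KNeighborsRegressor(n_neighbors=5)
    raise KeyError(f"unknown regressor family {family!r}")


CLASSIFIER_FAMILIES = ("decision_tree", "naive_bayes", "knn", "random_forest")
REGRESSOR_FAMILIES = ("linear", "knn")

LABEL_PERCENTILE = 70.0


def label_top_percentile(values: Sequence[float], q: float = LABEL_PERCENTILE) -> np.ndarray:
    """Binary labels: 1 iff value is strictly above the linear-interpolation
    q-th percentile of *values* (ties with the threshold get 0)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("labelling needs at least 4 values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical: labels would be degenerate")
    threshold = float(np.percentile(values, q))
    return (values > threshold).astype(int)


def build_features(
    traits: pd.DataFrame, feature_set: str = "paper-text"
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Assemble the feature matrix; returns (X, kept rows, n dropped)."""
    columns = FEATURE_SETS[feature_set]
    sub = traits.dropna(subset=[c for c in columns if c not in ("sex", "diet")])
    dropped = len(traits) - len(sub)
    X = np.column_stack(
        [
            sub["sex"].map(_SEX_CODE).to_numpy(dtype=float)
            if col == "sex"
            else sub["diet"].map(_DIET_CODE).to_numpy(dtype=float)
            if col == "diet"
            else sub[col].to_numpy(dtype=float)
            for col in columns
        ]
    )
    return X, sub, dropped


@dataclass
class ClassificationResult:
    mean_roc_auc: float
    fold_scores: list[float]
    skipped_folds: int
    n: int
    flags: str = ""


@dataclass
class RegressionResult:
    mean_r2_raw: float
    mean_r2_floored: float  # max(0, raw mean): the grid-comparable score
    iteration_scores: list[float]
    n: int
    flags: str = ""


def run_classification_cv(
    X: np.ndarray, y: np.ndarray, family: str, protocol: CVProtocol | None = None
) -> ClassificationResult:
    """Mean held-out ROC-AUC over (stratified) k folds for one model family.

    Folds whose test split contains a single class cannot be scored and
    are skipped with a count.  Deterministic for a fixed protocol seed.
    """
    protocol = protocol or CVProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        return ClassificationResult(float("nan"), [], 0, y.size, flags="single_class")
    if y.size < 2 * protocol.k:
        return ClassificationResult(
            float("nan"), [], 0, y.size, flags=f"too_few_samples(n={y.size})"
        )
    if protocol.stratified and counts.min() < protocol.k:
        return ClassificationResult(
            float("nan"), [], 0, y.size,
            flags=f"class_smaller_than_k(min={int(counts.min())})",
        )
    splitter = StratifiedKFold(
        n_splits=protocol.k, shuffle=True, random_state=protocol.seed
    )
    scores: list[float] = []
    skipped = 0
    for train_idx, test_idx in splitter.split(X, y):
        if np.unique(y[test_idx]).size < 2:
            skipped += 1
            continue
        model = _make_classifier(family, protocol.seed)
        model.fit(X[train_idx], y[train_idx])
        prob = model.predict_proba(X[test_idx])[:, 1]
        scores.append(float(roc_auc_score(y[test_idx], prob)))
    if not scores:
        return ClassificationResult(
            float("nan"), [], skipped, y.size, flags="no_scorable_folds"
        )
    return ClassificationResult(float(np.mean(scores)), scores, skipped, y.size)


def run_regression_iters(
    X: np.ndarray,
    target: np.ndarray,
    family: str,
    protocol: RegressionProtocol | None = None,
) -> RegressionResult:
    """Mean held-out R^2 over repeated random train-test splits.

    Reports both the raw mean (which can be negative) and the
    floored-at-zero variant used as the grid score.
    """
    protocol = protocol or RegressionProtocol()
    X = np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=float)
    if target.size < 10:
        return RegressionResult(
            float("nan"), float("nan"), [], target.size,
            flags=f"too_few_samples(n={target.size})",
        )
    scores: list[float] = []
    for i in range(protocol.iterations):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, target,
            train_size=protocol.train_fraction,
            random_state=protocol.seed + i,
        )
        model = _make_regressor(family)
        model.fit(X_tr, y_tr)
        scores.append(float(model.score(X_te, y_te)))
    raw = float(np.mean(scores))
    return RegressionResult(raw, max(0.0, raw), scores, target.size)


@dataclass
class ModelGrid:
    """Models-by-lines grid of cross-validated scores for one organ/task."""

    task: str  # "classify" or "regress"
    organ: str
    feature_set: str
    lines: tuple[str, ...]
    scores: pd.DataFrame  # rows = model families, columns = lines
    n: dict[str, int]  # animals used per line
    flags: dict[tuple[str, str], str]  # (family, line) -> reason
    protocol: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        cells = {
            family: {
                line: {
                    "score": None
                    if pd.isna(self.scores.loc[family, line])
                    else float(self.scores.loc[family, line]),
                    "n": self.n.get(line, 0),
                    "flags": self.flags.get((family, line), ""),
                }
                for line in self.lines
            }
            for family in self.scores.index
        }
        return {
            "task": self.task,
            "organ": self.organ,
            "feature_set": self.feature_set,
            "protocol": self.protocol,
            "grid": cells,
        }


def model_grid(
    traits: pd.DataFrame,
    organ: str,
    task: str,
    cv_protocol: CVProtocol | None = None,
    reg_protocol: RegressionProtocol | None = None,
    feature_set: str = "paper-text",
    per_line: bool = True,
    label_percentile: float = LABEL_PERCENTILE,
) -> ModelGrid:
    """Score every (model family, line) cell for one organ.

    In per-line mode (the default, matching the per-line grid layout)
    each line's animals form their own dataset and labelling population;
    ``per_line=False`` pools the whole cohort into a single "all" column.
    """
    if task not in ("classify", "regress"):
        raise ValueError("task must be 'classify' or 'regress'")
    target_col = f"pct_{organ}"
    if target_col not in traits.columns:
        raise KeyError(f"no column {target_col!r} in trait table")
    cv_protocol = cv_protocol or CVProtocol()
    reg_protocol = reg_protocol or RegressionProtocol()
    families = CLASSIFIER_FAMILIES if task == "classify" else REGRESSOR_FAMILIES

    groups = (
        [(line, traits[traits["line"] == line]) for line in
         sorted(traits["line"].unique())]
        if per_line
        else [("all", traits)]
    )
    lines = tuple(name for name, _ in groups)
    scores = pd.DataFrame(np.nan, index=list(families), columns=list(lines))
    n_used: dict[str, int] = {}
    flags: dict[tuple[str, str], str] = {}

    for line, sub in groups:
        X, kept, _dropped = build_features(sub, feature_set)
        target = kept[target_col].to_numpy(dtype=float)
        n_used[line] = len(kept)
        if task == "classify":
            try:
                y = label_top_percentile(target, label_percentile)
            except ValueError as exc:
                for family in families:
                    flags[(family, line)] = f"labels: {exc}"
                continue
            for family in families:
                res = run_classification_cv(X, y, family, cv_protocol)
                scores.loc[family, line] = res.mean_roc_auc
                if res.flags:
                    flags[(family, line)] = res.flags
        else:
            for family in families:
                res = run_regression_iters(X, target, family, reg_protocol)
                scores.loc[family, line] = res.mean_r2_floored
                if res.flags:
                    flags[(family, line)] = res.flags

    protocol_echo = (
        asdict(cv_protocol) if task == "classify" else asdict(reg_protocol)
    )
    if task == "classify":
        protocol_echo["label_percentile"] = label_percentile
    return ModelGrid(
        task=task, organ=organ, feature_set=feature_set, lines=lines,
        scores=scores, n=n_used, flags=flags, protocol=protocol_echo,
    )
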