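"""Feature fusion, correlation pruning and the classification harness.

Three classification tasks are supported on any window- or day-level
feature table: identifying the user, and identifying the three-level
loneliness-risk label derived from either the UCLA-3 or the LSNS-6
(Lubben) questionnaire total. Classifiers are a support vector machine
with an RBF kernel, a random forest, and XGBoost (plus logistic regression
as an optional fourth); tree ensembles run at library defaults apart from
the tree count. Evaluation reports accuracy and a percentage-normalised
confusion matrix whose rows (true classes) each sum to 100.

The cross-domain experiment trains on one domain (indoor or outdoor) and
evaluates on the other over the shared mobility features (distance,
estimated speed), in regression mode (RMSE, MAE, R² — reported unclipped,
negative R² means worse than predicting the mean) or classification mode
(accuracy plus per-user recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

META_COLUMNS = ("user_id", "day", "window_start", "window_end")
LABEL_COLUMNS = ("ucla_label", "lubben_label", "ucla_score", "lubben_score", "at_risk")
CATEGORICAL_COLUMNS = ("cluster_id", "emotion", "in_cluster_id", "out_cluster_id")

#: When a pair of features correlates above threshold, the member appearing
#: earlier here survives; distance and GPS speed over ground won the
#: feature-relevance comparison and are the configured keepers.
DEFAULT_KEEP_PRIORITY = (
    "avg_distance", "in_distance", "out_distance",
    "speed_over_ground", "out_speed_over_ground",
    "avg_speed", "avg_estimated_speed", "in_estimated_speed", "out_estimated_speed",
)

DEFAULT_N_ESTIMATORS = 100


@dataclass
class EvalReport:
    """Result of one train/evaluate run."""

    algorithm: str
    target: str
    classes: list
    accuracy: float                 # percent, 0-100
    confusion: np.ndarray           # L×L percentages, rows = true classes
    per_class_correct: dict         # class → % correct (diagonal)
    split: str
    seed: int
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "target": self.target,
            "classes": [str(c) for c in self.classes],
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class_correct": {str(k): v for k, v in self.per_class_correct.items()},
            "split": self.split,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


@dataclass
class TransferReport:
    """Result of a cross-domain transfer run."""

    mode: str
    train_domain: str
    test_domain: str
    rmse: float | None = None
    mae: float | None = None
    r2: float | None = None
    accuracy: float | None = None
    per_class_recall: dict | None = None

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "train_domain": self.train_domain,
             "test_domain": self.test_domain}
        for k in ("rmse", "mae", "r2", "accuracy"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.per_class_recall is not None:
            d["per_class_recall"] = {str(k): v for k, v in self.per_class_recall.items()}
        return d


# ---------------------------------------------------------------------------
# correlation pruning

def correlation_prune(
    table: pd.DataFrame,
    threshold: float = 0.9,
    keep_priority: Sequence[str] = DEFAULT_KEEP_PRIORITY,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop one member of every feature pair with |Pearson r| > threshold.

    Returns (pruned table, correlation matrix over the numeric features,
    dropped column names). The keeper of a flagged pair is the column
    earlier in ``keep_priority``; columns absent from the priority list
    rank after listed ones in table order. Constant columns have no defined
    correlation and are excluded (and reported as dropped).
    """
    numeric = [
        c for c in table.columns
        if c not in META_COLUMNS + LABEL_COLUMNS + CATEGORICAL_COLUMNS
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(numeric) < 2:
        raise ValueError("correlation pruning needs at least 2 numeric features")
    dropped: list[str] = []
    constant = [c for c in numeric if table[c].nunique(dropna=True) <= 1]
    numeric = [c for c in numeric if c not in constant]
    dropped.extend(constant)

    corr = table[numeric].corr(method="pearson")

    def rank(col: str) -> tuple[int, int]:
        try:
            return (0, list(keep_priority).index(col))
        except ValueError:
            return (1, numeric.index(col))

    flagged: set[str] = set()
    for i, a in enumerate(numeric):
        for b in numeric[i + 1:]:
            if a in flagged or b in flagged:
                continue
            if abs(corr.loc[a, b]) > threshold:
                loser = max((a, b), key=rank)
                flagged.add(loser)
    dropped.extend(sorted(flagged, key=numeric.index))
    pruned = table.drop(columns=[c for c in dropped if c in table.columns])
    return pruned, corr, dropped


# ---------------------------------------------------------------------------
# fusion

def _epoch_day(epoch: float) -> str:
    return datetime.fromtimestamp(epoch, tz=timezone.utc).strftime("%Y-%m-%d")


def _daily_aggregate(table: pd.DataFrame, prefix: str,
                     rename: dict[str, str]) -> pd.DataFrame:
    """Collapse window rows to one row per user-day: mean numerics, modal categoricals."""
    from .features import modal_category

    df = table.copy()
    df["day"] = [_epoch_day(t) for t in df["window_start"]]
    out_rows = []
    for (uid, day), grp in df.groupby(["user_id", "day"], sort=True):
        row = {"user_id": uid, "day": day}
        for col, new in rename.items():
            if col not in grp.columns:
                continue
            if col in CATEGORICAL_COLUMNS:
                row[f"{prefix}{new}"] = modal_category(list(grp[col]))
            else:
                row[f"{prefix}{new}"] = float(grp[col].mean())
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def fuse(
    indoor_rows: pd.DataFrame,
    outdoor_rows: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join indoor and outdoor day-level features on matching user-days.

    Window rows are first aggregated per user-day (mean of numeric
    features, mode of categoricals), then inner-joined: only user-days
    observed in *both* domains survive. Label columns are merged on
    user_id when supplied.
    """
    if indoor_rows.empty or outdoor_rows.empty:
        raise ValueError("fusion needs non-empty tables for both domains")
    ind = _daily_aggregate(
        indoor_rows, "in_",
        {"avg_distance": "distance", "avg_speed": "estimated_speed",
         "cluster_id": "cluster_id"},
    )
    out = _daily_aggregate(
        outdoor_rows, "out_",
        {"avg_distance": "distance", "avg_estimated_speed": "estimated_speed",
         "speed_over_ground": "speed_over_ground", "cluster_id": "cluster_id"},
    )
    fused = ind.merge(out, on=["user_id", "day"], how="inner")
    if fused.empty:
        ind_days = set(map(tuple, ind[["user_id", "day"]].itertuples(index=False)))
        out_days = set(map(tuple, out[["user_id", "day"]].itertuples(index=False)))
        raise ValueError(
            "no user-days present in both domains; "
            f"indoor-only={sorted(ind_days - out_days)[:5]}, "
            f"outdoor-only={sorted(out_days - ind_days)[:5]}"
        )
    if labels is not None:
        fused = fused.merge(
            labels[["user_id", "ucla_label", "lubben_label"]], on="user_id", how="left"
        )
    return fused


def attach_labels(table: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Merge per-user risk labels onto a feature table by user_id."""
    return table.merge(
        labels[["user_id", "ucla_label", "lubben_label"]], on="user_id", how="inner"
    )


# ---------------------------------------------------------------------------
# classification harness

_TARGET_COLUMN = {"user": "user_id", "ucla": "ucla_label", "lubben": "lubben_label"}


def _encode_features(table: pd.DataFrame, target_col: str) -> tuple[pd.DataFrame, pd.Series]:
    """Split features/target; one-hot the categorical columns."""
    drop = [c for c in META_COLUMNS + LABEL_COLUMNS if c in table.columns]
    if target_col in table.columns and target_col not in drop:
        drop.append(target_col)
    X = table.drop(columns=drop)
    cats = [c for c in CATEGORICAL_COLUMNS if c in X.columns]
    if cats:
        X = pd.get_dummies(X, columns=cats, dtype=float)
    y = table[target_col]
    return X, y


def _make_classifier(algorithm: str, seed: int, n_estimators: int):
    if algorithm == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if algorithm == "xgb":
        return XGBClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            verbosity=0,
        )
    if algorithm == "logreg":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _normalized_confusion(
    y_true, y_pred, classes, axis: Literal["rows", "cols"] = "rows"
) -> tuple[np.ndarray, list[str]]:
    cm = _sk_confusion(y_true, y_pred, labels=classes).astype(float)
    warnings = []
    sums = cm.sum(axis=1 if axis == "rows" else 0, keepdims=True)
    empty = np.where(sums.ravel() == 0)[0]
    for i in empty:
        warnings.append(f"class {classes[i]} absent from test fold")
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.where(sums > 0, 100.0 * cm / sums, 0.0)
    return cm, warnings


def train_eval(
    table: pd.DataFrame,
    target: Literal["user", "ucla", "lubben"],
    algorithm: Literal["svm", "rf", "xgb", "logreg"] = "xgb",
    test_size: float = 0.2,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    normalize: Literal["rows", "cols"] = "rows",
    grouped_by_user: bool = False,
) -> EvalReport:
    """Stratified hold-out evaluation of one classifier on one target.

    The default split is a stratified 80/20 hold-out with a fixed seed;
    windows of one user can land in both folds, which matches the usual
    protocol for such sensor studies but flatters generalisation — set
    ``grouped_by_user`` for a leave-users-out split (unavailable for the
    user target, where every class *is* a user).
    """
    target_col = _TARGET_COLUMN[target]
    if target_col not in table.columns:
        raise ValueError(f"table lacks target column {target_col!r}")
    X, y = _encode_features(table, target_col)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError(f"target {target!r} has a single class; nothing to classify")

    if grouped_by_user:
        if target == "user":
            raise ValueError("grouped split is undefined for the user target")
        users = sorted(table["user_id"].unique())
        rng = np.random.default_rng(seed)
        held = set(rng.choice(users, size=max(1, int(len(users) * test_size)),
                              replace=False))
        mask = table["user_id"].isin(held).to_numpy()
        X_tr, X_te, y_tr, y_te = X[~mask], X[mask], y[~mask], y[mask]
        split = f"grouped hold-out ({sorted(held)})"
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, random_state=seed, stratify=y
        )
        split = f"stratified {1 - test_size:.0%}/{test_size:.0%} hold-out"

    clf = _make_classifier(algorithm, seed, n_estimators)
    # tree/kernel classifiers want integer-coded targets
    class_index = {c: i for i, c in enumerate(classes)}
    clf.fit(X_tr, y_tr.map(class_index))
    y_pred = pd.Series(clf.predict(X_te)).map({i: c for c, i in class_index.items()})

    acc = 100.0 * float((y_pred.to_numpy() == y_te.to_numpy()).mean())
    cm, warnings = _normalized_confusion(y_te, y_pred, classes, axis=normalize)
    per_class = {c: float(cm[i, i]) for i, c in enumerate(classes)}
    return EvalReport(
        algorithm=algorithm,
        target=target,
        classes=list(classes),
        accuracy=acc,
        confusion=cm,
        per_class_correct=per_class,
        split=split,
        seed=seed,
        warnings=warnings,
    )


def cross_validate(
    table: pd.DataFrame,
    target: Literal["user", "ucla", "lubben"],
    algorithm: str = "xgb",
    n_splits: int = 5,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> list[float]:
    """Optional stratified k-fold accuracies (percent per fold)."""
    target_col = _TARGET_COLUMN[target]
    X, y = _encode_features(table, target_col)
    classes = sorted(y.unique())
    class_index = {c: i for i, c in enumerate(classes)}
    y_enc = y.map(class_index).to_numpy()
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y_enc):
        clf = _make_classifier(algorithm, seed, n_estimators)
        clf.fit(X.iloc[tr], y_enc[tr])
        accs.append(100.0 * float((clf.predict(X.iloc[te]) == y_enc[te]).mean()))
    return accs


# ---------------------------------------------------------------------------
# cross-domain transfer

SHARED_FEATURES = ("distance", "estimated_speed")


def domain_view(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a domain feature table to the shared mobility features.

    Renames the domain-specific column names (``avg_distance``,
    ``avg_speed`` / ``avg_estimated_speed``) to the common pair
    (distance, estimated_speed) so indoor and outdoor tables can face
    each other in a transfer experiment.
    """
    rename = {"avg_distance": "distance", "avg_speed": "estimated_speed",
              "avg_estimated_speed": "estimated_speed"}
    cols = {c: rename[c] for c in table.columns if c in rename}
    view = table.rename(columns=cols)
    keep = ["user_id", *SHARED_FEATURES]
    missing = [c for c in keep if c not in view.columns]
    if missing:
        raise ValueError(f"domain table lacks shared features {missing}")
    return view[keep]


def cross_domain(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    mode: Literal["regression", "classification"] = "regression",
    train_domain: str = "indoor",
    test_domain: str = "outdoor",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> TransferReport:
    """Train on one domain's shared mobility features, evaluate on the other.

    Regression mode fits an XGBoost regressor predicting distance from
    estimated speed on the training domain and scores it on the test
    domain; R² is reported as computed, including negative values (worse
    than predicting the test-set mean). Classification mode fits an
    XGBoost classifier identifying the user from (distance, estimated
    speed) and reports accuracy plus per-user recall.
    """
    tr = domain_view(train_table)
    te = domain_view(test_table)
    if mode == "regression":
        reg = XGBRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1,
                           verbosity=0)
        reg.fit(tr[["estimated_speed"]], tr["distance"])
        pred = reg.predict(te[["estimated_speed"]])
        err = te["distance"].to_numpy() - pred
        return TransferReport(
            mode=mode, train_domain=train_domain, test_domain=test_domain,
            rmse=float(np.sqrt(np.mean(err ** 2))),
            mae=float(mean_absolute_error(te["distance"], pred)),
            r2=float(r2_score(te["distance"], pred)),
        )
    if mode == "classification":
        classes = sorted(tr["user_id"].unique())
        class_index = {c: i for i, c in enumerate(classes)}
        clf = XGBClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1,
                            verbosity=0)
        clf.fit(tr[list(SHARED_FEATURES)], tr["user_id"].map(class_index))
        pred_idx = clf.predict(te[list(SHARED_FEATURES)])
        pred = pd.Series(pred_idx).map({i: c for c, i in class_index.items()})
        truth = te["user_id"].to_numpy()
        acc = 100.0 * float((pred.to_numpy() == truth).mean())
        recall = {}
        for c in sorted(set(truth)):
            mask = truth == c
            recall[c] = 100.0 * float((pred.to_numpy()[mask] == c).mean())
        return TransferReport(
            mode=mode, train_domain=train_domain, test_domain=test_domain,
            accuracy=acc, per_class_recall=recall,
        )
    raise ValueError(f"unknown mode {mode!r}")
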