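"""Ligand-function classification: split, preprocess, forest, post-processing.

The pipeline mirrors a conventional scikit-learn workflow: ordinal encoding
of interaction-type categories (NA is its own category; categories unseen at
predict time get a reserved code), mean imputation and standardization
fitted on the training split only, then a 500-tree random forest
(``bootstrap=False``, ``max_depth=30``, balanced-subsample class weights,
sqrt features per split) whose averaged class probabilities drive the
4-class prediction. Post-processing merges the three active classes into a
binary active/inactive call and applies majority-rule voting across docked
poses of the same ligand.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

__all__ = [
    "FOUR_CLASSES",
    "BINARY_CLASSES",
    "ACTIVE_LABELS",
    "Preprocessing",
    "ClassifierBundle",
    "ConfusionMatrix",
    "MetricsReport",
    "split",
    "fit_preprocessing",
    "apply_preprocessing",
    "train",
    "predict",
    "merge_active",
    "majority_vote",
    "confusion",
    "metrics",
    "save_bundle",
    "load_bundle",
]

FOUR_CLASSES = ("agonist", "antagonist", "inverse_agonist", "inactive")
ACTIVE_LABELS = ("agonist", "antagonist", "inverse_agonist")
BINARY_CLASSES = ("active", "inactive")

FOREST_CONFIG = dict(
    n_estimators=500,
    class_weight="balanced_subsample",
    bootstrap=False,
    max_depth=30,
    max_features="sqrt",  # the classification meaning of 'auto'
    min_samples_leaf=1,
    min_samples_split=2,
)

_META_COLUMNS = ("complex_id", "label", "model_id", "ligand_id", "receptor_id")


def split(
    frame: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomized disjoint train/test split with |train| = round((1-f) * n)."""
    n = len(frame)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(n * (1.0 - test_fraction)))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return (
        frame.iloc[np.sort(order[:n_train])].reset_index(drop=True),
        frame.iloc[np.sort(order[n_train:])].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class Preprocessing:
    feature_columns: list[str]
    categorical_columns: list[str]
    encoders: dict[str, dict[str, int]]
    impute_means: dict[str, float]
    scale_means: dict[str, float]
    scale_stds: dict[str, float]

    def encode(self, column: str, value: str) -> int:
        registry = self.encoders[column]
        # unseen category at predict time -> reserved code past the registry
        return registry.get(str(value), len(registry))


def _feature_cols(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in _META_COLUMNS]


def fit_preprocessing(train_frame: pd.DataFrame) -> Preprocessing:
    """Fit encoder registry, imputation means and scalers on training rows only."""
    cols = _feature_cols(train_frame)
    cat_cols = [c for c in cols if c.endswith("_type1") or c.endswith("_type2")]
    encoders: dict[str, dict[str, int]] = {}
    for c in cat_cols:
        cats = sorted(str(v) for v in train_frame[c].dropna().unique())
        encoders[c] = {cat: code for code, cat in enumerate(cats)}

    impute_means: dict[str, float] = {}
    scale_means: dict[str, float] = {}
    scale_stds: dict[str, float] = {}
    for c in cols:
        if c in encoders:
            codes = train_frame[c].astype(str).map(encoders[c]).astype(float)
            col = codes
        else:
            col = pd.to_numeric(train_frame[c], errors="coerce")
        mean = float(col.mean())
        if np.isnan(mean):
            warnings.warn(f"column {c!r} is entirely NA; imputing to 0", stacklevel=2)
            mean = 0.0
        impute_means[c] = mean
        filled = col.fillna(mean)
        mu = float(filled.mean())
        sd = float(filled.std(ddof=0))
        scale_means[c] = mu
        scale_stds[c] = sd if sd > 0 else 1.0
    return Preprocessing(
        feature_columns=cols,
        categorical_columns=cat_cols,
        encoders=encoders,
        impute_means=impute_means,
        scale_means=scale_means,
        scale_stds=scale_stds,
    )


def apply_preprocessing(prep: Preprocessing, frame: pd.DataFrame) -> np.ndarray:
    """Encode, impute, and standardize into a dense numeric matrix."""
    out = np.empty((len(frame), len(prep.feature_columns)), dtype=float)
    for k, c in enumerate(prep.feature_columns):
        if c not in frame.columns:
            raise ValueError(f"input frame lacks feature column {c!r}")
        if c in prep.encoders:
            col = np.array(
                [
                    np.nan if pd.isna(v) else prep.encode(c, v)
                    for v in frame[c]
                ],
                dtype=float,
            )
        else:
            col = pd.to_numeric(frame[c], errors="coerce").to_numpy(dtype=float)
        col = np.where(np.isnan(col), prep.impute_means[c], col)
        out[:, k] = (col - prep.scale_means[c]) / prep.scale_stds[c]
    return out


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass
class ClassifierBundle:
    preprocessing: Preprocessing
    forest: RandomForestClassifier
    classes: list[str]
    cv_score: float
    seed: int
    retained_positions: list[str] = field(default_factory=list)


def train(
    matrix: np.ndarray,
    labels: list[str] | np.ndarray,
    seed: int = 0,
    preprocessing: Preprocessing | None = None,
    n_folds: int = 10,
    retained_positions: list[str] | None = None,
) -> ClassifierBundle:
    """Fit the random forest and record the 10-fold CV mean accuracy."""
    labels = np.asarray(labels, dtype=object)
    class_counts = Counter(labels)
    if len(class_counts) < 2:
        raise ValueError("training labels contain a single class")
    n = len(labels)
    folds = min(n_folds, n)
    if folds < n_folds:
        warnings.warn(
            f"only {n} rows; reducing CV folds from {n_folds} to {folds}",
            stacklevel=2,
        )
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **FOREST_CONFIG)
    if min(class_counts.values()) >= folds:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(forest, matrix, labels, cv=cv, scoring="accuracy")
    forest.fit(matrix, labels)
    return ClassifierBundle(
        preprocessing=preprocessing,
        forest=forest,
        classes=[str(c) for c in forest.classes_],
        cv_score=float(np.mean(scores)),
        seed=seed,
        retained_positions=list(retained_positions or []),
    )


def predict(
    bundle: ClassifierBundle,
    matrix: np.ndarray,
    *,
    complex_ids: list[str] | None = None,
    true_labels: list[str] | None = None,
    groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Averaged-probability 4-class predictions as a tidy frame.

    Columns: complex_id, predicted, true (optional), ``p_<class>`` per
    class, plus any grouping columns passed via ``groups``.
    """
    n = matrix.shape[0] if matrix.ndim == 2 else 0
    cols = ["complex_id", "predicted", "true"] + [f"p_{c}" for c in bundle.classes]
    if n == 0:
        frame = pd.DataFrame(columns=cols)
        return frame
    if matrix.shape[1] != bundle.forest.n_features_in_:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns; model expects "
            f"{bundle.forest.n_features_in_}"
        )
    probs = bundle.forest.predict_proba(matrix)
    pred_idx = np.argmax(probs, axis=1)  # ties -> first label in registry order
    frame = pd.DataFrame(
        {
            "complex_id": complex_ids if complex_ids is not None else range(n),
            "predicted": [bundle.classes[i] for i in pred_idx],
            "true": true_labels if true_labels is not None else [None] * n,
        }
    )
    for k, c in enumerate(bundle.classes):
        frame[f"p_{c}"] = probs[:, k]
    if groups is not None:
        for c in groups.columns:
            frame[c] = groups[c].to_numpy()
    return frame


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def merge_active(labels: "pd.Series | list[str]") -> list[str]:
    """Collapse agonist/antagonist/inverse_agonist to 'active'."""
    out = []
    for lab in labels:
        if lab in ACTIVE_LABELS or lab == "active":
            out.append("active")
        elif lab == "inactive":
            out.append("inactive")
        else:
            raise ValueError(f"unknown 4-class label {lab!r}")
    return out


def majority_vote(
    predictions: pd.DataFrame,
    group_keys: list[str],
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """One modal prediction per (model, ligand) group of docked poses.

    Ties break toward the label with the largest summed probability across
    the group's poses, then registry order. Warns on even-sized groups (an
    odd pose count is recommended so votes cannot tie).
    """
    if classes is None:
        classes = [c[2:] for c in predictions.columns if c.startswith("p_")]
    out_rows = []
    for key, grp in predictions.groupby(group_keys, sort=True):
        if len(grp) % 2 == 0:
            warnings.warn(
                f"pose group {key} has an even size ({len(grp)}); "
                "an odd number of docked poses is recommended",
                stacklevel=2,
            )
        votes = Counter(grp["predicted"])
        top = max(votes.values())
        tied = [c for c in classes if votes.get(c, 0) == top]
        if len(tied) > 1:
            sums = {
                c: float(grp[f"p_{c}"].sum()) if f"p_{c}" in grp else 0.0
                for c in tied
            }
            best = max(sums.values())
            tied = [c for c in tied if sums[c] == best]
        winner = tied[0]
        row = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        row["predicted"] = winner
        row["n_poses"] = len(grp)
        truths = set(grp["true"].dropna().unique()) if "true" in grp else set()
        row["true"] = truths.pop() if len(truths) == 1 else None
        for c in classes:
            if f"p_{c}" in grp:
                row[f"p_{c}"] = float(grp[f"p_{c}"].mean())
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts with rows = actual label, columns = predicted label."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the label order")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion(
    true_labels: list[str],
    predicted_labels: list[str],
    label_order: list[str],
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lab: k for k, lab in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=list(label_order), counts=counts)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float  # micro-averaged == accuracy for single-label output
    recall: float
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    hit_rate: float | None  # % for binary active/inactive matrices, else None
    cv_score: float | None = None

    def rounded(self) -> dict:
        """Display rounding used in reports: metrics 2 dp, hit rate 1 dp."""
        return {
            "accuracy": round(self.accuracy, 2),
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "hit_rate": None if self.hit_rate is None else round(self.hit_rate, 1),
            "cv_score": None if self.cv_score is None else round(self.cv_score, 2),
        }


def metrics(cm: ConfusionMatrix, cv_score: float | None = None) -> MetricsReport:
    """Micro accuracy/precision/recall plus the binary hit rate.

    Hit rate = 100 x (actual actives among predicted actives)/(predicted
    actives); defined only for active/inactive matrices and None when no
    row is predicted active.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm.counts)) / total

    per_p, per_r = {}, {}
    for k, lab in enumerate(cm.labels):
        col = cm.counts[:, k].sum()
        row = cm.counts[k, :].sum()
        per_p[lab] = float(cm.counts[k, k]) / col if col else float("nan")
        per_r[lab] = float(cm.counts[k, k]) / row if row else float("nan")

    hit_rate = None
    if list(cm.labels) == list(BINARY_CLASSES):
        predicted_active = cm.counts[:, 0].sum()
        if predicted_active > 0:
            hit_rate = 100.0 * float(cm.counts[0, 0]) / float(predicted_active)
    return MetricsReport(
        accuracy=accuracy,
        precision=accuracy,
        recall=accuracy,
        per_class_precision=per_p,
        per_class_recall=per_r,
        hit_rate=hit_rate,
        cv_score=cv_score,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: ClassifierBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "classes": bundle.classes,
        "cv_score": bundle.cv_score,
        "seed": bundle.seed,
        "retained_positions": bundle.retained_positions,
        "forest_config": FOREST_CONFIG,
        "preprocessing": None,
    }
    if bundle.preprocessing is not None:
        p = bundle.preprocessing
        meta["preprocessing"] = {
            "feature_columns": p.feature_columns,
            "categorical_columns": p.categorical_columns,
            "encoders": p.encoders,
            "impute_means": p.impute_means,
            "scale_means": p.scale_means,
            "scale_stds": p.scale_stds,
        }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    joblib.dump(bundle.forest, directory / "forest.joblib")


def load_bundle(directory: str | Path) -> ClassifierBundle:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    prep = None
    if meta["preprocessing"] is not None:
        p = meta["preprocessing"]
        prep = Preprocessing(
            feature_columns=p["feature_columns"],
            categorical_columns=p["categorical_columns"],
            encoders=p["encoders"],
            impute_means=p["impute_means"],
            scale_means=p["scale_means"],
            scale_stds=p["scale_stds"],
        )
    forest = joblib.load(directory / "forest.joblib")
    return ClassifierBundle(
        preprocessing=prep,
        forest=forest,
        classes=meta["classes"],
        cv_score=meta["cv_score"],
        seed=meta["seed"],
        retained_positions=meta["retained_positions"],
    )


def train_table(
    table_frame: pd.DataFrame, seed: int = 0, n_folds: int = 10
) -> ClassifierBundle:
    """Convenience: fit preprocessing + forest from a labeled feature frame."""
    prep = fit_preprocessing(table_frame)
    X = apply_preprocessing(prep, table_frame)
    return train(
        X, list(table_frame["label"]), seed=seed,
        preprocessing=prep, n_folds=n_folds,
    )
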