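"""Table-shaped reports and the end-to-end screening workflow."""

from __future__ import annotations

import json
import warnings

import pandas as pd

from .classify import (
    BINARY_CLASSES,
    ClassifierBundle,
    ConfusionMatrix,
    MetricsReport,
    apply_preprocessing,
    majority_vote,
    merge_active,
    predict,
)

__all__ = ["render_report", "run_screening_workflow"]


def render_report(
    report: MetricsReport,
    cm: ConfusionMatrix,
    fmt: str = "text",
) -> str:
    """Render a confusion matrix + metrics block as text or JSON.

    Numbers follow the report rounding convention (metrics to 2 decimals,
    hit rate to 1); both renderings agree on every value.
    """
    rounded = report.rounded()
    if fmt == "json":
        payload = {
            "labels": cm.labels,
            "confusion_matrix": cm.counts.tolist(),
            "metrics": rounded,
            "per_class_precision": {
                k: round(v, 2) for k, v in report.per_class_precision.items()
            },
            "per_class_recall": {
                k: round(v, 2) for k, v in report.per_class_recall.items()
            },
        }
        return json.dumps(payload, indent=1)
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["Confusion matrix (rows = actual, columns = predicted)"]
    lines.append(cm.to_frame().to_string())
    lines.append("Classifier performance metrics")
    hit = rounded["hit_rate"]
    lines.append(f"hit rate (%) {'NA' if hit is None else hit}")
    lines.append(f"accuracy {rounded['accuracy']:.2f}")
    lines.append(f"precision {rounded['precision']:.2f}")
    lines.append(f"recall {rounded['recall']:.2f}")
    if rounded["cv_score"] is not None:
        lines.append(f"cross-validation score {rounded['cv_score']:.2f}")
    return "\n".join(lines)


def run_screening_workflow(
    feature_frame: pd.DataFrame,
    bundle: ClassifierBundle,
    group_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Predict, majority-vote per pose group, merge actives, rank.

    ``feature_frame`` rows are docked poses; ``group_keys`` (for example
    ``["model_id", "ligand_id"]``) identify each ligand's pose group. With
    no groups every row is predicted directly. Predicted actives sort
    first. An empty frame yields an empty report with a warning.
    """
    if feature_frame.empty:
        warnings.warn("no complexes to screen; empty report", stacklevel=2)
        return pd.DataFrame(
            columns=["predicted", "merged", "group_probability"]
        )
    matrix = apply_preprocessing(bundle.preprocessing, feature_frame)
    preds = predict(
        bundle,
        matrix,
        complex_ids=list(feature_frame.get("complex_id", range(len(feature_frame)))),
        true_labels=(
            list(feature_frame["label"]) if "label" in feature_frame else None
        ),
    )
    if group_keys:
        for key in group_keys:
            preds[key] = feature_frame[key].to_numpy()
        voted = majority_vote(preds, group_keys, classes=bundle.classes)
    else:
        voted = preds.copy()
    voted["merged"] = merge_active(voted["predicted"])
    prob_cols = [f"p_{c}" for c in bundle.classes if f"p_{c}" in voted]
    voted["group_probability"] = voted.apply(
        lambda row: float(row[f"p_{row['predicted']}"])
        if f"p_{row['predicted']}" in prob_cols
        else float("nan"),
        axis=1,
    )
    order = voted["merged"].map({c: i for i, c in enumerate(BINARY_CLASSES)})
    voted = voted.assign(_order=order).sort_values(
        ["_order", "group_probability"], ascending=[True, False]
    )
    return voted.drop(columns="_order").reset_index(drop=True)
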