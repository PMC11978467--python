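"""Discrimination metrics and the training-set operating point."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(probs, labels) -> float:
    """Rank-based AUC (ties averaged)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


def au_prc(probs, labels) -> float:
    """Area under the precision-recall curve by step integration."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(probs, dtype=float)))


def baseline_auprc(labels) -> float:
    """Chance-level AU-PRC: prevalence of the positive class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    return float(labels.mean())


def training_operating_point(train_probs, train_labels) -> float:
    """Threshold maximizing Youden's J on the training ROC.

    Predicted positive means prob >= threshold. Ties in J are broken toward
    higher specificity (i.e. the higher threshold). The threshold is the
    midpoint between adjacent observed scores so it transfers smoothly to
    unseen test scores.
    """
    probs = np.asarray(train_probs, dtype=float)
    labels = np.asarray(train_labels)
    _check_two_classes(labels)
    u = np.unique(probs)
    cands = np.concatenate(([u[0] - 1e-12], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1e-12]))
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    pred = probs[None, :] >= cands[:, None]
    sens = (pred & pos[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~pos[None, :]).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[np.argmax(spec[best] + 1e-9 * cands[best])]
    return float(cands[best])


def sensitivity_specificity(probs, labels, threshold: float) -> tuple[float, float]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pred = probs >= threshold
    pos = labels == 1
    sens = float((pred & pos).sum() / pos.sum()) if pos.any() else float("nan")
    spec = float((~pred & ~pos).sum() / (~pos).sum()) if (~pos).any() else float("nan")
    return sens, spec


def subgroup_pooled_metrics(records: pd.DataFrame, group_key: str) -> pd.DataFrame:
    """Pooled metrics per subgroup over all iterations' test predictions.

    ``records`` needs columns prob, label, pred (thresholded at each
    iteration's own training operating point) and the grouping column.
    Single-class groups report NaN for the rank metrics rather than raising.
    """
    rows = []
    for group, sub in records.groupby(group_key, sort=True):
        labels = sub["label"].to_numpy()
        probs = sub["prob"].to_numpy()
        pred = sub["pred"].to_numpy().astype(bool)
        pos = labels == 1
        both = pos.any() and (~pos).any()
        rows.append(
            {
                group_key: group,
                "n_records": len(sub),
                "n_lesions": sub["lesion_id"].nunique(),
                "auc": roc_auc(probs, labels) if both else float("nan"),
                "auprc": au_prc(probs, labels) if both else float("nan"),
                "baseline_auprc": float(labels.mean()),
                "sensitivity": float((pred & pos).sum() / pos.sum())
                if pos.any()
                else float("nan"),
                "specificity": float((~pred & ~pos).sum() / (~pos).sum())
                if (~pos).any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
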