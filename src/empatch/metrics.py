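"""Evaluation metrics and t-SNE separability analysis.

Thin, contract-checked wrappers over scikit-learn for the standard
multiclass and regression metrics, plus a seeded t-SNE embedding whose
silhouette score is the testable surrogate for cluster separability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def classification_metrics(y_true: np.ndarray, probabilities: np.ndarray) -> dict:
    """Accuracy, macro precision/recall/F1 and the 3×3 confusion matrix.

    Probability rows must sum to 1; undefined per-class ratios (0/0) are
    reported as 0.
    """
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    n_classes = probabilities.shape[1]
    if np.any((y_true < 0) | (y_true >= n_classes)):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    y_pred = probabilities.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(n_classes), average="macro",
        zero_division=0,
    )
    return {
        "accuracy": float(np.trace(cm) / cm.sum()),
        "macro_precision": float(prec),
        "macro_recall": float(rec),
        "macro_f1": float(f1),
        "confusion": cm,
    }


def pr_curves(y_true: np.ndarray, probabilities: np.ndarray) -> dict:
    """One-vs-rest precision-recall curves and average precision per class.

    Classes absent from ``y_true`` are skipped with a warning rather than
    producing an undefined curve.
    """
    from sklearn.metrics import average_precision_score, precision_recall_curve

    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    out = {}
    for cls in range(probabilities.shape[1]):
        bin_true = (y_true == cls).astype(int)
        if bin_true.sum() == 0:
            warnings.warn(f"class {cls} absent from y_true; skipped")
            continue
        prec, rec, thr = precision_recall_curve(bin_true, probabilities[:, cls])
        ap = float(average_precision_score(bin_true, probabilities[:, cls]))
        out[cls] = {"precision": prec, "recall": rec, "thresholds": thr,
                    "average_precision": ap}
    return out


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """R² = 1 − SSres/SStot, RMSE and MAE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need >= 2 observations")
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero-variance truth; R² undefined")
    ssres = float(np.sum((y_true - y_pred) ** 2))
    return {
        "r2": 1.0 - ssres / sstot,
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        "mae": float(np.mean(np.abs(y_true - y_pred))),
    }


def tsne_separability(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> tuple[np.ndarray, float]:
    """Seeded 2-D t-SNE embedding plus the silhouette of the labels on it."""
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    if n < 10:
        raise ValueError("need >= 10 samples for a meaningful embedding")
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 distinct labels")
    if perplexity >= n:
        raise ValueError(
            f"perplexity {perplexity} must be < n_samples {n}; lower the perplexity"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, max_iter=n_iter,
        random_state=seed, init="pca",
    ).fit_transform(features)
    sil = float(silhouette_score(coords, labels))
    return coords, sil


def metrics_to_json(metrics: dict) -> dict:
    """JSON-serialisable copy of a metrics dict (arrays → lists)."""
    out = {}
    for k, v in metrics.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = float(v)
        elif isinstance(v, dict):
            out[k] = metrics_to_json(v)
        else:
            out[k] = v
    return out


def confusion_to_frame(cm: np.ndarray, class_names=("CON", "HFFD", "HFFSD")) -> pd.DataFrame:
    return pd.DataFrame(cm, index=[f"true_{c}" for c in class_names],
                        columns=[f"pred_{c}" for c in class_names])
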