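"""Evaluation metrics: DSC/PPV/TPR/VD (segmentation), ACC/SN/SP/AUC
(classification), and fold aggregation.

All metrics are returned as fractions in [0, 1] (VD >= 0, possibly > 1);
reporting helpers scale to percent. Undefined cases (empty ground truth,
single-class folds) are reported as NaN, never silently as zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

SEG_METRICS = ("DSC", "PPV", "TPR", "VD")
CLS_METRICS = ("ACC", "SN", "SP", "AUC")


def seg_metrics(pred_mask: np.ndarray, truth: np.ndarray) -> dict:
    """Voxel-overlap metrics between binary prediction and ground truth.

    VD is the absolute relative volume difference |#pred - #truth|/#truth.
    """
    pred_mask = np.asarray(pred_mask)
    truth = np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError("shape mismatch")
    p = pred_mask.astype(bool)
    t = truth.astype(bool)
    inter = float(np.logical_and(p, t).sum())
    n_pred = float(p.sum())
    n_true = float(t.sum())
    dsc = 2.0 * inter / (n_pred + n_true) if (n_pred + n_true) > 0 else np.nan
    ppv = inter / n_pred if n_pred > 0 else np.nan
    tpr = inter / n_true if n_true > 0 else np.nan
    vd = abs(n_pred - n_true) / n_true if n_true > 0 else np.nan
    return {"DSC": dsc, "PPV": ppv, "TPR": tpr, "VD": vd}


def cls_metrics(labels, probs, threshold: float = 0.5) -> dict:
    """Case-level metrics from positive-class probabilities.

    SN is recall of the positive class (label 1), SP of the negative.
    AUC uses the rank/trapezoidal convention (ties get half credit).
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must align")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else np.nan
    sn = tp / (tp + fn) if (tp + fn) else np.nan
    sp = tn / (tn + fp) if (tn + fp) else np.nan
    if len(np.unique(labels)) == 2:
        auc = float(roc_auc_score(labels, probs))
    else:
        auc = np.nan
    return {"ACC": acc, "SN": sn, "SP": sp, "AUC": auc}


def aggregate_folds(reports: list[dict]) -> pd.DataFrame:
    """Unweighted mean and SD across folds per metric.

    NaN entries are excluded from the aggregate; a warning counts them.
    Returns a DataFrame with rows mean/sd and one column per metric.
    """
    if not reports:
        raise ValueError("no fold reports to aggregate")
    frame = pd.DataFrame(reports)
    n_missing = int(frame.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing metric value(s) excluded from "
                      "fold aggregation", stacklevel=2)
    out = pd.DataFrame({
        "mean": frame.mean(axis=0, skipna=True),
        "sd": frame.std(axis=0, ddof=0, skipna=True),
    }).T
    return out


def to_percent(report: dict | pd.DataFrame):
    """Scale rate metrics (and VD) to percent for table display."""
    if isinstance(report, dict):
        return {k: 100.0 * v for k, v in report.items()}
    return 100.0 * report
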