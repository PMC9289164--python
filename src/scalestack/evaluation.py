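"""Cohort partitioning and class-imbalance-aware metrics.

Splits are patient-wise (all slides of a patient stay in one partition,
preventing tile-level leakage) and stratified on the class label with
largest-remainder rounding.  Metrics follow the conventions used for
heavily imbalanced multiclass problems:

* per-class F1 with the 0/0 -> 0 convention (a class never predicted
  and never correctly recovered scores 0),
* macro F1 (unweighted mean over classes) and weighted F1
  (support-weighted mean),
* the multiclass Matthews correlation coefficient

  .. math::

     \\mathrm{MCC} = \\frac{c\\,s - \\sum_k p_k t_k}
     {\\sqrt{(s^2 - \\sum_k p_k^2)(s^2 - \\sum_k t_k^2)}}

  with ``c`` the trace, ``s`` the total, ``p_k``/``t_k`` the predicted/
  true class totals; zero variance in either margin yields 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "patient_wise_stratified_split",
    "undersample_per_class",
    "confusion_matrix_counts",
    "confusion_and_f1",
    "mcc_multiclass",
    "assert_patient_disjoint",
    "overall_accuracy",
    "metrics_report",
]


def assert_patient_disjoint(cohort: pd.DataFrame) -> None:
    """Leakage guard: no patient may appear in both train and test."""
    split = cohort[cohort["split"].isin(["train", "test"])]
    per_patient = split.groupby("patient_id")["split"].nunique()
    leaked = per_patient[per_patient > 1]
    if len(leaked):
        raise AssertionError(
            f"patient-wise leakage: {list(leaked.index[:5])} in both splits"
        )


def patient_wise_stratified_split(cohort: pd.DataFrame, train_frac: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Assign train/test keeping patients whole and classes stratified.

    Per-class train slide counts use largest-remainder rounding of
    ``train_frac``; classes with a single slide go wholly to train (with
    a warning).  Deterministic given the seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    patient_split: dict = {}
    for label, grp in cohort.groupby("class_label", sort=True):
        n = len(grp)
        if n == 1:
            warnings.warn(
                f"class {label} has a single slide; assigned to train",
                stacklevel=2,
            )
            patient_split.setdefault(grp["patient_id"].iloc[0], "train")
            continue
        target = train_frac * n
        n_train = int(np.floor(target))
        if target - n_train >= 0.5:
            n_train += 1
        n_train = min(max(n_train, 1), n - 1)
        patients = grp.groupby("patient_id").size()
        # slides of this class already placed via a multi-class patient
        assigned = sum(
            patients[p] for p in patients.index
            if patient_split.get(p) == "train"
        )
        order = np.array(
            [p for p in patients.index if p not in patient_split]
        )
        rng.shuffle(order)
        for pid in order:
            dest = "train" if assigned < n_train else "test"
            patient_split[pid] = dest
            if dest == "train":
                assigned += patients[pid]
    out["split"] = out["patient_id"].map(patient_split)
    assert_patient_disjoint(out)
    return out


def undersample_per_class(cohort: pd.DataFrame, cap: int = 100, seed: int = 0) -> pd.DataFrame:
    """Uniformly sample at most ``cap`` slides per class (whole class
    retained when smaller); deterministic given the seed."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep = []
    for _, grp in cohort.groupby("class_label", sort=True):
        idx = grp.index.to_numpy()
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.extend(idx)
    return cohort.loc[sorted(keep)].copy()


def confusion_matrix_counts(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts C[true, pred]; labels must lie in [0, n_classes)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError("labels outside [0, n_classes)")
    C = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(C, (y_true, y_pred), 1)
    return C


def confusion_and_f1(y_true, y_pred, n_classes: int):
    """(confusion matrix, per-class F1, macro F1, weighted F1).

    F1_c = 2 TP_c / (2 TP_c + FP_c + FN_c), defined as 0 when the
    denominator is 0.  Macro averages over all ``n_classes`` (absent
    classes included); weighted F1 weights by true-class support.
    """
    C = confusion_matrix_counts(y_true, y_pred, n_classes)
    tp = np.diag(C).astype(np.float64)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    macro = float(f1.mean())
    support = C.sum(axis=1)
    total = support.sum()
    weighted = float((support / total * f1).sum()) if total else 0.0
    return C, f1, macro, weighted


def mcc_multiclass(C) -> float:
    """Generalized multiclass Matthews correlation coefficient."""
    C = np.asarray(C, dtype=np.float64)
    s = C.sum()
    if s <= 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(C)
    t = C.sum(axis=1)  # true totals
    p = C.sum(axis=0)  # predicted totals
    cov = c * s - p @ t
    var_p = s * s - p @ p
    var_t = s * s - t @ t
    if var_p <= 0 or var_t <= 0:
        return 0.0
    return float(cov / np.sqrt(var_p * var_t))


def overall_accuracy(C) -> float:
    C = np.asarray(C, dtype=np.float64)
    return float(np.trace(C) / C.sum())


def metrics_report(y_true, y_pred, n_classes: int, class_names=None) -> pd.DataFrame:
    """One-column report: summary metrics then per-class F1 rows.

    Overall accuracy is labelled ``overall_accuracy`` explicitly (class
    acronyms such as "ACC" are reserved for class rows).
    """
    C, f1, macro, weighted = confusion_and_f1(y_true, y_pred, n_classes)
    if class_names is None:
        class_names = [f"class_{i}" for i in range(n_classes)]
    rows = {
        "weighted_f1": weighted,
        "macro_f1": macro,
        "mcc": mcc_multiclass(C),
        "overall_accuracy": overall_accuracy(C),
    }
    for name, val in zip(class_names, f1):
        rows[name] = float(val)
    return pd.DataFrame({"metric": list(rows), "value": list(rows.values())})
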