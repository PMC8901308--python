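"""Diagnostic-agreement statistics for 2x2 tables and location counts.

The 2x2 table compares an imaging call against the pathology gold standard,
with "positive" meaning malignant.  Besides the standard sensitivity,
specificity, accuracy and Cohen's kappa, the module provides a per-type
location-similarity score: the mean over tumor types of
``min(predicted, reference) / max(predicted, reference)`` expressed as a
percentage — a symmetric count-agreement measure for frequency tables whose
rows are tumor locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

KAPPA_BANDS = ("strong", "general", "poor")


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts; test = imaging call, truth = pathology,
    positive = malignant."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class LocationCounts:
    """Per-tumor-type predicted/reference counts: a sequence of
    ``(type_label, predicted, reference)`` triples."""

    entries: tuple

    def __init__(self, entries: Sequence):
        norm = tuple((str(t), int(p), int(r)) for t, p, r in entries)
        if len(norm) == 0:
            raise ValueError("at least one tumor type is required")
        for t, p, r in norm:
            if p < 0 or r < 0:
                raise ValueError(f"negative count for type {t!r}")
            if p == 0 and r == 0:
                raise ValueError(f"type {t!r} has zero predicted and reference counts")
        object.__setattr__(self, "entries", norm)


def confusion_from_labels(y_true, y_pred) -> ConfusionTable:
    """Tabulate a ConfusionTable from binary label vectors (1 = malignant)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionTable(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
    )


def sensitivity(ct: ConfusionTable) -> float:
    """True-positive rate tp / (tp + fn)."""
    if ct.tp + ct.fn == 0:
        raise ZeroDivisionError("no positive cases: sensitivity undefined")
    return ct.tp / (ct.tp + ct.fn)


def specificity(ct: ConfusionTable) -> float:
    """True-negative rate tn / (tn + fp)."""
    if ct.tn + ct.fp == 0:
        raise ZeroDivisionError("no negative cases: specificity undefined")
    return ct.tn / (ct.tn + ct.fp)


def accuracy(ct: ConfusionTable) -> float:
    """Overall agreement (tp + tn) / total."""
    return (ct.tp + ct.tn) / ct.total


def cohen_kappa(ct: ConfusionTable) -> float:
    """Chance-corrected agreement (Po − Pe) / (1 − Pe).

    Pe comes from the row/column margins.  When Pe = 1 (a degenerate table
    where both raters are constant) kappa is undefined and NaN is returned
    rather than raising.
    """
    n = ct.total
    po = (ct.tp + ct.tn) / n
    pe = ((ct.tp + ct.fp) * (ct.tp + ct.fn) + (ct.fn + ct.tn) * (ct.fp + ct.tn)) / n**2
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)


def kappa_band(kappa: float) -> str:
    """Agreement band: > 0.75 strong; 0.4 <= k <= 0.75 general; < 0.4 poor."""
    if math.isnan(kappa):
        raise ValueError("kappa is undefined (NaN); no band applies")
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa > 0.75:
        return "strong"
    if kappa >= 0.4:
        return "general"
    return "poor"


def location_similarity(counts: LocationCounts) -> float:
    """Mean over tumor types of min/max count ratio, as a percentage.

    100 iff every type's predicted and reference counts agree; symmetric in
    the two count vectors and invariant to type reordering.
    """
    ratios = [min(p, r) / max(p, r) for _, p, r in counts.entries]
    return float(np.mean(ratios) * 100.0)


def evaluate_confusion(ct: ConfusionTable) -> dict:
    """All 2x2 metrics in one dict (kappa band included when defined)."""
    k = cohen_kappa(ct)
    out = {
        "tp": ct.tp,
        "fp": ct.fp,
        "fn": ct.fn,
        "tn": ct.tn,
        "sensitivity": sensitivity(ct),
        "specificity": specificity(ct),
        "accuracy": accuracy(ct),
        "kappa": k,
    }
    out["kappa_band"] = None if math.isnan(k) else kappa_band(k)
    return out
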