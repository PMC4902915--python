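"""Precision/Recall/F agreement machinery.

For a predicted mask scored against a reference mask,

* precision  P = |pred & truth| / |pred|   (how much of the prediction is object),
* recall     R = |pred & truth| / |truth|  (how much of the object is captured),
* F          = 2PR / (P + R), the harmonic mean (0 when P + R = 0).

F is symmetric under exchanging which mask plays the reference, since the
exchange merely swaps P and R.  Method agreement over an image set is the
per-pair mean of per-image F values: 8 methods give 28 unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .segmentation import METHOD_NAMES, MaskSet

__all__ = [
    "EvaluationScore",
    "AgreementMatrix",
    "precision_recall_f",
    "pairwise_f_matrix",
    "methods_vs_reference",
]


@dataclass(frozen=True)
class EvaluationScore:
    precision: float
    recall: float
    f_value: float


def precision_recall_f(pred: np.ndarray, truth: np.ndarray) -> EvaluationScore:
    """Score a predicted binary mask against a reference mask.

    Empty prediction gives P = 0; empty reference gives R = 0; F follows
    with the 0/0 convention F = 0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = int(np.logical_and(pred, truth).sum())
    n_pred = int(pred.sum())
    n_truth = int(truth.sum())
    p = inter / n_pred if n_pred else 0.0
    r = inter / n_truth if n_truth else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvaluationScore(p, r, f)


@dataclass
class AgreementMatrix:
    """Mean-F agreement between all method pairs over an image set."""

    methods: tuple[str, ...]
    mean_f: np.ndarray      # symmetric, diagonal 1 by convention
    n_images: int

    @property
    def n_pairs(self) -> int:
        k = len(self.methods)
        return k * (k - 1) // 2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_f, index=self.methods, columns=self.methods)


def pairwise_f_matrix(sets: list[MaskSet]) -> AgreementMatrix:
    """Agreement matrix: per-image F for each unordered method pair, averaged.

    One mask of the pair is treated as reference and the other as
    prediction; F is invariant to which is which, so each unordered pair is
    evaluated once and mirrored.
    """
    if not sets:
        raise ValueError("need at least one MaskSet")
    k = len(METHOD_NAMES)
    acc = np.zeros((k, k), dtype=np.float64)
    for ms in sets:
        for (i, a), (j, b) in combinations(enumerate(METHOD_NAMES), 2):
            f = precision_recall_f(ms[a], ms[b]).f_value
            acc[i, j] += f
            acc[j, i] += f
    mean = acc / len(sets)
    np.fill_diagonal(mean, 1.0)
    return AgreementMatrix(METHOD_NAMES, mean, len(sets))


def methods_vs_reference(
    sets: list[MaskSet],
    refs: list[np.ndarray],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Score every method against a per-image reference mask.

    Images whose reference is empty are skipped.  Returns mean and standard
    error of the mean (sample SD / sqrt(n)) of P, R and F per method —
    overall, or stratified by ``labels`` (e.g. a W0/W1 week label per image)
    when given.

    Returns a tidy frame with columns
    ``method, label, n, precision_mean, precision_se, recall_mean,
    recall_se, f_mean, f_se``.
    """
    if len(sets) != len(refs):
        raise ValueError("sets and refs must have equal length")
    if labels is not None and len(labels) != len(sets):
        raise ValueError("labels must align with sets")
    rows = []
    for idx, (ms, ref) in enumerate(zip(sets, refs)):
        ref = np.asarray(ref, dtype=bool)
        if not ref.any():
            continue
        lab = labels[idx] if labels is not None else "all"
        for m in METHOD_NAMES:
            sc = precision_recall_f(ms[m], ref)
            rows.append((m, lab, sc.precision, sc.recall, sc.f_value))
    scores = pd.DataFrame(rows, columns=["method", "label", "precision", "recall", "f"])
    if scores.empty:
        raise ValueError("no image with a non-empty reference mask")

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        out = {"n": n}
        for col in ("precision", "recall", "f"):
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        return pd.Series(out)

    result = (
        scores.groupby(["method", "label"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    result["n"] = result["n"].astype(int)
    return result
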