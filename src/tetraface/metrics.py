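"""Evaluation metrics for both pipeline stages.

Stage 1 (chain interaction): confusion-matrix metrics, rank-based AUC, and
the per-complex PT vector (a, b) counting correctly predicted interactions
and non-interactions, with ||PT||₁ = a + b.

Stage 2 (interface residue pairs): the NPIRP vector (n₁..n₆) counts, per
chain pair of a complex, the true interface pairs among the top-t ranked
predictions; its L0 norm is the number of interfaces hit, its L1 norm the
total hits.  Accuracy4t is the percentage of complexes with at least z
interfaces hit among complexes having at least z native interfaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .ensemble import InterfaceRanking

#: fixed chain-pair order used for NPIRP components.
PAIR_ORDER_NOTE = "six unordered chain pairs in (AB, AC, AD, BC, BD, CD) order"


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValueError("confusion counts are all zero")


@dataclass
class NpirpVector:
    """Per-complex 6-vector of true interface pairs found in the top t."""

    n: np.ndarray  # length 6
    t: int

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, int)
        if self.n.shape != (6,):
            raise ValueError("NPIRP vector must have 6 components")
        if np.any(self.n < 0) or np.any(self.n > self.t):
            raise ValueError("each component must lie in [0, t]")

    @property
    def l0(self) -> int:
        return int(np.count_nonzero(self.n))

    @property
    def l1(self) -> int:
        return int(self.n.sum())


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Recall, specificity, precision, F1, MCC and accuracy from counts.

    Metrics with a zero denominator are reported as NaN with a warning.
    """
    tp, fn, fp, tn = c.tp, c.fn, c.fp, c.tn
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "recall": _safe_div(tp, tp + fn, "recall"),
        "specificity": _safe_div(tn, tn + fp, "specificity"),
        "precision": _safe_div(tp, tp + fp, "precision"),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
    }


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def pt_norm(pred_labels, true_labels) -> tuple[int, int, int]:
    """The PT vector (a, b) of one complex and its L1 norm a + b.

    ``a`` counts correctly predicted interactions, ``b`` correctly
    predicted non-interactions, over the six chain pairs.
    """
    pred = np.asarray(pred_labels, int)
    true = np.asarray(true_labels, int)
    if pred.shape != (6,) or true.shape != (6,):
        raise ValueError("a tetramer complex has exactly 6 chain-pair samples")
    a = int(np.sum((true == 1) & (pred == 1)))
    b = int(np.sum((true == 0) & (pred == 0)))
    return a, b, a + b


def npirp(
    rankings: list[InterfaceRanking],
    true_pairs: dict[tuple[str, str], set[tuple[int, int]]],
    t: int,
) -> NpirpVector:
    """Count true interface pairs among each chain pair's top-t predictions.

    ``rankings`` holds the six chain-pair rankings of one complex in the
    fixed pair order; ``true_pairs`` maps each chain pair to its positive
    residue-index pairs.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(rankings) != 6:
        raise ValueError("a tetramer complex has exactly 6 chain pairs")
    counts = []
    for ranking in rankings:
        top = ranking.top(t) if len(ranking.scores) > t else ranking
        truth = true_pairs[ranking.chain_pair]
        counts.append(
            sum(1 for i, j in map(tuple, top.pairs) if (i, j) in truth)
        )
    return NpirpVector(np.array(counts), t=t)


def accuracy4t(l0_values, native_counts, z: int) -> float:
    """Percentage of complexes with >= z interfaces hit, among complexes
    with >= z native interfaces.

    ``l0_values`` are per-complex NPIRP L0 norms at some t;
    ``native_counts`` the per-complex numbers of native interfaces.
    """
    l0 = np.asarray(l0_values, int)
    native = np.asarray(native_counts, int)
    if l0.shape != native.shape:
        raise ValueError("l0_values and native_counts must align")
    if z < 1:
        raise ValueError("z must be >= 1")
    ntp = int(np.sum(native >= z))
    if ntp == 0:
        raise ValueError(f"no complex has {z} native interfaces")
    nctp = int(np.sum(l0 >= z))
    return 100.0 * nctp / ntp
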