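"""Scoring estimated connection matrices against simulator ground truth.

Detection is scored as two independent binary classifications over the
N(N-1) ordered pairs: the excitatory category (is there a sufficiently
strong excitatory synapse?) and the inhibitory category.  Excitatory true
edges with conductance at or below ``exc_floor`` (on the raw, pre-A
scale) are too weak to be detectable in principle and are excluded from
the excitatory universe entirely — they count neither as positives nor
negatives.  A sign-flipped detection (true excitatory edge reported
inhibitory) is a false negative in the true category and a false positive
in the reported one.  Each category is summarized by its FPR, FNR and
Matthews correlation coefficient; the headline score is the macro-average
MCC = (MCC_e + MCC_i)/2, weighting both categories equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glmcc import ConnectionMatrix
from .mat_network import Connectivity

__all__ = ["CategoryCounts", "EvalResult", "confusion_counts", "scores",
           "mcc_from_counts"]


@dataclass(frozen=True)
class CategoryCounts:
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass(frozen=True)
class CategoryScore:
    TP: int
    FP: int
    FN: int
    TN: int
    FPR: float
    FNR: float
    MCC: float


@dataclass(frozen=True)
class EvalResult:
    excitatory: CategoryScore
    inhibitory: CategoryScore
    macro_mcc: float


def confusion_counts(truth: Connectivity, est: ConnectionMatrix,
                     exc_floor: float = 0.01) -> dict:
    """Per-category confusion counts of an estimate against ground truth.

    ``exc_floor`` is the excitatory-conductance threshold (raw scale,
    before the strength multiplier A) below which true excitatory edges
    are excluded from the excitatory category.
    """
    N = truth.n
    if est.n_units != N:
        raise ValueError(
            f"unit sets differ: truth has {N} units, estimate {est.n_units}")
    off = ~np.eye(N, dtype=bool)
    exc_src = truth.is_exc[:, None] & off
    true_e_strong = exc_src & (truth.G_raw > exc_floor)
    true_e_weak = exc_src & (truth.G_raw > 0) & (truth.G_raw <= exc_floor)
    true_i = (~truth.is_exc[:, None]) & off & (truth.G_raw > 0)
    pred_e = (est.sign == 1) & off
    pred_i = (est.sign == -1) & off

    univ_e = off & ~true_e_weak  # weak excitatory edges leave the universe
    counts = {}
    for name, tru, pred, univ in (
        ("excitatory", true_e_strong, pred_e, univ_e),
        ("inhibitory", true_i, pred_i, off),
    ):
        tp = int(np.sum(tru & pred & univ))
        fp = int(np.sum(~tru & pred & univ))
        fn = int(np.sum(tru & ~pred & univ))
        tn = int(np.sum(~tru & ~pred & univ))
        counts[name] = CategoryCounts(tp, fp, fn, tn)
    return counts


def mcc_from_counts(c: CategoryCounts) -> float:
    """Binary Matthews correlation; 0 when a denominator factor vanishes."""
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def scores(counts: dict) -> EvalResult:
    """FPR/FNR/MCC per category and the macro-average MCC."""
    out = {}
    for name, c in counts.items():
        fpr = c.FP / (c.FP + c.TN) if (c.FP + c.TN) > 0 else 0.0
        fnr = c.FN / (c.FN + c.TP) if (c.FN + c.TP) > 0 else 0.0
        out[name] = CategoryScore(c.TP, c.FP, c.FN, c.TN, fpr, fnr,
                                  mcc_from_counts(c))
    macro = 0.5 * (out["excitatory"].MCC + out["inhibitory"].MCC)
    return EvalResult(out["excitatory"], out["inhibitory"], macro)
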