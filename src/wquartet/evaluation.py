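"""Accuracy metrics: species-tree false-negative rate, support
calibration, ROC over contraction thresholds, and support ECDFs."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import AnnotatedTree

logger = logging.getLogger(__name__)

__all__ = [
    "SupportRecord",
    "fn_rate",
    "support_records",
    "calibration_table",
    "roc_curve",
    "support_ecdf",
    "CALIBRATION_BINS",
]


@dataclass(frozen=True)
class SupportRecord:
    branch: tuple
    support: float
    correct: bool

    def __post_init__(self):
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")


def fn_rate(true_tree: AnnotatedTree, estimated_tree: AnnotatedTree) -> float:
    """Fraction of the true tree's internal bipartitions missing from the
    estimate; equals the normalised Robinson-Foulds distance when both
    trees are binary."""
    if true_tree.leaf_names() != estimated_tree.leaf_names():
        raise ValueError("trees must share the same leaf set")
    true_bip = true_tree.bipartitions()
    if not true_bip:
        raise ValueError("true tree has no internal bipartitions")
    est_bip = estimated_tree.bipartitions()
    return len(true_bip - est_bip) / len(true_bip)


def support_records(true_tree: AnnotatedTree,
                    annotated_estimate: AnnotatedTree) -> list[SupportRecord]:
    """One record per supported internal branch of the estimate, marked
    correct when its bipartition occurs in the true tree."""
    true_bip = true_tree.bipartitions()
    all_names = frozenset(annotated_estimate.leaf_names())
    anchor = min(all_names)
    records = []
    below: dict[int, frozenset] = {}
    for node in annotated_estimate.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is annotated_estimate.root or node.parent is None:
            continue
        side = below[id(node)]
        if len(side) < 2 or len(all_names - side) < 2:
            continue
        if node.support is None:
            continue
        key = side if anchor not in side else all_names - side
        records.append(SupportRecord(tuple(sorted(key)), node.support,
                                     key in true_bip))
    return records


#: Half-open support bins plus a final {1} bin that captures supports
#: rounding to 1 at output precision (>= ROUND_ONE).
CALIBRATION_BINS: list[tuple[float, float]] = [
    (1.0 / 3.0, 0.5), (0.5, 0.75), (0.75, 0.9), (0.9, 0.95), (0.95, 1.0),
    (1.0, 1.0),
]
ROUND_ONE = 0.99995


def calibration_table(records) -> pd.DataFrame:
    """Per-bin count, mean correctness, and bin midpoint.

    Supports below 1/3 (outside the localPP range) are binned into the
    first bin with a warning; empty bins are absent from the table.
    """
    sup = np.array([r.support for r in records])
    cor = np.array([r.correct for r in records], dtype=float)
    if np.any(sup < 1.0 / 3.0):
        logger.warning("%d supports below 1/3 binned into the first bin",
                       int((sup < 1.0 / 3.0).sum()))
    rows = []
    last = len(CALIBRATION_BINS) - 1
    for i, (lo, hi) in enumerate(CALIBRATION_BINS):
        if i == 0:
            mask = sup < hi          # catches sub-1/3 stragglers too
        elif i == last:
            mask = sup >= ROUND_ONE
        else:
            mask = (sup >= lo) & (sup < (ROUND_ONE if hi == 1.0 else hi))
        mid = 1.0 if i == last else (lo + hi) / 2.0
        if not mask.any():
            continue
        rows.append({"bin_low": lo, "bin_high": hi, "midpoint": mid,
                     "count": int(mask.sum()),
                     "accuracy": float(cor[mask].mean())})
    return pd.DataFrame(rows)


def roc_curve(records, thresholds) -> pd.DataFrame:
    """Recall (kept correct / correct) and FPR (kept incorrect / incorrect)
    when keeping branches with support >= threshold.

    FPR is NaN (absent) when there are no incorrect branches.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    sup = np.array([r.support for r in records])
    cor = np.array([r.correct for r in records], dtype=bool)
    n_cor = int(cor.sum())
    n_inc = int((~cor).sum())
    rows = []
    for t in thresholds:
        keep = sup >= t
        recall = (keep & cor).sum() / n_cor if n_cor else np.nan
        fpr = (keep & ~cor).sum() / n_inc if n_inc else np.nan
        rows.append({"threshold": t, "recall": recall, "fpr": fpr})
    return pd.DataFrame(rows)


def support_ecdf(records):
    """ECDFs of supports for correct and incorrect branches.

    Returns ``(F_correct, F_incorrect, gap)`` where each F maps an array of
    values to cumulative fractions and ``gap`` is the maximum vertical
    distance between the two curves (requires at least one record in each
    class; otherwise the missing curve is None and the gap NaN).
    """
    sup = np.array([r.support for r in records])
    cor = np.array([r.correct for r in records], dtype=bool)

    def make_ecdf(values):
        values = np.sort(values)

        def F(x):
            x = np.asarray(x, dtype=float)
            return np.searchsorted(values, x, side="right") / len(values)

        return F

    Fc = make_ecdf(sup[cor]) if cor.any() else None
    Fi = make_ecdf(sup[~cor]) if (~cor).any() else None
    if Fc is None or Fi is None:
        return Fc, Fi, float("nan")
    grid = np.unique(sup)
    gap = float(np.max(np.abs(Fc(grid) - Fi(grid))))
    return Fc, Fi, gap
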