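"""Downstream relevance analytics: ZCR quadrants, global and hidden maps.

Links what the networks attend to (LRP relevance) with how the signals
behave (zero-crossing rate), summarizes input relevance globally and
per class, and characterizes hidden-unit usage.

Quadrant semantics (with "high" meaning strictly above the threshold,
by default the median over all points):

* Q1 — high relevance count, high ZCR
* Q2 — low relevance count, high ZCR
* Q3 — high relevance count, low ZCR
* Q4 — low relevance count, low ZCR
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lrp import NormalizedRelevance

__all__ = [
    "QuadrantPoint",
    "HiddenRelevanceMatrix",
    "zero_crossing_rate",
    "relevance_count",
    "quadrant_assign",
    "accumulated_input_relevance",
    "hidden_relevance_matrix",
]


@dataclass
class QuadrantPoint:
    """One (channel, class) point in ZCR x relevance-count space."""

    channel: int
    class_id: int
    zcr: float
    rel_count: int
    quadrant: str = ""


@dataclass
class HiddenRelevanceMatrix:
    """Per-class hidden-unit relevance with sorting and highlighting.

    ``values`` is (NH, n_classes) with each column summing to 1;
    ``row_order`` sorts units by the sort-class column descending;
    ``highlight_set`` is the smallest prefix of the all-class
    accumulated ranking whose cumulative share exceeds the threshold.
    """

    values: np.ndarray
    class_ids: list[int]
    row_order: np.ndarray
    highlight_set: list[int]
    sort_class: int


def zero_crossing_rate(signal: np.ndarray, fs: float) -> float:
    """Strict sign changes per second; zeros continue the previous sign.

    Duration is taken as n/fs so an alternating +1/-1 series at 100 Hz
    over 3 s gives 299/3 Hz.
    """
    x = np.asarray(signal, float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a zero-crossing rate")
    s = np.sign(x)
    # carry the previous sign through exact zeros
    for i in range(s.size):
        if s[i] == 0:
            s[i] = s[i - 1] if i > 0 else 0.0
    if np.all(s == 0):
        return 0.0
    # leading zeros adopt the first nonzero sign (no spurious crossing)
    first = np.argmax(s != 0)
    s[:first] = s[first]
    crossings = int(np.sum(s[1:] != s[:-1]))
    return crossings / (x.size / fs)


def relevance_count(
    norm: NormalizedRelevance | np.ndarray, quantile: float = 0.70
) -> np.ndarray:
    """Per-channel count of time points above the top-(1-q) threshold.

    The threshold is the ``quantile`` of all (channel x time) relevance
    values of the sample, taken jointly; counting is strict, so a
    degenerate all-equal map yields all-zero counts (with a warning).
    """
    temporal = norm.temporal if isinstance(norm, NormalizedRelevance) else np.asarray(norm, float)
    if temporal is None:
        raise ValueError("NormalizedRelevance has no temporal matrix")
    if temporal.ndim != 2:
        raise ValueError(f"temporal matrix must be 2-D, got {temporal.shape}")
    flat = temporal.ravel()
    if np.all(flat == flat[0]):
        warnings.warn("degenerate all-equal relevance map: all counts zero")
        return np.zeros(temporal.shape[1], dtype=int)
    # 'higher' keeps the strictly-above count within the (1-q) budget
    threshold = np.quantile(flat, quantile, method="higher")
    return (temporal > threshold).sum(axis=0).astype(int)


def quadrant_assign(
    points: list[QuadrantPoint],
    zcr_threshold: float | None = None,
    count_threshold: float | None = None,
) -> tuple[list[QuadrantPoint], pd.DataFrame]:
    """Label each point Q1..Q4 and tally per (class x quadrant).

    Thresholds default to the medians over all points; "high" is
    strictly above the threshold, so points exactly on a median fall on
    the low side.
    """
    if not points:
        raise ValueError("empty point set")
    if zcr_threshold is None:
        zcr_threshold = float(np.median([p.zcr for p in points]))
    if count_threshold is None:
        count_threshold = float(np.median([p.rel_count for p in points]))
    for p in points:
        high_r = p.rel_count > count_threshold
        high_z = p.zcr > zcr_threshold
        p.quadrant = {
            (True, True): "Q1",
            (False, True): "Q2",
            (True, False): "Q3",
            (False, False): "Q4",
        }[(high_r, high_z)]
    classes = sorted({p.class_id for p in points})
    tally = pd.DataFrame(
        0, index=classes, columns=["Q1", "Q2", "Q3", "Q4"], dtype=int
    )
    for p in points:
        tally.loc[p.class_id, p.quadrant] += 1
    tally.index.name = "class_id"
    return points, tally


def accumulated_input_relevance(per_class: pd.DataFrame) -> pd.Series:
    """Sum column-normalized class relevances per channel, renormalize,
    and sort descending."""
    totals = per_class.sum(axis=1)
    totals = totals / totals.sum()
    return totals.sort_values(ascending=False)


def hidden_relevance_matrix(
    norms,
    labels,
    predictions,
    sort_class: int = 0,
    highlight_threshold: float = 0.55,
    class_ids=None,
) -> HiddenRelevanceMatrix:
    """Class-wise hidden-unit relevance from per-sample normalizations.

    Per correctly classified sample, the absolute hidden relevance is
    summed over time and l1-normalized (this is exactly the global
    normalization the per-sample ``NormalizedRelevance`` carries);
    vectors are averaged per class and re-normalized so each column
    sums to 1.  Rows are sorted by the ``sort_class`` column
    descending; ``highlight_set`` is the smallest prefix of the
    all-class accumulated ranking exceeding ``highlight_threshold``.
    """
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    if class_ids is None:
        class_ids = sorted(set(labels.tolist()))
    cols = {}
    for cid in class_ids:
        idx = np.where((labels == cid) & (predictions == cid))[0]
        if idx.size == 0:
            warnings.warn(f"class {cid}: no correct predictions; excluded")
            continue
        V = np.mean([norms[i].global_rel for i in idx], axis=0)
        cols[cid] = V / V.sum()
    if not cols:
        raise ValueError("no class had correct predictions")
    kept_ids = list(cols)
    values = np.column_stack([cols[c] for c in kept_ids])
    sort_col = kept_ids.index(sort_class) if sort_class in cols else 0
    row_order = np.argsort(-values[:, sort_col], kind="stable")
    accumulated = values.sum(axis=1)
    accumulated = accumulated / accumulated.sum()
    ranking = np.argsort(-accumulated, kind="stable")
    cum = 0.0
    highlight: list[int] = []
    for unit in ranking:
        highlight.append(int(unit))
        cum += accumulated[unit]
        if cum > highlight_threshold:
            break
    return HiddenRelevanceMatrix(
        values=values,
        class_ids=kept_ids,
        row_order=row_order,
        highlight_set=highlight,
        sort_class=sort_class,
    )
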