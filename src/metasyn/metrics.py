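"""Evaluation surface: confusion counts, P/R/F1, best-F1 sweep, DL-vs-RBA
prediction-difference breakdown.

A score is predicted positive when it is greater than or equal to the
threshold (boundary inclusive, so binary 0/1 rule outputs are evaluable at
threshold 0.5).  Zero-denominator ratios are reported as 0 with an explicit
flag rather than NaN, which keeps threshold sweeps stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "DifferenceRow",
    "confusion_at",
    "prf1",
    "best_f1",
    "difference_breakdown",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall / F1 at one threshold.

    ``undefined`` lists the metrics whose denominator was zero (reported as
    0 by convention).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Confusion counts with prediction = (score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError(f"scores and labels differ in length: {s.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def prf1(c: ConfusionCounts, threshold: float | None = None) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero pairs")
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        undefined=frozenset(undefined),
    )


def best_f1(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] | None = None,
) -> tuple[float, MetricsReport]:
    """Threshold maximizing F1 over a grid (default 0.00..1.00 step 0.01).

    Ties resolve to the lowest threshold.  Returns the winning threshold
    and the full metric report at it.
    """
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    best_t = float(grid[0])
    best: MetricsReport | None = None
    for t in grid:
        report = prf1(confusion_at(scores, labels, float(t)), threshold=float(t))
        if best is None or report.f1 > best.f1:
            best, best_t = report, float(t)
    assert best is not None
    return best_t, best


class DifferenceRow(NamedTuple):
    """One disagreement stratum of the DL-vs-RBA comparison."""

    label: int
    dl: int
    rba: int
    sim_flag: str | None
    count: int


def difference_breakdown(
    dl_preds: Sequence[int],
    rba_preds: Sequence[int],
    labels: Sequence[int],
    sim_flags: Sequence[str | None],
) -> list[DifferenceRow]:
    """Distribution of pairs where the two approaches disagree.

    Rows are keyed by (label, DL prediction, RBA prediction, SIM/NOSIM
    flag); their counts partition the disagreeing pairs.  Positives carry a
    ``None`` flag and are reported in a stratum of their own per label.
    """
    n = len(labels)
    if not (len(dl_preds) == len(rba_preds) == n == len(sim_flags)):
        raise ValueError("all input vectors must have equal length")
    counts: dict[tuple[int, int, int, str | None], int] = {}
    for dl, rba, y, flag in zip(dl_preds, rba_preds, labels, sim_flags):
        if dl == rba:
            continue
        key = (int(y), int(dl), int(rba), flag)
        counts[key] = counts.get(key, 0) + 1
    return [
        DifferenceRow(*key, count)
        for key, count in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], str(kv[0][3])))
    ]
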