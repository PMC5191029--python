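"""Confusion matrices, macro performance measures, and split protocols.

Conventions
-----------
Confusion matrices are oriented rows = recognized (predicted) class,
columns = annotated (true) class.  The four macro measures are

* recall    — mean over classes of diagonal / row sum,
* precision — mean over classes of diagonal / column sum,
* F-measure — harmonic mean of recall and precision,
* accuracy  — trace / total,

under the default ``as_printed`` orientation, which reproduces published
summary tables for this benchmark from their printed matrices.  The
``as_equations`` orientation swaps the roles of row and column sums
(recall = diagonal/colsum, precision = diagonal/rowsum), the literal
reading of the defining formulas with rows-recognized matrices; the two
differ only by a transpose.  A class with zero row (column) total
contributes 0 to its macro mean, keeping the class count fixed.

Reference matrices: the package ships the two 12-activity confusion
matrices published for the PAMAP2 IE-feature experiment (three sensors,
half/half chronological split).  The published summary of those matrices
prints its harmonic-mean and trace/total columns interchanged relative to
the column headers; ``reference_measures`` returns the values computed
both ways so the mapping is explicit.

Split protocols: the dependent-subject protocol pools all subjects and
splits each subject's windows of each activity chronologically in half;
the independent-subject protocol applies that split within each subject
separately and trains one model per subject, aggregating the per-subject
measures weighted by test-sample counts N_i / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .pamap2 import WindowSet

__all__ = [
    "ConfusionMatrix",
    "PerformanceMeasures",
    "confusion",
    "measures",
    "dependent_split",
    "split_masks",
    "independent_protocol",
    "overall_pm",
    "reference_confusions",
    "reference_measures",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows = recognized class, columns = annotated class."""

    counts: np.ndarray
    classes: list[int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PerformanceMeasures:
    recall: float
    precision: float
    f_measure: float
    accuracy: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.recall, self.precision, self.f_measure, self.accuracy)


def confusion(
    true_labels, predicted_labels, classes: list[int] | int
) -> ConfusionMatrix:
    """Count (recognized i, annotated j) pairs.

    ``classes`` is either an explicit label list or an integer C meaning
    labels 1..C.
    """
    if isinstance(classes, int):
        classes = list(range(1, classes + 1))
    index = {c: i for i, c in enumerate(classes)}
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    C = len(classes)
    M = np.zeros((C, C), dtype=int)
    for ti, pi in zip(t, p):
        if int(ti) not in index or int(pi) not in index:
            raise ValueError(f"label out of range: true={ti}, predicted={pi}")
        M[index[int(pi)], index[int(ti)]] += 1
    return ConfusionMatrix(counts=M, classes=list(classes))


def _macro_ratio(diag: np.ndarray, sums: np.ndarray) -> float:
    # zero-support classes contribute 0, keeping the 1/C factor fixed
    ratio = np.where(sums > 0, diag / np.where(sums > 0, sums, 1), 0.0)
    return float(np.mean(ratio))


def measures(
    matrix: ConfusionMatrix | np.ndarray, orientation: str = "as_printed"
) -> PerformanceMeasures:
    """The four macro measures of a confusion matrix (see module docstring)."""
    M = matrix.counts if isinstance(matrix, ConfusionMatrix) else np.asarray(matrix)
    if M.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(M).astype(float)
    row = M.sum(axis=1).astype(float)
    col = M.sum(axis=0).astype(float)
    if orientation == "as_printed":
        recall, precision = _macro_ratio(diag, row), _macro_ratio(diag, col)
    elif orientation == "as_equations":
        recall, precision = _macro_ratio(diag, col), _macro_ratio(diag, row)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    f = 0.0 if recall * precision == 0 else 2 * recall * precision / (recall + precision)
    accuracy = float(diag.sum() / M.sum())
    return PerformanceMeasures(recall=recall, precision=precision, f_measure=f, accuracy=accuracy)


def split_masks(
    subject: np.ndarray,
    activity: np.ndarray,
    start_time: np.ndarray,
    fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Chronological per-subject per-activity train/test masks.

    Within each (subject, activity) group, windows sorted by start time
    are split first-``fraction`` train / rest test.  Deterministic.
    """
    n = len(activity)
    train = np.zeros(n, dtype=bool)
    for s in np.unique(subject):
        for a in np.unique(activity):
            idx = np.flatnonzero((subject == s) & (activity == a))
            if idx.size == 0:
                continue
            order = idx[np.argsort(start_time[idx], kind="stable")]
            n_train = int(idx.size * fraction)
            train[order[:n_train]] = True
    return train, ~train


def dependent_split(
    windows: WindowSet, fraction: float = 0.5
) -> tuple[WindowSet, WindowSet]:
    """Pooled-subject chronological split (train half earlier in time)."""
    tr, te = split_masks(windows.subject, windows.activity, windows.start_time, fraction)
    return _take(windows, tr), _take(windows, te)


def _take(w: WindowSet, mask: np.ndarray) -> WindowSet:
    return WindowSet(
        data=w.data[mask],
        activity=w.activity[mask],
        subject=w.subject[mask],
        start_time=w.start_time[mask],
        fs=w.fs,
        window=w.window,
        shift=w.shift,
    )


def independent_protocol(
    windows: WindowSet, fraction: float = 0.5
) -> dict[int, tuple[WindowSet, WindowSet]]:
    """Per-subject (train, test) pairs: the chronological split applied
    within each subject's own data, no cross-subject mixing."""
    out: dict[int, tuple[WindowSet, WindowSet]] = {}
    for s in sorted(int(v) for v in np.unique(windows.subject)):
        sub = _take(windows, windows.subject == s)
        out[s] = dependent_split(sub, fraction)
    return out


def overall_pm(
    per_subject: list[tuple[PerformanceMeasures, int]]
) -> PerformanceMeasures:
    """Sample-weighted aggregate: each measure summed as (N_i / N) * PM_i."""
    if not per_subject:
        raise ValueError("no per-subject measures to aggregate")
    total = sum(n for _, n in per_subject)
    if total <= 0:
        raise ValueError("sample counts must be positive")
    acc = np.zeros(4)
    for pm, n in per_subject:
        acc += (n / total) * np.array(pm.as_tuple())
    return PerformanceMeasures(*acc)


def reference_confusions() -> dict[str, ConfusionMatrix]:
    """The packaged 12-activity reference confusion matrices (IE features).

    Keys ``train`` and ``test`` follow the matrices' own captions (fit on
    the train half, scored on the test half).
    """
    out = {}
    for key, fname in (("train", "confusion_train_ie.tsv"), ("test", "confusion_test_ie.tsv")):
        text = resources.files("hhtar.data").joinpath(fname).read_text()
        M = np.array(
            [[int(v) for v in line.split()] for line in text.strip().splitlines()]
        )
        out[key] = ConfusionMatrix(counts=M, classes=list(range(1, 13)))
    return out


def reference_measures() -> dict[str, PerformanceMeasures]:
    """Macro measures recomputed from the packaged reference matrices."""
    return {k: measures(m) for k, m in reference_confusions().items()}
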