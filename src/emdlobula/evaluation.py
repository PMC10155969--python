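"""Threshold segmentation and F-measure scoring against ground truth.

A stage signal (EMD output, module input conductance, or module sigmoid
output) is binarized each frame at a fraction of its per-frame maximum
(50 % by default) after orienting it by the evaluated module's preferred
sign, then scored against the analytic foreground mask with precision,
recall and the F-measure 2TP/(2TP + FP + FN).  Frame averages exclude an
initial transient (50 frames by default) and frames whose ground truth is
empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegmentationSeries",
    "segment",
    "confusion",
    "precision",
    "recall",
    "f_measure",
    "evaluate_series",
]

TRANSIENT_FRAMES = 50


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def segment(
    stage_matrix: np.ndarray,
    threshold_fraction: float = 0.5,
    preferred_sign: int = 1,
) -> np.ndarray:
    """Binarize a signed stage matrix at a fraction of its maximum.

    The matrix is first oriented by ``preferred_sign`` (−1 evaluates the
    leftward/negative component); pixels at or above
    ``threshold_fraction * max`` are foreground.  If the oriented maximum is
    not positive the mask is all-false.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if preferred_sign not in (1, -1):
        raise ValueError("preferred_sign must be +1 or -1")
    s = preferred_sign * np.asarray(stage_matrix, dtype=float)
    smax = s.max() if s.size else 0.0
    if smax <= 0.0:
        return np.zeros_like(s, dtype=bool)
    return s >= threshold_fraction * smax


def confusion(mask: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError("mask and ground truth must share shape")
    tp = int(np.count_nonzero(mask & truth))
    fp = int(np.count_nonzero(mask & ~truth))
    fn = int(np.count_nonzero(~mask & truth))
    tn = mask.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f_measure(counts: ConfusionCounts) -> float:
    """F = 2TP/(2TP + FP + FN); 1.0 by convention when prediction and truth
    are both empty (perfect agreement), 0.0 when TP = 0 otherwise."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


@dataclass
class SegmentationSeries:
    """Per-frame masks and scores for one stage, with transient-free means."""

    stage: str
    threshold_fraction: float
    masks: np.ndarray  # (T, H, W) bool
    f: np.ndarray  # (T,)
    precision: np.ndarray
    recall: np.ndarray
    evaluated: np.ndarray  # (T,) bool: past transient and nonempty truth
    transient_frames: int = TRANSIENT_FRAMES

    @property
    def mean_f(self) -> float:
        if not self.evaluated.any():
            return float("nan")
        return float(self.f[self.evaluated].mean())


def evaluate_series(
    signals: np.ndarray,
    truths: np.ndarray,
    stage: str = "module_output",
    threshold_fraction: float = 0.5,
    preferred_sign: int = 1,
    transient_frames: int = TRANSIENT_FRAMES,
    border_margin: int = 0,
) -> SegmentationSeries:
    """Segment and score a stack of per-frame stage matrices.

    ``border_margin`` optionally excludes that many pixels at the array
    border from the confusion counts (zero-padded receptive fields distort
    the outermost units).  Frames with empty ground truth are flagged as not
    evaluated rather than scored.
    """
    signals = np.asarray(signals, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if signals.shape != truths.shape:
        raise ValueError("signals and ground-truth stacks must share shape")
    T = signals.shape[0]
    masks = np.zeros_like(truths)
    f = np.zeros(T)
    prec = np.zeros(T)
    rec = np.zeros(T)
    evaluated = np.zeros(T, dtype=bool)
    m = border_margin
    sl = (slice(m, signals.shape[1] - m or None), slice(m, signals.shape[2] - m or None))
    for t in range(T):
        mask = segment(signals[t], threshold_fraction, preferred_sign)
        masks[t] = mask
        counts = confusion(mask[sl], truths[t][sl])
        f[t] = f_measure(counts)
        prec[t] = precision(counts)
        rec[t] = recall(counts)
        evaluated[t] = t >= transient_frames and truths[t][sl].any()
    return SegmentationSeries(
        stage=stage,
        threshold_fraction=threshold_fraction,
        masks=masks,
        f=f,
        precision=prec,
        recall=rec,
        evaluated=evaluated,
        transient_frames=transient_frames,
    )
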