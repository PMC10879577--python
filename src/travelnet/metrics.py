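"""Threshold-independent evaluation and cycle-stability summaries.

AUROC is computed in its Mann-Whitney rank form: the probability that a
randomly chosen positive sample receives a higher score than a randomly
chosen negative one, counting ties as 1/2.  The instability index summarises
how much a per-cycle AUROC series jitters between consecutive cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvalResult", "auroc", "instability_index", "best_cycle"]


@dataclass(frozen=True)
class EvalResult:
    """Pooled evaluation of a classifier on a labelled score set."""

    auroc: float
    mean_loss: float
    n_pos: int
    n_neg: int


class UndefinedAUROCError(ValueError):
    """Raised when the label set contains only one class."""


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via mid-ranks (Mann-Whitney U).

    Parameters
    ----------
    scores
        Real-valued disease scores; higher means more likely positive.
    labels
        Binary labels, 1 = positive.

    Returns
    -------
    float
        P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg).

    Raises
    ------
    UndefinedAUROCError
        If the labels are all positive or all negative.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError(
            f"AUROC undefined: {n_pos} positive and {n_neg} negative labels"
        )
    ranks = rankdata(s)  # mid-ranks handle ties at 1/2
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def instability_index(auroc_series: Sequence[float], window: int | None = None) -> float:
    """Standard deviation of successive differences over the last `window` cycles.

    Quantifies cycle-to-cycle variability of a training curve: 0 for a
    constant series (and for any series whose consecutive differences are all
    equal), growing as the curve oscillates.  Population convention (ddof=0).

    Parameters
    ----------
    auroc_series
        Per-cycle metric values, at least 2 of them.
    window
        Number of trailing values to use; defaults to the full series.
    """
    s = np.asarray(auroc_series, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if window is None:
        window = s.size
    if window > s.size:
        raise ValueError(f"window {window} exceeds series length {s.size}")
    if window < 2:
        raise ValueError("window must be >= 2")
    tail = s[-window:]
    diffs = np.diff(tail)
    return float(np.std(diffs))


def best_cycle(test_losses: Sequence[float]) -> int:
    """1-based index of the cycle with the lowest test loss; ties -> earliest."""
    losses = np.asarray(test_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("history is empty")
    return int(np.argmin(losses)) + 1
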