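"""Evaluation metrics and cross-method rank statistics.

The ranking quality of a prioritizer is summarised by a threshold-rank
ROC: for rank cutoffs t = 0..T, sensitivity(t) is the percentage of
leave-one-out lists whose target gene ranks within the top t, and the
false-positive rate is the mean fraction of the 99 non-target
candidates ranked within the top t.  The partial curve is completed by
the chord from its last point to (1, 1) — the standard closure of a
truncated ROC — and the AUC is the trapezoidal area under the result.
This keeps the calibration anchors at every threshold: a perfect
ranker scores exactly 100%, a uniform-random ranker about 50%, and a
ranker that buries every target at the bottom scores 0 on the full
sweep.

Method comparison across diseases uses within-disease ranks: mean
ranks per method and the Friedman chi-square omnibus test (with tie
correction, chi-square approximation for the p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .prioritizer import RankList

INTERVAL_DECOYS = 99  # non-target candidates per leave-one-out list


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero; refusing to report a silent 0."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class ScoreTable:
    """Diseases × methods matrix of AUC values (percent)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("value matrix does not match the labels")
        if np.isnan(self.values).any():
            raise ValueError("score table has missing cells")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: score table has missing cells")
        return cls(list(df.index), list(df.columns), df.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def column_means(self) -> dict[str, float]:
        return {c: float(m) for c, m in zip(self.col_labels, self.values.mean(axis=0))}


def target_ranks(rank_lists: Sequence[RankList] | Sequence[int]) -> np.ndarray:
    ranks = np.array(
        [rl.target_rank if isinstance(rl, RankList) else int(rl) for rl in rank_lists]
    )
    if ranks.size == 0:
        raise ValueError("no rank lists given")
    if ranks.min() < 1 or ranks.max() > INTERVAL_DECOYS + 1:
        raise ValueError("target ranks must lie in 1..100")
    return ranks


def threshold_auc(
    rank_lists: Sequence[RankList] | Sequence[int],
    max_threshold: int,
    interval_size: int = INTERVAL_DECOYS + 1,
) -> float:
    """Threshold-rank ROC AUC over cutoffs 1..T, in percent.

    Accepts RankLists or bare target ranks.  The partial curve is
    closed by the chord to (1, 1).  All targets at rank 1 gives 100
    exactly; uniform-random ranks give ≈50 at any threshold; all
    targets at the bottom give 0 on the full sweep (T = 99).
    """
    if max_threshold < 1:
        raise ValueError("max_threshold must be >= 1")
    if max_threshold > interval_size - 1:
        raise ValueError(
            f"max_threshold {max_threshold} exceeds interval_size-1 = {interval_size - 1}"
        )
    ranks = target_ranks(rank_lists)
    decoys = interval_size - 1
    ts = np.arange(0, max_threshold + 1)
    hit = ranks[None, :] <= ts[:, None]  # (T+1, n_lists)
    sens = 100.0 * hit.mean(axis=1)
    fpr = ((ts[:, None] - hit) / decoys).mean(axis=1)
    if fpr[-1] < 1.0:
        fpr = np.append(fpr, 1.0)
        sens = np.append(sens, 100.0)
    return float(np.trapezoid(sens, fpr))


def confusion_at_threshold(
    rank_lists: Sequence[RankList] | Sequence[int],
    threshold: int,
    interval_size: int = INTERVAL_DECOYS + 1,
) -> ConfusionCounts:
    """Pool leave-one-out lists into one confusion matrix at a cutoff:
    each list contributes its target (positive) and the decoys
    (negatives); predicted-positive = ranked within the top t."""
    ranks = target_ranks(rank_lists)
    n = ranks.size
    tp = int((ranks <= threshold).sum())
    fn = n - tp
    fp = n * threshold - tp
    tn = n * (interval_size - 1) - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1), each in percent."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp = 0")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn = 0")
    p = 100.0 * counts.tp / (counts.tp + counts.fp)
    r = 100.0 * counts.tp / (counts.tp + counts.fn)
    if p + r == 0:
        return p, r, 0.0
    return p, r, 2 * p * r / (p + r)


def _row_ranks(table: ScoreTable, higher_is_better: bool) -> np.ndarray:
    v = table.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    signed = -v if higher_is_better else v
    return np.vstack([rankdata(row, method="average") for row in signed])


def friedman_mean_ranks(
    table: ScoreTable, higher_is_better: bool = True
) -> dict[str, float]:
    """Per-method mean within-row rank (1 = best); means sum to k(k+1)/2."""
    ranks = _row_ranks(table, higher_is_better)
    return {c: float(m) for c, m in zip(table.col_labels, ranks.mean(axis=0))}


def friedman_chi_square(
    table: ScoreTable, higher_is_better: bool = True
) -> tuple[float, int, float]:
    """Friedman omnibus statistic with tie correction.

    χ² = 12/(n·k·(k+1)) · Σ R_j² − 3n(k+1), divided by
    1 − Σ(t³−t)/(n·k·(k²−1)) when rows contain ties; p-value from the
    chi-square survival function with k−1 degrees of freedom.
    """
    ranks = _row_ranks(table, higher_is_better)
    n, k = ranks.shape
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(R**2)) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in table.values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if tie_sum > 0 and correction > 0:
        stat /= correction
    df = k - 1
    return stat, df, float(chi2.sf(stat, df))
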