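"""Fisher's-criterion feature scoring and channel selection.

Each channel contributes one (or more) feature columns; the Fisher score
of a column is the ratio of its between-class scatter to its within-class
scatter, F(f) = S_b(f) / S_w(f).  Channels are ranked by descending score
and the top-d (most discriminative) or worst-d (least discriminative)
subset selected.  Only the scatter diagonals are needed for the ranking;
the score is invariant to per-column affine rescaling of the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "LabelledFeatureTable",
    "FisherRanking",
    "scatter_diagonals",
    "fisher_scores",
    "select_channels",
    "rank_table",
    "write_ranking",
]

#: Floor applied to the within-class scatter before division.
DEFAULT_GUARD = 1e-12


@dataclass(frozen=True)
class LabelledFeatureTable:
    """Trials x features matrix with binary class labels.

    ``groups`` maps each column to a channel index so multi-column features
    (e.g. AR coefficients) can be ranked per channel; scalar per-channel
    features use the identity mapping.
    """

    values: np.ndarray  # (n_trials, q)
    labels: np.ndarray  # (n_trials,)
    channel_names: Tuple[str, ...]
    groups: Optional[np.ndarray] = None  # (q,) column -> channel index

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if values.shape[0] != labels.size:
            raise ValueError("labels length does not match trial count")
        if values.shape[1] < 1:
            raise ValueError("need at least one feature column")
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        if np.any(counts < 2):
            raise ValueError("each class needs at least 2 trials")
        if self.groups is None:
            if len(self.channel_names) != values.shape[1]:
                raise ValueError("channel_names must match columns when groups is None")
            object.__setattr__(self, "groups", np.arange(values.shape[1]))
        else:
            groups = np.asarray(self.groups, dtype=int)
            if groups.shape != (values.shape[1],):
                raise ValueError("groups must map every column to a channel")
            object.__setattr__(self, "groups", groups)

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FisherRanking:
    """Per-column Fisher scores, descending order, and scatter diagonals."""

    scores: np.ndarray
    order: np.ndarray  # column indices sorted by descending score
    sw_diag: np.ndarray
    sb_diag: np.ndarray
    channel_names: Tuple[str, ...] = ()


def scatter_diagonals(table: LabelledFeatureTable) -> Tuple[np.ndarray, np.ndarray]:
    """Diagonals of the within- and between-class scatter matrices.

    S_w(f) = sum_i P_i * (1/n_i) sum_j (x_ijf - m_if)^2 (population
    variances) and S_b(f) = sum_i P_i (m_if - m_f)^2 with class priors
    P_i = n_i / n.  Both are translation invariant and scale with the
    square of any per-column rescaling.
    """
    X, y = table.values, table.labels
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / counts.sum()
    grand_mean = np.zeros(X.shape[1])
    class_means = []
    for c, P in zip(classes, priors):
        m = X[y == c].mean(axis=0)
        class_means.append(m)
        grand_mean += P * m
    sw = np.zeros(X.shape[1])
    sb = np.zeros(X.shape[1])
    for c, P, m in zip(classes, priors, class_means):
        sw += P * ((X[y == c] - m) ** 2).mean(axis=0)
        sb += P * (m - grand_mean) ** 2
    return sw, sb


def fisher_scores(sw_diag: np.ndarray, sb_diag: np.ndarray,
                  guard: float = DEFAULT_GUARD,
                  channel_names: Sequence[str] = ()) -> FisherRanking:
    """Fisher scores F(f) = S_b(f) / max(S_w(f), guard), descending order.

    The guard floors a vanishing within-class scatter instead of emitting
    infinities; ties in the ranking break by ascending column index (the
    sort is stable on the negated scores).
    """
    sw = np.asarray(sw_diag, dtype=float)
    sb = np.asarray(sb_diag, dtype=float)
    if sw.shape != sb.shape:
        raise ValueError("scatter diagonals must have the same length")
    if guard <= 0:
        raise ValueError("guard must be positive")
    scores = sb / np.maximum(sw, guard)
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(scores=scores, order=order, sw_diag=sw, sb_diag=sb,
                         channel_names=tuple(channel_names))


def rank_table(table: LabelledFeatureTable, guard: float = DEFAULT_GUARD) -> FisherRanking:
    """Fisher ranking of a feature table, aggregated per channel.

    For scalar per-channel features this is the column ranking.  When a
    channel owns several columns (AR coefficients) its score is the mean
    of its column scores, so the ranking stays one-per-channel.
    """
    sw, sb = scatter_diagonals(table)
    col_ranking = fisher_scores(sw, sb, guard=guard)
    groups = table.groups
    n_ch = len(table.channel_names)
    if groups.size == n_ch and np.array_equal(np.sort(groups), np.arange(n_ch)):
        # scalar features: reorder per channel directly
        scores = np.empty(n_ch)
        scores[groups] = col_ranking.scores
        sw_ch = np.empty(n_ch)
        sw_ch[groups] = sw
        sb_ch = np.empty(n_ch)
        sb_ch[groups] = sb
    else:
        scores = np.array([col_ranking.scores[groups == ch].mean()
                           for ch in range(n_ch)])
        sw_ch = np.array([sw[groups == ch].mean() for ch in range(n_ch)])
        sb_ch = np.array([sb[groups == ch].mean() for ch in range(n_ch)])
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(scores=scores, order=order, sw_diag=sw_ch, sb_diag=sb_ch,
                         channel_names=table.channel_names)


def select_channels(ranking: FisherRanking, d: int, mode: str = "top") -> np.ndarray:
    """Indices of the d best- or worst-scoring channels, score-ordered.

    ``mode='top'`` returns the d highest scores in descending order;
    ``mode='worst'`` the d lowest in ascending order.  Whenever 2d <= q the
    two subsets are disjoint.
    """
    q = ranking.scores.size
    if not 1 <= d <= q:
        raise ValueError(f"invalid d={d}: require 1 <= d <= {q}")
    if mode == "top":
        return ranking.order[:d].copy()
    if mode == "worst":
        return ranking.order[::-1][:d].copy()
    raise ValueError(f"unknown selection mode: {mode!r}")


def write_ranking(ranking: FisherRanking, path: Union[str, Path]) -> None:
    """Write a (channel, score, rank) table as tab-delimited text."""
    names = ranking.channel_names or tuple(
        f"CH{i}" for i in range(ranking.scores.size))
    rank_of = np.empty(ranking.scores.size, dtype=int)
    rank_of[ranking.order] = np.arange(1, ranking.scores.size + 1)
    frame = pd.DataFrame({
        "channel": list(names),
        "score": ranking.scores,
        "rank": rank_of,
    })
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
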