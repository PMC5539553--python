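"""Classifiers, leave-one-out cross-validation and the pipeline evaluator.

Accuracy is always estimated by leave-one-out cross-validation (LOO-CV):
one fold per trial, every trial serving as the test item exactly once.
Channel selection can either be nested inside each training fold (the
statistically sound default) or computed once on the full session
("paper-faithful" mode, which reproduces the global-ranking protocol at
the cost of selection leakage into the folds).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import fd
from .features import (BandDefinition, ar_features, band_power, csp_features,
                       csp_fit)
from .io import EpochSet
from .selection import (LabelledFeatureTable, rank_table, select_channels)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CVReport",
    "knn_predict",
    "lda_fit_predict",
    "loo_cv",
    "grid_search",
    "extract_feature_table",
    "pipeline_evaluate",
]

ChannelPolicy = Union[str, Tuple[str, int], None]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to use and how to condition the features.

    K-NN with K=1 is the default (odd K avoids voting ties); LDA uses a
    pooled covariance with optional shrinkage.  ``standardize`` z-scores
    every feature with training-fold statistics before classification,
    which matters for distance-based K-NN when feature scales differ.
    """

    kind: str = "knn"
    K: int = 1
    shrinkage: Optional[Union[float, str]] = None
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "lda"):
            raise ValueError("classifier kind must be 'knn' or 'lda'")
        if self.kind == "knn" and self.K < 1:
            raise ValueError("K must be >= 1")
        if isinstance(self.shrinkage, float) and self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")


@dataclass(frozen=True)
class CVReport:
    """LOO-CV outcome for one task / feature / channel configuration."""

    task: str
    feature_method: str
    channel_config: str
    accuracy: float
    n_folds: int
    chosen_params: Dict[str, object]
    per_fold: np.ndarray  # predicted label per fold
    labels: np.ndarray  # true label per fold

    def __post_init__(self) -> None:
        correct = float(np.mean(self.per_fold == self.labels))
        if abs(correct - self.accuracy) > 1e-12:
            raise ValueError("per-fold predictions do not reassemble the accuracy")


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def knn_predict(train_x: np.ndarray, train_y: np.ndarray, query: np.ndarray,
                K: int = 1) -> int:
    """Majority label among the K Euclidean-nearest training points.

    Voting ties break by the smaller mean neighbor distance, then by the
    lower class index.  Equidistant points at the neighborhood boundary are
    resolved by training order (stable sort).
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if K > train_x.shape[0]:
        raise ValueError("K exceeds the training-set size")
    dist = np.linalg.norm(train_x - np.asarray(query, dtype=float)[None, :], axis=1)
    nearest = np.argsort(dist, kind="stable")[:K]
    votes_y = train_y[nearest]
    votes_d = dist[nearest]
    classes = np.unique(votes_y)
    counts = np.array([(votes_y == c).sum() for c in classes])
    best = classes[counts == counts.max()]
    if best.size == 1:
        return int(best[0])
    mean_d = np.array([votes_d[votes_y == c].mean() for c in best])
    best = best[mean_d == mean_d.min()]
    return int(best.min())


def _make_lda(spec: ClassifierSpec, n_samples: int, n_features: int,
              priors: Sequence[float]) -> LinearDiscriminantAnalysis:
    shrinkage = spec.shrinkage
    if shrinkage is None and n_features >= n_samples - 2:
        logger.warning("ill-conditioned pooled covariance "
                       "(%d features, %d trials): falling back to shrinkage",
                       n_features, n_samples)
        shrinkage = "auto"
    if shrinkage in (None, 0, 0.0):
        return LinearDiscriminantAnalysis(solver="svd", priors=priors)
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                      priors=priors)


def lda_fit_predict(train_x: np.ndarray, train_y: np.ndarray, query: np.ndarray,
                    spec: Optional[ClassifierSpec] = None) -> int:
    """Linear discriminant with pooled covariance and equal class priors."""
    spec = spec or ClassifierSpec(kind="lda")
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    classes, counts = np.unique(train_y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("need at least 2 trials per class for LDA")
    priors = np.full(classes.size, 1.0 / classes.size)
    model = _make_lda(spec, train_x.shape[0], train_x.shape[1], priors)
    model.fit(train_x, train_y)
    return int(model.predict(np.atleast_2d(query))[0])


def _predict(spec: ClassifierSpec, train_x: np.ndarray, train_y: np.ndarray,
             query: np.ndarray) -> int:
    if spec.kind == "knn":
        return knn_predict(train_x, train_y, query, K=spec.K)
    return lda_fit_predict(train_x, train_y, query, spec)


def _standardize(train_x: np.ndarray, query: np.ndarray):
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (train_x - mu) / sd, (query - mu) / sd


# ---------------------------------------------------------------------------
# LOO-CV and grid search
# ---------------------------------------------------------------------------

def _parse_policy(policy: ChannelPolicy) -> Optional[Tuple[str, int]]:
    if policy in (None, "all"):
        return None
    if isinstance(policy, str):
        mode, _, num = policy.partition(":")
        if mode not in ("top", "worst") or not num.isdigit():
            raise ValueError(f"unrecognized channel policy: {policy!r}")
        return mode, int(num)
    mode, d = policy
    if mode not in ("top", "worst"):
        raise ValueError(f"unrecognized channel policy mode: {mode!r}")
    return mode, int(d)


def loo_cv(table: LabelledFeatureTable, spec: ClassifierSpec,
           selection: ChannelPolicy = None, task: str = "",
           feature_method: str = "") -> CVReport:
    """Leave-one-out cross-validation over a labelled feature table.

    With ``selection`` (e.g. ``('top', 5)``) the Fisher ranking and channel
    subset are recomputed on every training fold, so the held-out trial
    never influences its own channel configuration.  Standardization
    statistics are likewise training-fold only.
    """
    policy = _parse_policy(selection)
    X, y = table.values, table.labels
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for LOO-CV")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        query = X[i]
        if policy is not None:
            fold_table = LabelledFeatureTable(Xtr, ytr, table.channel_names,
                                              groups=table.groups)
            chans = select_channels(rank_table(fold_table), policy[1], policy[0])
            cols = np.isin(table.groups, chans)
            Xtr, query = Xtr[:, cols], query[cols]
        if spec.standardize:
            Xtr, query = _standardize(Xtr, query)
        preds[i] = _predict(spec, Xtr, ytr, query)
    accuracy = float(np.mean(preds == y))
    config = "all" if policy is None else f"{policy[0]}:{policy[1]} (nested)"
    return CVReport(task=task, feature_method=feature_method,
                    channel_config=config, accuracy=accuracy, n_folds=n,
                    chosen_params={"classifier": spec.kind,
                                   "K": spec.K if spec.kind == "knn" else None},
                    per_fold=preds, labels=y.copy())


def grid_search(candidates: Iterable, objective: Callable[[object], float]
                ) -> Tuple[object, Dict[object, float]]:
    """Evaluate every candidate; return the argmax and the full table.

    Ties in accuracy break toward the smaller parameter value.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty parameter grid")
    accuracies = {c: float(objective(c)) for c in candidates}
    best = max(sorted(accuracies), key=lambda c: accuracies[c])
    return best, accuracies


# ---------------------------------------------------------------------------
# feature extraction over sessions
# ---------------------------------------------------------------------------

def extract_feature_table(session: EpochSet, method: str, tau: int = 50,
                          epsilon: float = 1e-3, M_max: int = 50,
                          kmax: int = 100, band: Optional[BandDefinition] = None,
                          ar_order: int = 4, bp_method: str = "butter",
                          bp_log: bool = False,
                          max_vectors: Optional[int] = None) -> LabelledFeatureTable:
    """Per-channel feature table for a session (one row per trial).

    ``gpfd``/``hfd``/``bp`` give one column per channel, ``ar`` gives
    ``ar_order`` columns per channel (grouped for channel-level ranking).
    CSP is supervised and spatial, hence handled by the pipeline, not here.
    """
    data = session.data
    n, q, s = data.shape
    if method == "gpfd":
        flat = data.reshape(n * q, s)
        values = np.array([fd.gpfd(sig, tau=tau, epsilon=epsilon, M_max=M_max,
                                   max_vectors=max_vectors).fd
                           for sig in flat]).reshape(n, q)
        groups = None
    elif method == "hfd":
        values = fd.hfd_batch(data.reshape(n * q, s), kmax=kmax).reshape(n, q)
        groups = None
    elif method == "bp":
        if band is None:
            raise ValueError("band power requires a BandDefinition")
        values = np.stack([band_power(trial, band, session.fs, method=bp_method,
                                      log=bp_log) for trial in data])
        groups = None
    elif method == "ar":
        values = np.stack([ar_features(trial, ar_order) for trial in data])
        groups = np.repeat(np.arange(q), ar_order)
    else:
        raise ValueError(f"unknown feature method: {method!r}")
    return LabelledFeatureTable(values=values, labels=session.labels,
                                channel_names=tuple(session.channel_names),
                                groups=groups)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _csp_loo(session: EpochSet, band: Optional[BandDefinition], p: int,
             spec: ClassifierSpec, policy: Optional[Tuple[str, int]],
             paper_faithful: bool) -> np.ndarray:
    """LOO predictions for the CSP pipeline (CSP refit on every fold)."""
    def bp_table(sess: EpochSet) -> LabelledFeatureTable:
        sel_band = band or BandDefinition(8.0, 30.0, "broad")
        values = np.stack([band_power(trial, sel_band, sess.fs)
                           for trial in sess.data])
        return LabelledFeatureTable(values, sess.labels,
                                    tuple(sess.channel_names))

    if policy is not None and paper_faithful:
        chans = select_channels(rank_table(bp_table(session)), policy[1], policy[0])
        session = session.pick_channels(sorted(chans))
        policy = None

    n = session.n_trials
    y = session.labels
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = EpochSet(session.data[mask], session.fs,
                         list(session.channel_names), y[mask], session.task)
        if policy is not None:
            chans = select_channels(rank_table(bp_table(train)), policy[1], policy[0])
            train = train.pick_channels(sorted(chans))
            query_epoch = session.data[i][sorted(chans), :]
        else:
            query_epoch = session.data[i]
        a, b = train.class_split()
        model = csp_fit(a.data, b.data, band=band, fs=session.fs, p=p,
                        class_labels=(0, 1))
        Xtr = np.stack([csp_features(e, model) for e in train.data])
        query = csp_features(query_epoch, model)
        if spec.standardize:
            Xtr, query = _standardize(Xtr, query)
        preds[i] = _predict(spec, Xtr, train.labels, query)
    return preds


def pipeline_evaluate(session: EpochSet, feature_method: str = "gpfd",
                      channel_policy: ChannelPolicy = "all",
                      spec: Optional[ClassifierSpec] = None,
                      paper_faithful: bool = False,
                      csp_pairs: int = 2, **feature_params) -> CVReport:
    """Extract features, apply the channel policy, run LOO-CV.

    In the default nested mode any channel selection is refit inside each
    training fold; ``paper_faithful=True`` instead scores channels once on
    all trials before cross-validating, matching the global-ranking
    protocol.  CSP refuses single-channel configurations.
    """
    spec = spec or ClassifierSpec()
    policy = _parse_policy(channel_policy)
    if np.unique(session.labels).size != 2:
        raise ValueError("pipeline_evaluate expects a two-class session")

    if feature_method == "csp":
        if session.n_channels < 2 or (policy is not None and policy[1] < 2):
            raise ValueError("at least two channels are required for CSP")
        band = feature_params.get("band")
        preds = _csp_loo(session, band, csp_pairs, spec, policy, paper_faithful)
        config = ("all" if policy is None else
                  f"{policy[0]}:{policy[1]}" + ("" if paper_faithful else " (nested)"))
        return CVReport(task=session.task, feature_method="csp",
                        channel_config=config,
                        accuracy=float(np.mean(preds == session.labels)),
                        n_folds=session.n_trials,
                        chosen_params={"classifier": spec.kind, "p": csp_pairs,
                                       "band": getattr(band, "name", None)},
                        per_fold=preds, labels=session.labels.copy())

    table = extract_feature_table(session, feature_method, **feature_params)
    if policy is None:
        report = loo_cv(table, spec, selection=None, task=session.task,
                        feature_method=feature_method)
    elif paper_faithful:
        chans = sorted(select_channels(rank_table(table), policy[1], policy[0]))
        cols = np.isin(table.groups, chans)
        names = tuple(table.channel_names[c] for c in chans)
        groups = (np.repeat(np.arange(len(chans)), feature_params.get("ar_order", 4))
                  if feature_method == "ar" else None)
        sub = LabelledFeatureTable(table.values[:, cols], table.labels, names,
                                   groups=groups)
        report = loo_cv(sub, spec, selection=None, task=session.task,
                        feature_method=feature_method)
        report = dataclasses.replace(
            report, channel_config=f"{policy[0]}:{policy[1]} (global)")
    else:
        report = loo_cv(table, spec, selection=policy, task=session.task,
                        feature_method=feature_method)
    params = dict(report.chosen_params)
    params.update({k: v for k, v in feature_params.items() if not hasattr(v, "shape")})
    return dataclasses.replace(report, chosen_params=params)
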