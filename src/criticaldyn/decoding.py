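"""Excitability decoding from active, passive and combined iEEG features.

Three multinomial logistic-regression classifiers (L2-regularized, softmax
over K classes) discriminate the excitability condition of single trials:
the *active* classifier consumes the raw multi-channel voltage of the
250 ms post-pulse window without feature extraction; the *passive*
classifier consumes the five critical-slowing signatures of a 4 s
stimulation-free epoch per channel; the *combined* classifier concatenates
both.  Performance is assessed with stratified, session-grouped 5-fold
cross-validation and compared to a label-permutation null with
p = (C + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .signatures import (Epoch, autocorr_halfwidth, line_length, skewness,
                         spatial_correlation, variance)
from .synthetic import Recording

CLASS_ORDER = ("low", "normal", "high")
PASSIVE_FEATURE_NAMES = ("line_length", "variance", "skewness",
                         "autocorr_halfwidth")


@dataclass
class FeatureSet:
    kind: Literal["active", "passive", "combined"]
    X: NDArray[np.float64]  # trials x features
    labels: NDArray  # condition per trial
    feature_names: list[str]
    sessions: NDArray  # session id per trial

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("label count must match trial count")

    def subset_features(self, names: Sequence[str]) -> "FeatureSet":
        """Restrict to features whose name starts with any of ``names``."""
        idx = [i for i, n in enumerate(self.feature_names)
               if any(n.startswith(p) for p in names)]
        if not idx:
            raise ValueError(f"no features match {names}")
        return FeatureSet(self.kind, self.X[:, idx], self.labels,
                          [self.feature_names[i] for i in idx], self.sessions)


@dataclass
class ClassifierReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: NDArray[np.int64]  # K x K pooled counts, rows = true class
    classes: list[str]
    permutation_scores: list[float] = field(default_factory=list)
    p_value: float | None = None

    def class_counts(self, cls: str) -> dict[str, int]:
        """One-vs-rest TP/TN/FP/FN pooled over folds."""
        k = self.classes.index(cls)
        cm = self.confusion
        tp = int(cm[k, k])
        fp = int(cm[:, k].sum() - tp)
        fn = int(cm[k].sum() - tp)
        tn = int(cm.sum() - tp - fp - fn)
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (tp + tn) / (tp + tn + fp + fn)


def permutation_p_value(true_score: float, null_scores: Sequence[float]) -> float:
    """p = (C + 1) / (n_perm + 1), C = permutations scoring >= the truth."""
    null = np.asarray(null_scores, dtype=float)
    c = int((null >= true_score).sum())
    return (c + 1) / (null.size + 1)


# ---------------------------------------------------------------------------
# feature construction


def build_active_features(
    recordings: Sequence[Recording], window_ms: float = 250.0,
) -> FeatureSet:
    """Raw post-stimulus multi-channel voltage, one trial per pulse.

    Features are the concatenated [0, window] ms samples of every channel
    (no feature extraction); standardization happens inside the classifier
    pipeline, fitted on training folds only.
    """
    n_ch = recordings[0].n_channels
    rows, labels, sessions = [], [], []
    for s_idx, rec in enumerate(recordings):
        if rec.n_channels != n_ch:
            raise ValueError("channel counts differ across sessions")
        sf = rec.sampling_rate_hz
        ns = int(round(window_ms / 1000.0 * sf))
        for e in rec.events:
            i0 = int(round(e.onset_s * sf))
            if i0 + ns > rec.signal.shape[1]:
                continue
            rows.append(rec.signal[:, i0 : i0 + ns].ravel())
            labels.append(rec.condition)
            sessions.append(s_idx)
    names = [f"ch{c}_t{i}" for c in range(n_ch)
             for i in range(len(rows[0]) // n_ch)]
    return FeatureSet("active", np.array(rows), np.array(labels), names,
                      np.array(sessions))


def build_passive_features(
    recordings: Sequence[Recording], epoch_s: float = 4.0,
    min_gap_s: float = 2.0,
) -> FeatureSet:
    """Per-trial passive signatures: 4 per channel plus mean spatial r.

    Each trial is the stimulation-free epoch preceding one pulse (the
    window ending ``min_gap_s`` before the onset); trials whose epoch would
    leave the recording are dropped.
    """
    n_ch = recordings[0].n_channels
    rows, labels, sessions = [], [], []
    for s_idx, rec in enumerate(recordings):
        sf = rec.sampling_rate_hz
        ns = int(round(epoch_s * sf))
        gap = int(round(min_gap_s * sf))
        for e in rec.events:
            i1 = int(round(e.onset_s * sf)) - gap
            i0 = i1 - ns
            if i0 < 0:
                continue
            window = rec.signal[:, i0:i1]
            feats = []
            try:
                for c in range(n_ch):
                    ep = Epoch(window[c], sf)
                    feats += [line_length(ep), variance(ep), skewness(ep),
                              autocorr_halfwidth(ep)]
                feats.append(spatial_correlation(window))
            except ValueError:
                continue  # degenerate epoch; drop trial
            rows.append(feats)
            labels.append(rec.condition)
            sessions.append(s_idx)
    names = [f"{f}_ch{c}" for c in range(n_ch) for f in PASSIVE_FEATURE_NAMES]
    names.append("spatial_correlation")
    return FeatureSet("passive", np.array(rows), np.array(labels), names,
                      np.array(sessions))


def build_combined_features(
    recordings: Sequence[Recording], **kwargs
) -> FeatureSet:
    """Active ++ passive features on the intersection of valid trials."""
    act = build_active_features(recordings)
    pas = build_passive_features(recordings, **kwargs)
    # align by (session, trial order): passive drops early trials; match by
    # greedy pairing within session
    rows, labels, sessions = [], [], []
    for s in np.unique(act.sessions):
        ia = np.flatnonzero(act.sessions == s)
        ip = np.flatnonzero(pas.sessions == s)
        n = min(ia.size, ip.size)
        # passive keeps the *last* n trials of the session
        for a, p in zip(ia[-n:], ip[-n:]):
            rows.append(np.concatenate([act.X[a], pas.X[p]]))
            labels.append(act.labels[a])
            sessions.append(s)
    names = act.feature_names + pas.feature_names
    return FeatureSet("combined", np.array(rows), np.array(labels), names,
                      np.array(sessions))


# ---------------------------------------------------------------------------
# training and evaluation


def _make_model(l2: float) -> object:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=l2, max_iter=2000),  # L2 penalty (default)
    )


def train_crossvalidated(
    features: FeatureSet,
    n_folds: int = 5,
    l2: float = 1.0,
    seed: int = 0,
    group_by_session: bool = True,
    labels: NDArray | None = None,
) -> ClassifierReport:
    """Stratified (and session-grouped) K-fold CV of the softmax classifier.

    Grouping prevents trials of one session from straddling the train/test
    split; ``labels`` overrides the stored labels (for permutations).
    """
    y = features.labels if labels is None else np.asarray(labels)
    classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(y))
    class_idx = {c: i for i, c in enumerate(classes)}
    X = features.X
    if group_by_session and len(np.unique(features.sessions)) >= n_folds:
        cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed)
        splits = cv.split(X, y, groups=features.sessions)
    else:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = cv.split(X, y)
    fold_acc = []
    K = len(classes)
    cm = np.zeros((K, K), dtype=np.int64)
    for train, test in splits:
        if len(set(y[train])) < K:
            raise ValueError("a class is absent from a training fold; "
                             "use more sessions or fewer folds")
        model = _make_model(l2)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        for yt, yp in zip(y[test], pred):
            cm[class_idx[yt], class_idx[yp]] += 1
    return ClassifierReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.trace(cm) / cm.sum()),
        confusion=cm, classes=classes,
    )


def permutation_test(
    features: FeatureSet,
    n_perm: int = 100,
    seed: int = 0,
    session_level: bool = True,
    **cv_kwargs,
) -> ClassifierReport:
    """Label-permutation null for the cross-validated accuracy.

    Permutations shuffle labels at the session level by default (all trials
    of a session swap condition together, respecting the grouped CV);
    ``session_level=False`` permutes trial-wise.
    """
    report = train_crossvalidated(features, seed=seed, **cv_kwargs)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        if session_level:
            sess = np.unique(features.sessions)
            sess_label = {s: features.labels[features.sessions == s][0]
                          for s in sess}
            perm = rng.permutation([sess_label[s] for s in sess])
            mapping = dict(zip(sess, perm))
            y = np.array([mapping[s] for s in features.sessions])
        else:
            y = rng.permutation(features.labels)
        r = train_crossvalidated(features, seed=seed, labels=y, **cv_kwargs)
        null.append(r.mean_accuracy)
    report.permutation_scores = null
    report.p_value = permutation_p_value(report.mean_accuracy, null)
    return report


def timepoint_decoding(
    recordings: Sequence[Recording],
    window_ms: tuple[float, float] = (-100.0, 250.0),
    step_ms: float = 10.0,
    n_folds: int = 5,
    l2: float = 1.0,
    seed: int = 0,
    n_perm: int = 20,
) -> "TimepointDecodingResult":
    """One classifier per peri-stimulus timepoint (features = that sample
    across channels), with a permutation chance band per timepoint."""
    sf = recordings[0].sampling_rate_hz
    n_ch = recordings[0].n_channels
    t_grid = np.arange(window_ms[0], window_ms[1], step_ms)
    rows, labels, sessions = [], [], []
    for s_idx, rec in enumerate(recordings):
        for e in rec.events:
            i0 = int(round(e.onset_s * sf))
            idx = (i0 + np.round(t_grid / 1000.0 * sf)).astype(int)
            if idx[0] < 0 or idx[-1] >= rec.signal.shape[1]:
                continue
            rows.append(rec.signal[:, idx])  # n_ch x n_t
            labels.append(rec.condition)
            sessions.append(s_idx)
    cube = np.array(rows)  # trials x channels x timepoints
    labels_a, sessions_a = np.array(labels), np.array(sessions)
    acc = np.empty(t_grid.size)
    band_hi = np.empty(t_grid.size)
    rng = np.random.default_rng(seed)
    for ti in range(t_grid.size):
        fs = FeatureSet("active", cube[:, :, ti], labels_a,
                        [f"ch{c}" for c in range(n_ch)], sessions_a)
        rep = train_crossvalidated(fs, n_folds=n_folds, l2=l2, seed=seed)
        acc[ti] = rep.mean_accuracy
        null = []
        for _ in range(n_perm):
            y = rng.permutation(labels_a)
            null.append(train_crossvalidated(fs, n_folds=n_folds, l2=l2,
                                             seed=seed, labels=y).mean_accuracy)
        band_hi[ti] = float(np.percentile(null, 95))
    return TimepointDecodingResult(t_grid, acc, band_hi)


@dataclass
class TimepointDecodingResult:
    time_ms: NDArray[np.float64]
    accuracy: NDArray[np.float64]
    chance_band_95: NDArray[np.float64]
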