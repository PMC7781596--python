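"""Supervised population decoding: features, balanced LOO-CV, classifiers.

All classification uses leave-one-out cross-validation with per-fold class
balancing (training classes subsampled to the minimum class count).  Each
cell x time-bin is one feature; features are standardized over all trials by
default (with a strict per-fold alternative).  Four fixed classifier
bundles are provided: L2 logistic regression, Gaussian-kernel SVM
(gamma = 0.001), a 1000-tree random forest considering all features per
split, and Gaussian naive Bayes on the top 10% of features by
Kruskal-Wallis H score (selected within each training fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .core_model import Session, bin_aligned_counts
from .pv_analysis import bootstrap_accuracy_ci
from .single_cell_stats import class_labels, kruskal_wallis_h_matrix

__all__ = [
    "FeatureTensor",
    "DecodingResult",
    "ClassifierSpec",
    "classifier_specs",
    "build_features",
    "loo_cv",
    "nine_class_decoding",
    "time_resolved_decoding",
    "outcome_decoding",
    "ALIGNMENT_EVENTS",
]

#: the five task events time-resolved decoding can align to
ALIGNMENT_EVENTS = {
    "sample_goal_arrival": "t_sample_goal_arrival",
    "center_arrival": "t_center_arrival",
    "delay_on": "t_delay_on",
    "route_available": "t_delay_off",
    "choice_entry": "t_choice_entry",
    "test_goal_arrival": "t_test_goal_arrival",
}


@dataclass(frozen=True)
class FeatureTensor:
    """Trials x (cells * bins) feature matrix with labels and scaling record."""

    X: np.ndarray
    feature_cells: np.ndarray
    feature_bins: np.ndarray
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scoring; zero-variance columns are set to all-zero."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return Z, mean, sd


def build_features(
    session: Session,
    events: np.ndarray,
    window: tuple[float, float],
    binwidth: float,
    cells=None,
    standardize: bool = True,
) -> FeatureTensor:
    """Concatenated per-bin spike counts for event-aligned windows.

    Dimensionality is n_cells * n_bins; bins are referenced to the window
    start.  With ``standardize`` each feature is z-scored over trials
    (zero-variance features become all-zero).
    """
    if cells is None:
        units = session.units
        cell_ids = session.cell_ids
    else:
        units = session.units_by_ids(cells)
        cell_ids = np.asarray(cells)
    counts = bin_aligned_counts(units, np.asarray(events, float), window, binwidth)
    n_trials, n_cells, n_bins = counts.shape
    X = counts.reshape(n_trials, n_cells * n_bins).astype(float)
    feature_cells = np.repeat(cell_ids, n_bins)
    feature_bins = np.tile(np.arange(n_bins), n_cells)
    mean = sd = None
    if standardize:
        X, mean, sd = standardize_columns(X)
    return FeatureTensor(X=X, feature_cells=feature_cells,
                         feature_bins=feature_bins, mean=mean, sd=sd)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named, fixed hyperparameter bundle."""

    name: str
    params: dict = dataclass_field(default_factory=dict)
    nb_top_frac: float = 0.10  # NB only: fraction of features kept by H score

    def make(self):
        if self.name == "lr":
            # L2 regularization (sklearn default) with C=1
            return LogisticRegression(C=1.0, max_iter=2000, **self.params)
        if self.name == "svm":
            return SVC(kernel="rbf", gamma=0.001, C=1.0, **self.params)
        if self.name == "rf":
            # all features considered at each split; n_estimators overridable
            params = {"n_estimators": 1000, "max_features": None,
                      "random_state": 0, **self.params}
            return RandomForestClassifier(**params)
        if self.name == "nb":
            return GaussianNB(**self.params)
        raise ValueError(f"unknown classifier {self.name!r}")

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params),
                "nb_top_frac": self.nb_top_frac}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(name=d["name"], params=dict(d.get("params", {})),
                   nb_top_frac=d.get("nb_top_frac", 0.10))


def classifier_specs(**overrides) -> dict[str, ClassifierSpec]:
    """The four fixed classifier bundles keyed by short name."""
    specs = {name: ClassifierSpec(name=name, params=dict(overrides.get(name, {})))
             for name in ("lr", "svm", "rf", "nb")}
    return specs


@dataclass
class DecodingResult:
    """LOO-CV decoding outcome: predictions, confusion, class-mean accuracy."""

    trial_indices: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    confusion: pd.DataFrame
    accuracy: float          # mean of per-class accuracies
    class_accuracy: dict
    ci: tuple[float, float]
    spec: dict


def _class_mean_accuracy(labels, flags) -> tuple[float, dict]:
    class_acc = {}
    for c in np.unique(labels):
        sel = labels == c
        class_acc[int(c) if np.issubdtype(type(c), np.integer) else c] = \
            float(flags[sel].mean())
    return float(np.mean(list(class_acc.values()))), class_acc


def _bootstrap_class_mean(labels, flags, n_boot: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = labels.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        lb, fb = labels[idx], flags[idx]
        accs = [fb[lb == c].mean() for c in np.unique(lb)]
        vals[b] = np.mean(accs)
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def _balance(y_train: np.ndarray, rng, groups: np.ndarray | None = None) -> np.ndarray:
    """Indices of a training subset with equal class counts (subsampling).

    With ``groups`` (a nuisance factor crossed with the decoded label, e.g.
    the start when decoding the goal), counts are equalized per
    (group, class) cell instead.  This removes the label-nuisance
    association a leave-one-out fold otherwise induces: deleting the test
    trial leaves its own label under-represented *within its nuisance
    group*, which drives nuisance-keyed classifiers systematically below
    chance on null data.  Classes stay exactly balanced either way.
    """
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("degenerate training set: single class")
    strata = ([(g, c) for g in np.unique(groups) for c in classes]
              if groups is not None else [(None, c) for c in classes])
    sel = [(np.ones(y_train.size, bool) if g is None else groups == g) & (y_train == c)
           for g, c in strata]
    m = min(int(s.sum()) for s in sel)
    if m < 1:
        raise ValueError("empty (group, class) cell in training fold")
    keep = []
    for s in sel:
        idx = np.flatnonzero(s)
        if idx.size > m:
            idx = rng.choice(idx, size=m, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def loo_cv(
    features: FeatureTensor | np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
    standardization: str = "global",
    n_boot: int = 1000,
    trial_indices: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-out cross-validation with per-fold class balancing.

    ``standardization='global'`` assumes features were already z-scored over
    all trials (the default, matching how the features are built);
    ``'per_fold'`` re-standardizes within each training fold (strictly
    leakage-free) and applies those parameters to the held-out trial.
    NB feature selection is always computed within the training fold.
    ``groups`` stratifies the balancing by a crossed nuisance factor (see
    ``_balance``).
    """
    X = features.X if isinstance(features, FeatureTensor) else np.asarray(features, float)
    y = np.asarray(labels)
    n = X.shape[0]
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes")
    if standardization not in ("global", "per_fold"):
        raise ValueError("standardization must be 'global' or 'per_fold'")

    g = np.asarray(groups) if groups is not None else None
    if g is not None:
        # Stratification needs every (group, class) cell populated in every
        # training fold, i.e. >= 2 trials per cell overall (one may be held
        # out).  Small sessions can miss this; fall back to plain balancing.
        cells = list(zip(g.tolist(), y.tolist()))
        if min(cells.count(c) for c in set(cells)) < 2:
            warnings.warn("too few trials per (group, class) cell; "
                          "falling back to unstratified class balancing")
            g = None
    fold_seeds = SeedSequence(seed).spawn(n)
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        rng = default_rng(fold_seeds[i])
        train = np.delete(np.arange(n), i)
        keep = _balance(y[train], rng, g[train] if g is not None else None)
        tr = train[keep]
        Xtr, ytr, Xte = X[tr], y[tr], X[i:i + 1]
        if standardization == "per_fold":
            Xtr, mean, sd = standardize_columns(Xtr)
            Xte = np.where(sd > 0, (Xte - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        if spec.name == "nb":
            H, _ = kruskal_wallis_h_matrix(Xtr, ytr)
            k = max(1, int(round(spec.nb_top_frac * Xtr.shape[1])))
            top = np.argsort(H)[::-1][:k]
            Xtr, Xte = Xtr[:, top], Xte[:, top]
        est = spec.make()
        est.fit(Xtr, ytr)
        preds[i] = est.predict(Xte)[0]

    flags = preds == y
    acc, class_acc = _class_mean_accuracy(y, flags)
    ci = _bootstrap_class_mean(y, flags, n_boot, seed + 1)
    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for yt, yp in zip(y, preds):
        conf.loc[yt, yp] += 1
    if trial_indices is None:
        trial_indices = np.arange(n)
    return DecodingResult(trial_indices=np.asarray(trial_indices),
                          predictions=preds, labels=y, confusion=conf,
                          accuracy=acc, class_accuracy=class_acc, ci=ci,
                          spec=spec.to_dict())


def _nuisance_groups(trials, target: str, mask: np.ndarray) -> np.ndarray | None:
    """Crossed nuisance factor for a 3-class scheme, or None.

    In the balanced design the start is crossed with the goal, so goal (and
    ego, which is a goal rotation) decoding stratifies by start and start
    decoding stratifies by goal.
    """
    if target in ("goal", "ego"):
        return trials.starts[mask]
    if target == "start":
        return trials.goals[mask]
    return None


def delay_decoding(
    session: Session,
    target: str,
    binwidth: float,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    correct_only: bool = True,
    standardization: str = "global",
    cells=None,
) -> DecodingResult:
    """Delay-period decoding of a 3-class scheme (start/goal/ego) or 9-class.

    For the 3-class schemes the per-fold balancing is stratified by the
    crossed nuisance factor of the task design (the start when decoding the
    goal and vice versa), which keeps nuisance-keyed classifiers calibrated
    at chance on goal-free data (see ``_balance``).
    """
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    labels = class_labels(trials, target,
                          int(session.meta.get("ego_offset", 0)))[mask]
    feats = build_features(session, trials.delay_on[mask],
                           (0.0, trials.delay_duration), binwidth,
                           cells=cells, standardize=(standardization == "global"))
    return loo_cv(feats, labels, spec or ClassifierSpec("lr"), seed=seed,
                  standardization=standardization,
                  trial_indices=np.flatnonzero(mask),
                  groups=_nuisance_groups(trials, target, mask))


def nine_class_decoding(
    session: Session,
    binwidth: float,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    correct_only: bool = True,
) -> DecodingResult:
    """Nine-class (start x goal) delay decoding with its 9 x 9 confusion matrix.

    With start coding only, confusion mass concentrates in the 3 x 3
    same-start blocks; conjunctive coding makes the diagonal dominant.
    """
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    labels = class_labels(trials, "start_x_goal")[mask]
    present = np.unique(labels)
    if present.size < 9:
        missing = sorted(set(range(1, 10)) - set(present.tolist()))
        raise ValueError(f"missing start x goal combinations: {missing}")
    feats = build_features(session, trials.delay_on[mask],
                           (0.0, trials.delay_duration), binwidth)
    return loo_cv(feats, labels, spec or ClassifierSpec("svm"), seed=seed,
                  trial_indices=np.flatnonzero(mask))


def _tracking_features(session: Session, window_starts: np.ndarray,
                       window: float, fs_grid: float = 30.0) -> np.ndarray:
    """Raw two-LED coordinates plus heading (sin, cos) sampled within windows."""
    tr = session.tracking
    if tr is None:
        raise ValueError("session has no tracking data")
    t = tr.t
    n_pts = max(2, int(round(window * fs_grid)))
    offs = np.linspace(0.0, window, n_pts)
    feats = []
    for t0 in window_starts:
        ts = t0 + offs
        cols = []
        for arr in (tr.led1_xy, tr.led2_xy):
            cols.append(np.interp(ts, t, arr[:, 0]))
            cols.append(np.interp(ts, t, arr[:, 1]))
        d = tr.led1_xy - tr.led2_xy
        ang = np.arctan2(np.interp(ts, t, d[:, 1]), np.interp(ts, t, d[:, 0]))
        cols.extend([np.sin(ang), np.cos(ang)])
        feats.append(np.concatenate(cols))
    return np.asarray(feats)


def time_resolved_decoding(
    session: Session,
    source: str,
    alignment: str,
    target: str,
    t_range: tuple[float, float] = (-3.0, 3.0),
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    correct_only: bool = True,
    n_boot: int = 500,
) -> pd.DataFrame:
    """Sliding-window decoding from neural or tracking data around a task event.

    Neural windows are 800 ms (200 ms bins) stepped by 200 ms; tracking
    windows are 330 ms stepped by 100 ms, with the two LEDs' coordinates and
    the heading angle as features.  Returns a tidy frame of window centers,
    class-mean accuracy and bootstrap CI.  Windows exceeding the recording
    are dropped.
    """
    if source == "neural":
        window, binwidth, step = 0.8, 0.2, 0.2
    elif source == "tracking":
        window, binwidth, step = 0.33, None, 0.1
    else:
        raise ValueError("source must be 'neural' or 'tracking'")
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    events = trials.field(ALIGNMENT_EVENTS[alignment])[mask]
    labels = class_labels(trials, target,
                          int(session.meta.get("ego_offset", 0)))[mask]
    duration = session.recording_duration()
    spec = spec or ClassifierSpec("lr")

    t0s = np.arange(t_range[0], t_range[1] - window + 1e-9, step)
    rows = []
    for k, t0 in enumerate(t0s):
        starts = events + t0
        if starts.min() < 0 or (starts + window).max() > duration:
            continue
        if source == "neural":
            feats = build_features(session, starts, (0.0, window), binwidth)
            X = feats.X
        else:
            X, _, _ = standardize_columns(_tracking_features(session, starts, window))
        res = loo_cv(X, labels, spec, seed=seed + k, n_boot=n_boot,
                     groups=_nuisance_groups(trials, target, mask))
        rows.append({"t_center": t0 + window / 2, "accuracy": res.accuracy,
                     "ci_low": res.ci[0], "ci_high": res.ci[1]})
    return pd.DataFrame(rows)


def outcome_decoding(
    session: Session,
    target: str,
    binwidth: float = 0.75,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    inbound_sample: np.ndarray | None = None,
    inbound_test: np.ndarray | None = None,
    center_window: float = 1.0,
    test_return_latency: float = 2.0,
) -> DecodingResult:
    """Outcome / task-phase decoding.

    ``upcoming_error``: delay activity vs correctness of the same trial.
    ``past_error``: delay activity vs correctness of the previous trial.
    ``task_phase_at_center``: activity after arriving at the center,
    sample-phase vs test-phase; when per-trial inbound bridges are supplied,
    only trials where the same bridge was taken back to center in both
    phases are compared (removing the arrival-direction confound).  The
    test-phase center arrival is approximated as ``t_test_goal_arrival +
    test_return_latency``.
    """
    trials = session.trial_table
    spec = spec or ClassifierSpec("lr")
    if target == "upcoming_error":
        labels = np.where(trials.correct, "correct", "error")
        feats = build_features(session, trials.delay_on,
                               (0.0, trials.delay_duration), binwidth)
        keep = np.ones(len(trials), bool)
        X, y = feats.X, labels
        idx = np.flatnonzero(keep)
    elif target == "past_error":
        labels = np.where(trials.correct[:-1], "correct", "error")
        feats = build_features(session, trials.delay_on[1:],
                               (0.0, trials.delay_duration), binwidth)
        X, y = feats.X, labels
        idx = np.arange(1, len(trials))
    elif target == "task_phase_at_center":
        keep = np.ones(len(trials), bool)
        if inbound_sample is not None and inbound_test is not None:
            keep = np.asarray(inbound_sample) == np.asarray(inbound_test)
        if not keep.any():
            raise ValueError("no trials left after inbound-bridge matching")
        t_sample = trials.field("t_center_arrival")[keep]
        t_test = (trials.field("t_test_goal_arrival") + test_return_latency)[keep]
        duration = session.recording_duration()
        ok = t_test + center_window <= duration
        events = np.concatenate([t_sample, t_test[ok]])
        y = np.asarray(["sample"] * t_sample.size + ["test"] * int(ok.sum()))
        feats = build_features(session, events, (0.0, center_window), binwidth)
        X = feats.X
        idx = np.arange(events.size)
    else:
        raise ValueError(f"unknown target {target!r}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError(f"need >= 2 trials per outcome class, got {dict(zip(classes, counts))}")
    return loo_cv(X, y, spec, seed=seed, trial_indices=idx)
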