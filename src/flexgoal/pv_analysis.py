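"""Population-vector correlation analyses and the correlation-based decoder.

The decoder correlates time-binned delay-period population vectors (PVs)
with per-class template PVs and predicts, per trial, either the class with
the highest bin-averaged correlation ('mean' mode) or the class winning the
most bins ('majority' mode).  Goal templates are the mean sample-phase
goal-arrival PVs; start templates are mean delay-period PVs excluding the
decoded trial's own contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    PVMatrix,
    Session,
    bin_aligned_counts,
    delay_windows,
    goal_arrival_windows,
    population_vector,
)

__all__ = [
    "CorrelationDecoderResult",
    "pv_correlation_matrix",
    "goal_template_pvs",
    "correlation_decode",
    "bootstrap_accuracy_ci",
    "goal_phase_cross_decoding",
    "DEFAULT_BINWIDTHS",
]

#: correlation-decoder binwidth grids (s) keyed by delay duration
DEFAULT_BINWIDTHS = {3.0: (0.375, 0.75, 1.5, 3.0), 3.2: (0.4, 0.8, 1.6, 3.2)}


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B.

    Zero-variance rows yield NaN entries (undefined correlation) rather
    than an arbitrary value.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the cell dimension")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac ** 2).sum(axis=1))
    sb = np.sqrt((Bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (Ac @ Bc.T) / np.outer(sa, sb)
    out[sa == 0, :] = np.nan
    out[:, sb == 0] = np.nan
    return out


def pv_correlation_matrix(A: PVMatrix, B: PVMatrix) -> np.ndarray:
    """Pearson correlations of all PV pairs; entry (i, j) = corr(A_i, B_j)."""
    if not np.array_equal(A.cell_ids, B.cell_ids):
        raise ValueError("PV matrices must use the same cells in the same order")
    return _row_corr(A.values, B.values)


def goal_template_pvs(
    session: Session,
    cells=None,
    window_duration: float = 3.0,
    correct_only: bool = True,
) -> np.ndarray:
    """(3, n_cells) mean sample-phase goal-arrival PVs, one template per goal."""
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    windows = goal_arrival_windows(trials, window_duration)
    pv = population_vector(session, windows, cells, window_name="goal_arrival")
    goals = trials.goals
    templates = np.empty((3, pv.values.shape[1]))
    for g in (1, 2, 3):
        rows = mask & (goals == g)
        if not rows.any():
            raise ValueError(f"no {'correct ' if correct_only else ''}trial with goal {g}")
        templates[g - 1] = pv.values[rows].mean(axis=0)
    return templates


@dataclass
class CorrelationDecoderResult:
    """Per-trial predictions and accuracies of the correlation decoder."""

    trial_indices: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    mode: str
    binwidth: float
    accuracy: float
    class_accuracy: dict
    ci: tuple[float, float]
    n_ties: int


def _decide(corr: np.ndarray, mode: str) -> tuple[int, bool]:
    """Winning class (1-based) from a (bins, 3) correlation table.

    NaN entries (undefined correlations, e.g. an all-zero bin PV) carry no
    weight: they are excluded from the 'mean' average and cast no 'majority'
    vote.  Ties break to the lowest class index.
    """
    if mode == "mean":
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
            scores = np.nanmean(corr, axis=0)
        scores = np.where(np.isnan(scores), -np.inf, scores)
    elif mode == "majority":
        votes = np.zeros(3)
        for row in corr:
            if np.all(np.isnan(row)):
                continue
            row = np.where(np.isnan(row), -np.inf, row)
            votes[int(np.argmax(row))] += 1
        scores = votes
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best = float(np.max(scores))
    tie = int(np.sum(scores == best)) > 1
    return int(np.argmax(scores)) + 1, tie


def correlation_decode(
    session: Session,
    target: str,
    binwidth: float,
    mode: str = "mean",
    cells=None,
    templates: np.ndarray | None = None,
    correct_only: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationDecoderResult:
    """Correlation-based classification of the delay period.

    Each decoded trial's delay is cut into ``binwidth`` bins (final partial
    bin dropped); each bin PV is correlated with the three class templates.
    ``target='goal'`` uses sample-phase goal-arrival templates;
    ``target='start'`` uses mean delay PVs per start with the decoded
    trial's own delay excluded from its templates.
    """
    trials = session.trial_table
    if cells is None:
        cells = [u.unit_id for u in session.units]
    units = session.units_by_ids(cells)
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    decode_idx = np.flatnonzero(mask)
    if target == "goal":
        labels = trials.goals
        if templates is None:
            templates = goal_template_pvs(session, cells, correct_only=correct_only)
    elif target == "start":
        labels = trials.starts
        delay_pv = population_vector(session, delay_windows(trials), cells).values
    else:
        raise ValueError("target must be 'goal' or 'start'")

    counts = bin_aligned_counts(units, trials.delay_on, (0.0, trials.delay_duration),
                                binwidth)
    bin_pvs = counts / binwidth  # (trials, cells, bins) -> rates

    preds = np.empty(decode_idx.size, dtype=int)
    n_ties = 0
    for k, i in enumerate(decode_idx):
        if target == "start":
            templates = np.empty((3, len(units)))
            for s in (1, 2, 3):
                rows = mask & (trials.starts == s)
                rows[i] = False  # exclude current trial's contribution
                if not rows.any():
                    raise ValueError(f"no template trial for start {s} excluding trial {i}")
                templates[s - 1] = delay_pv[rows].mean(axis=0)
        corr = _row_corr(bin_pvs[i].T, templates)  # (bins, 3)
        preds[k], tie = _decide(corr, mode)
        n_ties += int(tie)

    flags = preds == labels[decode_idx]
    class_acc = {}
    for c in (1, 2, 3):
        sel = labels[decode_idx] == c
        class_acc[c] = float(flags[sel].mean()) if sel.any() else np.nan
    ci = bootstrap_accuracy_ci(flags, n_boot=n_boot, seed=seed)
    return CorrelationDecoderResult(
        trial_indices=decode_idx, predictions=preds, labels=labels[decode_idx],
        mode=mode, binwidth=binwidth, accuracy=float(flags.mean()),
        class_accuracy=class_acc, ci=ci, n_ties=n_ties,
    )


def bootstrap_accuracy_ci(
    correct_flags, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of a mean of boolean flags.

    Draws ``n_boot`` resamples with replacement and returns the 2.5 and
    97.5 percentiles of the resampled means.
    """
    flags = np.asarray(correct_flags, dtype=float)
    if flags.size == 0:
        raise ValueError("need at least one flag")
    if not 1 <= n_boot:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    boot = rng.choice(flags, size=(n_boot, flags.size), replace=True).mean(axis=1)
    return float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))


def goal_phase_cross_decoding(
    session: Session,
    cells=None,
    window_duration: float = 3.0,
    correct_only: bool = True,
) -> dict:
    """Cross-task-phase goal decoding from goal-arrival PVs.

    Trains a logistic-regression goal classifier on one phase's goal-arrival
    PVs (sample: after ``t_sample_goal_arrival``; test: after
    ``t_test_goal_arrival``) and evaluates it on the other phase, both
    directions.  Returns mean-over-classes accuracies.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    if not mask.any():
        raise ValueError("no trials available for cross-phase decoding")
    goals = trials.goals[mask]
    sample_w = goal_arrival_windows(trials, window_duration)[mask]
    t_test = trials.field("t_test_goal_arrival")[mask]
    test_w = np.column_stack([t_test, t_test + window_duration])
    X_sample = population_vector(session, sample_w, cells).values
    X_test = population_vector(session, test_w, cells).values

    def _one_direction(Xtr, ytr, Xte, yte):
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        return float(np.mean([np.mean(pred[yte == c] == c)
                              for c in np.unique(yte)]))

    acc_s2t = _one_direction(X_sample, goals, X_test, goals)
    acc_t2s = _one_direction(X_test, goals, X_sample, goals)
    return {"sample_to_test": acc_s2t, "test_to_sample": acc_t2s,
            "mean": 0.5 * (acc_s2t + acc_t2s)}
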