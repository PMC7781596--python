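"""Behavioral metrics: performance summaries, VTE screening, search times."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import Session, TrackingData, TrialTable
from .pv_analysis import bootstrap_accuracy_ci

__all__ = ["performance_summary", "detect_vte", "search_time_summary"]


def _split_row(label: str, flags: np.ndarray, n_boot: int, seed: int) -> dict:
    if flags.size == 0:
        return {"split": label, "n": 0, "accuracy": np.nan,
                "ci_low": np.nan, "ci_high": np.nan}
    lo, hi = bootstrap_accuracy_ci(flags, n_boot=n_boot, seed=seed)
    return {"split": label, "n": int(flags.size),
            "accuracy": float(flags.mean()), "ci_low": lo, "ci_high": hi}


def performance_summary(trials: TrialTable, n_boot: int = 2000,
                        seed: int = 0) -> pd.DataFrame:
    """Test-phase accuracy overall, per goal, and per route-congruence split.

    Route congruence compares the test-phase bridge with the sample-phase
    outbound bridge (same vs different); comparable accuracy across this
    split indicates the goal location, not a route, was remembered.
    95% CIs are percentile bootstraps over trials.  Empty splits are
    reported with NaN accuracy rather than zero.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    correct = trials.correct
    goals = trials.goals
    same_route = trials.field("test_route") == trials.field("sample_route")
    rows = [_split_row("overall", correct, n_boot, seed)]
    for g in (1, 2, 3):
        rows.append(_split_row(f"goal_{g}", correct[goals == g], n_boot, seed + g))
    rows.append(_split_row("route_same", correct[same_route], n_boot, seed + 10))
    rows.append(_split_row("route_different", correct[~same_route], n_boot, seed + 11))
    return pd.DataFrame(rows)


def detect_vte(
    tracking: TrackingData,
    trials: TrialTable,
    speed_window: float = 0.330,
    speed_thresh: float = 5.0,
    event_window: float = 0.800,
) -> np.ndarray:
    """Per-trial vicarious-trial-and-error (VTE) screen at the choice point.

    Head position is the midpoint of the two LEDs.  Speed is displacement
    over sliding windows of ``speed_window`` s (stepped at the tracking
    sample interval; the stride is a package choice).  A trial is flagged
    when at least one window's speed falls below ``speed_thresh`` cm/s
    within the ``event_window`` centered on outer-ring entry
    (``t_choice_entry``).  Trials whose window is not covered by tracking
    are returned as NaN (unevaluable).
    """
    head = tracking.head_xy()
    t = tracking.t
    half = event_window / 2.0
    out = np.zeros(len(trials))
    for i, trial in enumerate(trials):
        t0, t1 = trial.t_choice_entry - half, trial.t_choice_entry + half
        if t.size == 0 or t[0] > t0 + 1e-9 or t[-1] < t1 - 1e-9:
            out[i] = np.nan
            continue
        # window start times stepped by one tracking sample
        starts = t[(t >= t0 - 1e-9) & (t + speed_window <= t1 + 1e-9)]
        if starts.size == 0:
            out[i] = np.nan
            continue
        p0 = np.column_stack([np.interp(starts, t, head[:, 0]),
                              np.interp(starts, t, head[:, 1])])
        p1 = np.column_stack([np.interp(starts + speed_window, t, head[:, 0]),
                              np.interp(starts + speed_window, t, head[:, 1])])
        speeds = np.linalg.norm(p1 - p0, axis=1) / speed_window
        out[i] = float(np.any(speeds < speed_thresh))
    return out


def search_time_summary(
    trials: TrialTable,
    t_search_start: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Start-port search time (search onset to nose-poke) by trial outcome.

    The search interval defaults to [center arrival, delay onset]; pass
    ``t_search_start`` to use a different per-trial onset.  Means with
    percentile-bootstrap 95% CIs are reported separately for correct and
    incorrect trials; an empty outcome group is reported with NaNs.
    """
    if t_search_start is None:
        t_search_start = trials.field("t_center_arrival")
    durations = trials.delay_on - np.asarray(t_search_start, dtype=float)
    correct = trials.correct
    rows = []
    for label, mask in (("correct", correct), ("incorrect", ~correct)):
        d = durations[mask]
        if d.size == 0:
            rows.append({"outcome": label, "n": 0, "mean_s": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        rng = np.random.default_rng(seed)
        boot = rng.choice(d, size=(n_boot, d.size), replace=True).mean(axis=1)
        rows.append({"outcome": label, "n": int(d.size), "mean_s": float(d.mean()),
                     "ci_low": float(np.percentile(boot, 2.5)),
                     "ci_high": float(np.percentile(boot, 97.5))})
    return pd.DataFrame(rows)
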