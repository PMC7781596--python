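"""Task-structure embedding of population vectors and session reports."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from .core_model import PVMatrix, Session, delay_windows, goal_arrival_windows, population_vector

__all__ = ["task_location_pvs", "tsne_embed", "session_report", "write_report",
           "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


def task_location_pvs(
    session: Session, correct_only: bool = True
) -> tuple[PVMatrix, dict]:
    """PVs at the key task locations, labeled start-/goal-/bridge-1..3.

    Per (correct) trial: the delay period (labeled by start), 0-3 s after
    sample-phase goal arrival (labeled by goal), and the bridge crossing
    after the delay, ``[t_delay_off, t_choice_entry)`` (labeled by test
    route).  All three reuse the same population-vector code path.  The
    second return value reports the mean bridge-crossing duration.
    """
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    idx = np.flatnonzero(mask)

    delays = delay_windows(trials)[mask]
    goals_w = goal_arrival_windows(trials, 3.0)[mask]
    bridge_w = np.column_stack([trials.delay_off, trials.field("t_choice_entry")])[mask]

    windows = np.vstack([delays, goals_w, bridge_w])
    labels = np.concatenate([
        [f"start-{t.start}" for t in trials if mask[t.index]],
        [f"goal-{t.goal}" for t in trials if mask[t.index]],
        [f"bridge-{t.test_route}" for t in trials if mask[t.index]],
    ])
    pv = population_vector(session, windows,
                           trial_indices=np.concatenate([idx, idx, idx]),
                           window_name="task_locations")
    pv = PVMatrix(values=pv.values, trial_indices=pv.trial_indices,
                  cell_ids=pv.cell_ids, window_name=pv.window_name,
                  row_labels=labels)
    info = {"mean_bridge_crossing_s": float((bridge_w[:, 1] - bridge_w[:, 0]).mean()),
            "n_pvs": int(pv.values.shape[0])}
    return pv, info


def tsne_embed(
    pvs: PVMatrix,
    perplexity: float = 35.0,
    learning_rate: float = 100.0,
    n_runs: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-dimensional t-SNE of PVs; the minimum-KL run of ``n_runs`` is kept.

    Returns ``(coords, kl_per_run)`` where ``coords`` belongs to the run
    with the lowest Kullback-Leibler divergence.  PVs are z-scored per cell
    by default before embedding.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(pvs.values, float)
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 points for an embedding, got {n}")
    if standardize:
        sd = X.std(axis=0)
        X = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1), 0.0)
    if n <= 3 * perplexity:
        warnings.warn(f"only {n} points for perplexity {perplexity}; "
                      "embedding may be unstable")
    perp = min(perplexity, (n - 1) / 3.0)

    best_coords, kls = None, []
    for run in range(n_runs):
        ts = TSNE(n_components=2, perplexity=perp, learning_rate=learning_rate,
                  init="random", random_state=seed * 1000 + run)
        coords = ts.fit_transform(X)
        kls.append(float(ts.kl_divergence_))
        if best_coords is None or kls[-1] == min(kls):
            best_coords = coords
    return best_coords, np.asarray(kls)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def session_report(
    meta: dict | None = None,
    behavior: dict | None = None,
    selection: dict | None = None,
    decoding: dict | None = None,
    phase: dict | None = None,
    covariance: dict | None = None,
    embedding: dict | None = None,
) -> dict:
    """Machine-readable collation of all stage outputs.

    Every stage key is present (null when the stage was not run); the
    report carries a schema version and a hash of the provenance metadata
    so regenerating from the same inputs is byte-identical.
    """
    stages = {"behavior": behavior, "selection": selection, "decoding": decoding,
              "phase": phase, "covariance": covariance, "embedding": embedding}
    if all(v is None for v in stages.values()):
        raise ValueError("need at least one stage output")
    meta = meta or {}
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "meta": meta,
        "config_hash": _config_hash(meta),
        **stages,
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(report), indent=1, sort_keys=True))
    return path
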