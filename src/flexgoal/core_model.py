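"""Domain types, session I/O and event-aligned spike binning.

A *session* bundles everything one recording of the multi-start/multi-goal/
multi-route (MSMGMR) working-memory task produces: a trial table with event
timestamps, per-unit spike trains, optional multi-channel LFP and optional
two-LED head tracking.  All times are seconds from recording start; all rates
are Hz.

Binning conventions used throughout the package:

* bins are half-open ``[a, b)`` -- a spike exactly at a window's end is
  excluded, a spike exactly on an interior edge belongs to the later bin;
* when a bin width does not tile a window exactly, the final partial bin is
  dropped (a partial-width bin is never analyzed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Trial",
    "TrialTable",
    "Unit",
    "LFPSignal",
    "TrackingData",
    "PVMatrix",
    "Session",
    "save_session",
    "load_session",
    "bin_aligned_counts",
    "n_bins_for",
    "population_vector",
]

#: permitted nose-poke delay durations (s); one animal used 3.2 s
DELAY_DURATIONS = (3.0, 3.2)

#: tolerance on the delay off-minus-on duration (s)
DELAY_TOL = 1e-3

CLASSES = (1, 2, 3)

_EVENT_FIELDS = (
    "t_sample_goal_arrival",
    "t_center_arrival",
    "t_delay_on",
    "t_delay_off",
    "t_choice_entry",
    "t_test_goal_arrival",
)


class ValidationError(ValueError):
    """A session component violates one of its structural invariants."""


@dataclass(frozen=True)
class Trial:
    """One trial of the task: labels plus the six event timestamps.

    ``goal`` is the allocentric goal sampled (and to be remembered), ``start``
    the test-phase start port, ``sample_route``/``test_route`` the bridge
    available in each phase, and ``test_choice`` the goal the animal actually
    visited first in the test phase (so ``correct == (test_choice == goal)``).
    """

    index: int
    goal: int
    start: int
    sample_route: int
    test_route: int
    correct: bool
    t_sample_goal_arrival: float
    t_center_arrival: float
    t_delay_on: float
    t_delay_off: float
    t_choice_entry: float
    t_test_goal_arrival: float
    test_choice: int

    def validate(self, delay_duration: float) -> None:
        if self.index < 0:
            raise ValidationError(f"trial {self.index}: negative index")
        for name, value in (
            ("goal", self.goal),
            ("start", self.start),
            ("sample_route", self.sample_route),
            ("test_route", self.test_route),
            ("test_choice", self.test_choice),
        ):
            if value not in CLASSES:
                raise ValidationError(
                    f"trial {self.index}: {name}={value} not in {CLASSES}"
                )
        ts = [getattr(self, f) for f in _EVENT_FIELDS]
        if not all(b > a for a, b in zip(ts, ts[1:])):
            raise ValidationError(
                f"trial {self.index}: event timestamps not strictly increasing"
            )
        if abs((self.t_delay_off - self.t_delay_on) - delay_duration) > DELAY_TOL:
            raise ValidationError(
                f"trial {self.index}: delay duration "
                f"{self.t_delay_off - self.t_delay_on:.4f} s != {delay_duration} s"
            )
        if self.correct != (self.test_choice == self.goal):
            raise ValidationError(
                f"trial {self.index}: correct flag inconsistent with test_choice"
            )


@dataclass(frozen=True)
class TrialTable:
    """Ordered trials plus the session's nose-poke delay duration."""

    trials: tuple[Trial, ...]
    delay_duration: float

    def __post_init__(self):
        object.__setattr__(self, "trials", tuple(self.trials))

    def validate(self) -> None:
        if self.delay_duration not in DELAY_DURATIONS:
            raise ValidationError(
                f"delay_duration {self.delay_duration} not in {DELAY_DURATIONS}"
            )
        for pos, trial in enumerate(self.trials):
            if trial.index != pos:
                raise ValidationError(
                    f"trial at position {pos} has index {trial.index}; "
                    "indices must be contiguous from 0"
                )
            trial.validate(self.delay_duration)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i) -> Trial:
        return self.trials[i]

    def field(self, name: str) -> np.ndarray:
        """Per-trial array of one Trial field (e.g. ``'goal'``)."""
        return np.asarray([getattr(t, name) for t in self.trials])

    @property
    def goals(self) -> np.ndarray:
        return self.field("goal")

    @property
    def starts(self) -> np.ndarray:
        return self.field("start")

    @property
    def correct(self) -> np.ndarray:
        return self.field("correct").astype(bool)

    @property
    def delay_on(self) -> np.ndarray:
        return self.field("t_delay_on")

    @property
    def delay_off(self) -> np.ndarray:
        return self.field("t_delay_off")

    def reindexed(self) -> "TrialTable":
        """Same trials with indices renumbered 0..n-1 (after subsetting)."""
        new = tuple(replace(t, index=i) for i, t in enumerate(self.trials))
        return TrialTable(new, self.delay_duration)

    def subset(self, mask_or_indices) -> "TrialTable":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TrialTable(tuple(self.trials[i] for i in idx), self.delay_duration).reindexed()


@dataclass(frozen=True)
class Unit:
    """A sorted unit: spike train plus the metadata the filters consume."""

    unit_id: int
    spike_times: np.ndarray
    waveform_width: float  # peak-to-trough, ms
    mean_rate: float  # Hz over the whole session
    subarea: str = "PL"
    channel_index: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )

    def validate(self, session_duration: Optional[float] = None) -> None:
        st = self.spike_times
        if st.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times not 1-D")
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike_times must be sorted and non-negative"
            )
        if session_duration is not None and session_duration > 0:
            expected = st.size / session_duration
            if abs(expected - self.mean_rate) > 1e-6 + 1e-9 * abs(expected):
                raise ValidationError(
                    f"unit {self.unit_id}: mean_rate {self.mean_rate:.6f} Hz "
                    f"inconsistent with {expected:.6f} Hz from spike count"
                )


@dataclass(frozen=True)
class LFPSignal:
    """Multi-channel LFP, ``samples`` shaped (channels, time)."""

    fs: float
    samples: np.ndarray
    channel_indices: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float32))
        object.__setattr__(
            self, "channel_indices", np.asarray(self.channel_indices, dtype=int)
        )

    def validate(self, highest_band_edge: float = 30.0) -> None:
        if self.fs <= 2 * highest_band_edge:
            raise ValidationError(
                f"LFP fs {self.fs} Hz <= 2 x highest analysis band edge "
                f"({highest_band_edge} Hz)"
            )
        if self.samples.ndim != 2:
            raise ValidationError("LFP samples must be 2-D (channels x time)")
        if self.samples.shape[0] != self.channel_indices.size:
            raise ValidationError("LFP channel_indices length != number of channels")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs


@dataclass(frozen=True)
class TrackingData:
    """Two-LED head tracking at (nominally) 30 Hz; coordinates in cm."""

    fs: float
    t: np.ndarray
    led1_xy: np.ndarray
    led2_xy: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "led1_xy", np.asarray(self.led1_xy, dtype=float))
        object.__setattr__(self, "led2_xy", np.asarray(self.led2_xy, dtype=float))

    def validate(self, jitter_tol: float = 0.5) -> None:
        if self.t.size >= 2:
            dt = np.diff(self.t)
            nominal = 1.0 / self.fs
            if np.any(np.abs(dt - nominal) > jitter_tol * nominal):
                raise ValidationError("tracking sampling non-uniform beyond tolerance")
        for name, arr in (("led1_xy", self.led1_xy), ("led2_xy", self.led2_xy)):
            if arr.shape != (self.t.size, 2):
                raise ValidationError(f"tracking {name} must be (n, 2)")

    def head_xy(self) -> np.ndarray:
        """Head position as midpoint of the two LEDs."""
        return 0.5 * (self.led1_xy + self.led2_xy)


@dataclass(frozen=True)
class PVMatrix:
    """Population-vector matrix: per-trial firing-rate vectors (Hz)."""

    values: np.ndarray  # (n_trials, n_cells)
    trial_indices: np.ndarray
    cell_ids: np.ndarray
    window_name: str = ""
    row_labels: Optional[np.ndarray] = None  # optional per-row class labels

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "trial_indices", np.asarray(self.trial_indices, dtype=int))
        object.__setattr__(self, "cell_ids", np.asarray(self.cell_ids, dtype=int))
        if self.values.shape != (self.trial_indices.size, self.cell_ids.size):
            raise ValidationError("PVMatrix shape inconsistent with indices")
        if np.any(self.values < 0):
            raise ValidationError("PVMatrix rates must be non-negative")


@dataclass
class Session:
    """Container binding trials, units and the optional continuous signals."""

    trial_table: TrialTable
    units: list[Unit]
    lfp: Optional[LFPSignal] = None
    tracking: Optional[TrackingData] = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.trial_table.validate()
        duration = self.recording_duration()
        for u in self.units:
            u.validate(session_duration=duration)
        if self.lfp is not None:
            self.lfp.validate()
        if self.tracking is not None:
            self.tracking.validate()
        if len(self.trial_table):
            t_max = max(t.t_test_goal_arrival for t in self.trial_table)
            if duration is not None and t_max > duration + 1e-6:
                raise ValidationError(
                    f"event timestamp {t_max:.3f} s beyond recording duration "
                    f"{duration:.3f} s"
                )

    def recording_duration(self) -> Optional[float]:
        """Recording span (s); from meta if present, else inferred."""
        if "duration" in self.meta:
            return float(self.meta["duration"])
        candidates = []
        if self.lfp is not None:
            candidates.append(self.lfp.duration)
        if self.tracking is not None and self.tracking.t.size:
            candidates.append(float(self.tracking.t[-1]))
        if len(self.trial_table):
            candidates.append(max(t.t_test_goal_arrival for t in self.trial_table) + 1.0)
        for u in self.units:
            if u.spike_times.size:
                candidates.append(float(u.spike_times[-1]))
        return max(candidates) if candidates else None

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray([u.unit_id for u in self.units])

    def unit_by_id(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no unit with id {unit_id}")

    def units_by_ids(self, cell_ids: Sequence[int]) -> list[Unit]:
        return [self.unit_by_id(c) for c in cell_ids]


# ---------------------------------------------------------------------------
# Session I/O (plain-text CSV + raw float32 LFP)
# ---------------------------------------------------------------------------

_TRIALS_COLUMNS = [
    "index", "goal", "start", "sample_route", "test_route", "correct",
    "t_sample_goal_arrival", "t_center_arrival", "t_delay_on", "t_delay_off",
    "t_choice_entry", "t_test_goal_arrival", "test_choice",
]


def save_session(session: Session, dir_path) -> Path:
    """Write a session to ``dir_path`` in the package's on-disk layout.

    Layout: ``trials.csv``, ``spikes.csv``, ``units.csv`` always;
    ``lfp.bin`` (little-endian float32, channel-major frames) + ``lfp.json``
    and ``tracking.csv`` when those parts are present; ``meta.json`` with
    provenance.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trial_table:
        rows.append({
            "index": t.index, "goal": t.goal, "start": t.start,
            "sample_route": t.sample_route, "test_route": t.test_route,
            "correct": int(t.correct),
            "t_sample_goal_arrival": t.t_sample_goal_arrival,
            "t_center_arrival": t.t_center_arrival,
            "t_delay_on": t.t_delay_on, "t_delay_off": t.t_delay_off,
            "t_choice_entry": t.t_choice_entry,
            "t_test_goal_arrival": t.t_test_goal_arrival,
            "test_choice": t.test_choice,
        })
    pd.DataFrame(rows, columns=_TRIALS_COLUMNS).to_csv(d / "trials.csv", index=False)

    uid = np.concatenate([np.full(u.spike_times.size, u.unit_id, dtype=int)
                          for u in session.units]) if session.units else np.array([], int)
    st = np.concatenate([u.spike_times for u in session.units]) if session.units else np.array([])
    order = np.argsort(st, kind="stable")
    pd.DataFrame({"unit_id": uid[order], "time_s": st[order]}).to_csv(
        d / "spikes.csv", index=False)

    pd.DataFrame({
        "unit_id": [u.unit_id for u in session.units],
        "waveform_width_ms": [u.waveform_width for u in session.units],
        "mean_rate_hz": [u.mean_rate for u in session.units],
        "subarea": [u.subarea for u in session.units],
        "channel_index": [u.channel_index for u in session.units],
    }).to_csv(d / "units.csv", index=False)

    if session.lfp is not None:
        # channel-major frames: one frame = all channels at one sample time
        session.lfp.samples.T.astype("<f4").tofile(d / "lfp.bin")
        (d / "lfp.json").write_text(json.dumps({
            "fs_hz": session.lfp.fs,
            "n_channels": int(session.lfp.samples.shape[0]),
            "channel_indices": session.lfp.channel_indices.tolist(),
        }))

    if session.tracking is not None:
        tr = session.tracking
        pd.DataFrame({
            "t_s": tr.t,
            "x1_cm": tr.led1_xy[:, 0], "y1_cm": tr.led1_xy[:, 1],
            "x2_cm": tr.led2_xy[:, 0], "y2_cm": tr.led2_xy[:, 1],
        }).to_csv(d / "tracking.csv", index=False)
        meta_tracking_fs = tr.fs
    else:
        meta_tracking_fs = None

    meta = dict(session.meta)
    meta["delay_duration"] = session.trial_table.delay_duration
    if meta_tracking_fs is not None:
        meta["tracking_fs"] = meta_tracking_fs
    (d / "meta.json").write_text(json.dumps(meta, default=_json_default, indent=1))
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_session(dir_path) -> Session:
    """Load a session directory written by :func:`save_session`.

    Raises
    ------
    FileNotFoundError
        if a mandatory file (trials.csv, spikes.csv, units.csv) is absent.
    ValidationError
        if a loaded component violates an invariant (names the trial/unit).
    """
    d = Path(dir_path)
    for fname in ("trials.csv", "spikes.csv", "units.csv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"mandatory session file missing: {d / fname}")

    meta = json.loads((d / "meta.json").read_text()) if (d / "meta.json").exists() else {}
    delay_duration = float(meta.get("delay_duration", 3.0))

    tdf = pd.read_csv(d / "trials.csv")
    trials = tuple(
        Trial(
            index=int(r["index"]), goal=int(r["goal"]), start=int(r["start"]),
            sample_route=int(r["sample_route"]), test_route=int(r["test_route"]),
            correct=bool(int(r["correct"])),
            t_sample_goal_arrival=float(r["t_sample_goal_arrival"]),
            t_center_arrival=float(r["t_center_arrival"]),
            t_delay_on=float(r["t_delay_on"]), t_delay_off=float(r["t_delay_off"]),
            t_choice_entry=float(r["t_choice_entry"]),
            t_test_goal_arrival=float(r["t_test_goal_arrival"]),
            test_choice=int(r["test_choice"]),
        )
        for _, r in tdf.iterrows()
    )
    trial_table = TrialTable(trials, delay_duration)

    sdf = pd.read_csv(d / "spikes.csv")
    udf = pd.read_csv(d / "units.csv")
    by_unit = {int(k): np.sort(np.asarray(v, dtype=float))
               for k, v in sdf.groupby("unit_id")["time_s"]}
    units = [
        Unit(
            unit_id=int(r["unit_id"]),
            spike_times=by_unit.get(int(r["unit_id"]), np.array([])),
            waveform_width=float(r["waveform_width_ms"]),
            mean_rate=float(r["mean_rate_hz"]),
            subarea=str(r["subarea"]),
            channel_index=int(r["channel_index"]),
        )
        for _, r in udf.iterrows()
    ]

    lfp = None
    if (d / "lfp.bin").exists() and (d / "lfp.json").exists():
        info = json.loads((d / "lfp.json").read_text())
        raw = np.fromfile(d / "lfp.bin", dtype="<f4")
        n_ch = int(info["n_channels"])
        lfp = LFPSignal(
            fs=float(info["fs_hz"]),
            samples=raw.reshape(-1, n_ch).T,
            channel_indices=np.asarray(info["channel_indices"], dtype=int),
        )

    tracking = None
    if (d / "tracking.csv").exists():
        kdf = pd.read_csv(d / "tracking.csv")
        tracking = TrackingData(
            fs=float(meta.get("tracking_fs", 30.0)),
            t=kdf["t_s"].to_numpy(),
            led1_xy=kdf[["x1_cm", "y1_cm"]].to_numpy(),
            led2_xy=kdf[["x2_cm", "y2_cm"]].to_numpy(),
        )

    session = Session(trial_table=trial_table, units=units, lfp=lfp,
                      tracking=tracking, meta=meta)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Event-aligned binning and population vectors
# ---------------------------------------------------------------------------

def n_bins_for(t0: float, t1: float, binwidth: float) -> int:
    """Number of full bins of ``binwidth`` tiling [t0, t1); partial bin dropped."""
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    return int(np.floor((t1 - t0) / binwidth + 1e-9))


def bin_aligned_counts(
    units: Sequence[Unit],
    events: np.ndarray,
    window: tuple[float, float],
    binwidth: float,
    recording_duration: Optional[float] = None,
) -> np.ndarray:
    """Event-aligned spike counts, shape (trials, cells, bins).

    ``counts[i, j, k]`` is the number of spikes of cell ``j`` in
    ``[event_i + t0 + k*binwidth, event_i + t0 + (k+1)*binwidth)``.
    Bins are referenced to the window start; a final partial bin is dropped.
    """
    if len(units) == 0:
        raise ValueError("empty unit list")
    events = np.asarray(events, dtype=float)
    t0, t1 = window
    nb = n_bins_for(t0, t1, binwidth)
    if recording_duration is not None:
        bad = np.flatnonzero(
            (events + t0 < -1e-9) | (events + t0 + nb * binwidth > recording_duration + 1e-9)
        )
        if bad.size:
            raise ValueError(f"events outside recording for trials {bad.tolist()}")
    edges_rel = t0 + binwidth * np.arange(nb + 1)
    counts = np.empty((events.size, len(units), nb), dtype=np.int64)
    for j, u in enumerate(units):
        # (trials, nb+1) absolute edges; searchsorted left => half-open bins
        edges = events[:, None] + edges_rel[None, :]
        pos = np.searchsorted(u.spike_times, edges.ravel(), side="left").reshape(edges.shape)
        counts[:, j, :] = np.diff(pos, axis=1)
    return counts


def population_vector(
    session: Session,
    window_spec: np.ndarray,
    cells: Optional[Sequence[int]] = None,
    window_name: str = "",
    trial_indices: Optional[np.ndarray] = None,
) -> PVMatrix:
    """Firing-rate population vectors for per-trial windows.

    Parameters
    ----------
    window_spec : (n, 2) array of absolute [t0, t1) windows, one per trial.
    cells : cell ids to include (default: all units, session order).
    trial_indices : trial indices labeling the rows (default 0..n-1).
    """
    window_spec = np.asarray(window_spec, dtype=float)
    if window_spec.ndim != 2 or window_spec.shape[1] != 2:
        raise ValueError("window_spec must be (n, 2)")
    durations = window_spec[:, 1] - window_spec[:, 0]
    if np.any(durations <= 0):
        raise ValueError("windows must have positive duration")
    if cells is None:
        cells = [u.unit_id for u in session.units]
    units = session.units_by_ids(cells)  # KeyError on unknown id
    values = np.empty((window_spec.shape[0], len(units)))
    for j, u in enumerate(units):
        lo = np.searchsorted(u.spike_times, window_spec[:, 0], side="left")
        hi = np.searchsorted(u.spike_times, window_spec[:, 1], side="left")
        values[:, j] = (hi - lo) / durations
    if trial_indices is None:
        trial_indices = np.arange(window_spec.shape[0])
    return PVMatrix(values=values, trial_indices=trial_indices,
                    cell_ids=np.asarray(cells), window_name=window_name)


def delay_windows(trial_table: TrialTable) -> np.ndarray:
    """(n, 2) absolute delay-period windows [t_delay_on, t_delay_off)."""
    return np.column_stack([trial_table.delay_on, trial_table.delay_off])


def goal_arrival_windows(trial_table: TrialTable, duration: float = 3.0) -> np.ndarray:
    """(n, 2) windows covering ``duration`` s after sample-phase goal arrival."""
    t0 = trial_table.field("t_sample_goal_arrival")
    return np.column_stack([t0, t0 + duration])
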