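"""Ground-truth synthetic sessions of the MSMGMR working-memory task.

The generator emulates the statistical structure every analysis stage needs:

* balanced pseudorandom trial sequences (27-trial blocks of all
  start x goal x test-route combinations, balanced 9-trial subblocks, no
  goal repeated more than twice in a row, sample routes covering each route
  once per goal per subblock);
* inhomogeneous-Poisson spike trains with configurable selectivity for the
  start port, the allocentric goal, the egocentric goal, start x goal
  conjunctions, within-delay sequences, oscillatory phase locking, pairwise
  fast synchrony, and slow rate drift;
* multi-channel LFP as three band-limited oscillations (2.5-5, 5-12,
  15-30 Hz) whose amplitude is elevated during delays, plus pink noise;
* two-LED tracking that is stationary (sub-cm sensor noise) during every
  nose-poke delay and follows piecewise-linear paths between task locations
  otherwise.

Everything is driven by named, independently seeded RNG streams so each data
component is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import zlib

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter
from scipy.special import i0

from .core_model import (
    Session,
    TrackingData,
    Trial,
    TrialTable,
    LFPSignal,
    Unit,
)

__all__ = [
    "SelectivityConfig",
    "GroundTruth",
    "TimingConfig",
    "generate_trial_sequence",
    "generate_session",
    "apply_rotation",
    "ego_class",
    "BANDS",
]

#: analysis frequency bands (Hz) with elevated delay-period power
BANDS = {"slow": (2.5, 5.0), "theta": (5.0, 12.0), "beta": (15.0, 30.0)}

#: oscillation center frequency used by the generator per band (Hz)
BAND_CENTERS = {"slow": 3.5, "theta": 8.0, "beta": 22.0}

_STREAMS = {"trials": 1, "spikes": 2, "lfp": 3, "tracking": 4, "truth": 5, "sync": 6}


def _rng(seed: int, stream: str, *extra: int) -> Generator:
    return default_rng(SeedSequence((int(seed), _STREAMS[stream]) + tuple(int(e) for e in extra)))


def ego_class(goal, start, offset: int = 0):
    """Egocentric goal class in {1, 2, 3} from (goal - start) mod 3.

    With ``offset=0`` the mapping is 1='behind', 2='left', 3='right' under
    the identity-offset convention; ``offset`` rotates the convention.  The
    class is invariant under joint rotation of goal and start.
    """
    return ((np.asarray(goal) - np.asarray(start) + offset) % 3) + 1


# ---------------------------------------------------------------------------
# Trial-sequence generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingConfig:
    """Mean durations (s) of the task steps used to lay out timestamps."""

    t_first_trial: float = 5.0
    sample_run: float = 3.0
    sample_return: float = 3.0
    search: float = 2.0
    run_to_choice: float = 1.5
    choice_to_goal: float = 1.5
    inter_trial: float = 2.5
    jitter_frac: float = 0.15  # multiplicative lognormal-ish jitter on gaps


def _balanced_block(rng: Generator) -> np.ndarray:
    """One 27-trial block (start, goal, test_route), balanced subblocks.

    The 27 triples over {0,1,2}^3 are partitioned by (s+g+r) mod 3 into three
    9-trial groups; each group contains every start, goal and route exactly
    three times.  Random relabelings of each coordinate plus random group
    order and within-group order randomize the sequence while preserving
    balance by construction.
    """
    ps, pg, pr = (rng.permutation(3) for _ in range(3))
    groups = []
    for c in rng.permutation(3):
        combos = [(ps[s], pg[g], pr[(c - s - g) % 3]) for s in range(3) for g in range(3)]
        groups.append(np.asarray(combos))
    return groups  # list of three (9, 3) arrays, ordering within group TBD


def _order_subblock(sub: np.ndarray, prev_goals: list[int], rng: Generator,
                    max_tries: int = 500) -> Optional[np.ndarray]:
    """Random order of a 9-trial subblock keeping goal runs <= 2 across the boundary."""
    for _ in range(max_tries):
        perm = rng.permutation(len(sub))
        goals = sub[perm, 1]
        seq = prev_goals[-2:] + list(goals)
        ok = all(not (seq[i] == seq[i + 1] == seq[i + 2]) for i in range(len(seq) - 2))
        if ok:
            return sub[perm]
    return None


def _assign_sample_routes(subblock: np.ndarray, rng: Generator) -> np.ndarray:
    """Per goal within a 9-trial subblock, the three trials get distinct sample routes."""
    routes = np.empty(len(subblock), dtype=int)
    for g in range(3):
        idx = np.flatnonzero(subblock[:, 1] == g)
        routes[idx] = rng.permutation(3)
    return routes


def generate_trial_sequence(
    n_blocks: int,
    delay_duration: float = 3.0,
    seed: int = 0,
    accuracy: float | Callable[[int], float] = 0.7737,
    timing: TimingConfig = TimingConfig(),
    max_retries: int = 50,
) -> TrialTable:
    """Balanced pseudorandom trial sequence of ``n_blocks`` 27-trial blocks.

    Each block is a permutation of the 27 (start, goal, test-route)
    combinations whose three 9-trial subblocks each contain every start,
    goal and test route exactly three times; the same goal never occurs on
    more than two consecutive trials (also across block and subblock
    boundaries); within each subblock the three trials sharing a goal use
    the three distinct sample routes.

    ``accuracy`` is the per-trial probability of a correct test-phase choice
    (default: the behavioral level the task is performed at, ~77%); pass a
    callable of the trial position for non-stationary accuracy models.
    Errors pick one of the two wrong goals uniformly.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = _rng(seed, "trials")
    rows = []
    goals_so_far: list[int] = []
    for _ in range(n_blocks):
        for attempt in range(max_retries + 1):
            groups = _balanced_block(rng)
            ordered = []
            tail = list(goals_so_far)
            ok = True
            for sub in groups:
                placed = _order_subblock(sub, tail, rng)
                if placed is None:
                    ok = False
                    break
                ordered.append(placed)
                tail = tail + list(placed[:, 1])
            if ok:
                break
        else:
            raise RuntimeError(
                f"trial-sequence constraints unsatisfiable after {max_retries} "
                f"retries (seed={seed})"
            )
        for sub in ordered:
            sroutes = _assign_sample_routes(sub, rng)
            for (s, g, r), sr in zip(sub, sroutes):
                rows.append([int(s) + 1, int(g) + 1, int(sr) + 1, int(r) + 1])
            goals_so_far.extend(int(g) for g in sub[:, 1])

    rows = np.asarray(rows)
    n = len(rows)
    acc = np.asarray([accuracy(i) if callable(accuracy) else accuracy for i in range(n)])
    correct = rng.random(n) < acc
    test_choice = rows[:, 1].copy()
    for i in np.flatnonzero(~correct):
        wrong = [g for g in (1, 2, 3) if g != rows[i, 1]]
        test_choice[i] = wrong[rng.integers(2)]

    trials = _layout_timestamps(rows, correct, test_choice, delay_duration, timing, rng)
    table = TrialTable(trials, delay_duration)
    table.validate()
    return table


def _layout_timestamps(rows, correct, test_choice, delay_duration, timing, rng):
    def gap(mean):
        return mean * float(np.exp(rng.normal(0.0, timing.jitter_frac)))

    trials = []
    t = timing.t_first_trial
    for i, (s, g, sr, tr) in enumerate(rows):
        t_sample = t + gap(timing.sample_run)
        t_center = t_sample + gap(timing.sample_return)
        t_on = t_center + gap(timing.search)
        t_off = t_on + delay_duration
        t_choice = t_off + gap(timing.run_to_choice)
        t_goal = t_choice + gap(timing.choice_to_goal)
        trials.append(Trial(
            index=i, goal=int(g), start=int(s), sample_route=int(sr),
            test_route=int(tr), correct=bool(correct[i]),
            t_sample_goal_arrival=t_sample, t_center_arrival=t_center,
            t_delay_on=t_on, t_delay_off=t_off, t_choice_entry=t_choice,
            t_test_goal_arrival=t_goal, test_choice=int(test_choice[i]),
        ))
        t = t_goal + gap(timing.inter_trial)
    return tuple(trials)


# ---------------------------------------------------------------------------
# Selectivity configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectivityConfig:
    """What structure to inject into the synthetic spike trains.

    Fractions refer to exclusive selectivity classes drawn in the order
    goal, start, ego, conjunctive, sequence; their sum must not exceed 1.
    ``gain`` multiplies the delay-period rate on trials matching a selective
    cell's preferred label; with ``goal_arrival_gain`` (default), goal cells
    additionally fire at the gained rate while the animal is at their
    preferred goal in the sample phase (place-like firing at the goal),
    which is what makes them detectable from goal-arrival rates.  ``phase_lock`` entries are
    ``(cell, band, kappa, preferred_phase, goal_specific)``; with
    ``goal_specific`` the preferred phase is rotated by 2*pi/3 per goal
    (same rate, different phase -- a phase-only code).  ``sync_pairs``
    entries are ``(cell_a, cell_b, shared_event_rate_hz, jitter_sd_s,
    preferred_only)``: shared excess spikes during delays, each copy
    independently jittered.
    """

    n_cells: int = 90
    base_rate: float = 3.0
    frac_goal_cells: float = 0.0
    frac_start_cells: float = 0.0
    frac_ego_cells: float = 0.0
    frac_conjunctive_cells: float = 0.0
    frac_sequence_cells: float = 0.0
    gain: float = 3.0
    goal_arrival_gain: bool = True    # goal cells also gain at their goal (sample phase)
    goal_arrival_window: float = 3.0  # s of gained firing after sample goal arrival
    drift_cells: tuple = ()           # (cell, start_rate_hz, end_rate_hz)
    phase_lock: tuple = ()            # (cell, band, kappa, pref_phase, goal_specific)
    sync_pairs: tuple = ()            # (cell_a, cell_b, rate_hz, jitter_sd_s, preferred_only)
    seed: int = 0
    ego_offset: int = 0
    n_interneurons: int = 0
    interneuron_rate: float = 25.0
    interneuron_width: float = 0.22   # ms, peak-to-trough
    principal_width: float = 0.65     # ms
    sequence_sigma: float = 0.25      # s, width of sequence-cell rate bumps
    with_lfp: bool = True
    lfp_fs: float = 2500.0
    n_lfp_channels: int = 16
    lfp_channel_spacing: int = 2      # probe sites between adjacent LFP channels
    tracking_fs: float = 30.0
    tracking_noise: float = 0.1       # cm sd, clipped to +-0.3 cm

    def validate(self) -> None:
        total = (self.frac_goal_cells + self.frac_start_cells + self.frac_ego_cells
                 + self.frac_conjunctive_cells + self.frac_sequence_cells)
        if total > 1 + 1e-9:
            raise ValueError(f"selectivity fractions sum to {total:.3f} > 1")
        for fr in (self.frac_goal_cells, self.frac_start_cells, self.frac_ego_cells,
                   self.frac_conjunctive_cells, self.frac_sequence_cells):
            if not 0 <= fr <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        for entry in self.phase_lock:
            if entry[2] < 0:
                raise ValueError("kappa must be >= 0")
        for entry in self.sync_pairs:
            if entry[3] < 0:
                raise ValueError("jitter_sd must be >= 0")


@dataclass
class RotationSpec:
    """Mid-session maze rotation: tuning remap + accuracy drop-and-ramp."""

    at_trial: int
    p_drop: float = 1.0 / 3.0
    p_asymptote: float = 0.75
    ramp_midpoint: float = 15.0   # trials after rotation to half-recovery
    ramp_scale: float = 5.0

    def accuracy(self, i: int, pre_accuracy: float) -> float:
        if i < self.at_trial:
            return pre_accuracy
        x = (i - self.at_trial - self.ramp_midpoint) / self.ramp_scale
        return self.p_drop + (self.p_asymptote - self.p_drop) / (1.0 + np.exp(-x))


@dataclass
class GroundTruth:
    """What was injected: per-cell selectivity, pairs, conventions, rotation."""

    cell_class: dict          # cell_id -> scheme in {none,goal,start,ego,conj,seq,interneuron}
    preferred: dict           # cell_id -> preferred label (int, (s,g) tuple, or None)
    sequence_latency: dict    # cell_id -> bump latency from delay onset (s)
    phase_lock: tuple
    sync_pairs: tuple         # entries + resolved pair preferred goal
    ego_offset: int
    config: SelectivityConfig
    rotation: Optional[RotationSpec] = None
    preferred_post: dict = field(default_factory=dict)  # post-rotation remap

    def cells_of_class(self, scheme: str) -> list[int]:
        return [c for c, s in self.cell_class.items() if s == scheme]


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _assign_cells(config: SelectivityConfig, rng: Generator):
    n = config.n_cells
    counts = {
        "goal": int(round(config.frac_goal_cells * n)),
        "start": int(round(config.frac_start_cells * n)),
        "ego": int(round(config.frac_ego_cells * n)),
        "conj": int(round(config.frac_conjunctive_cells * n)),
        "seq": int(round(config.frac_sequence_cells * n)),
    }
    order = rng.permutation(n)
    cell_class = {c: "none" for c in range(n)}
    preferred = {c: None for c in range(n)}
    pos = 0
    for scheme, k in counts.items():
        for j in range(k):
            c = int(order[pos]); pos += 1
            cell_class[c] = scheme
            if scheme == "conj":
                preferred[c] = (int(rng.integers(1, 4)), int(rng.integers(1, 4)))
            elif scheme == "seq":
                preferred[c] = int(rng.integers(1, 4))  # goal gating the sequence
            else:
                # cycle preferred labels so each class is represented
                preferred[c] = (j % 3) + 1
    return cell_class, preferred


def _delay_label_match(scheme, pref, trial: Trial, ego_offset: int) -> bool:
    if scheme == "goal":
        return trial.goal == pref
    if scheme == "start":
        return trial.start == pref
    if scheme == "ego":
        return int(ego_class(trial.goal, trial.start, ego_offset)) == pref
    if scheme == "conj":
        return (trial.start, trial.goal) == pref
    return False


def _band_phase_fn(band_name: str, seed: int):
    """Deterministic analytic phase of the generator's band oscillation."""
    f = BAND_CENTERS[band_name]
    phi0 = float(_rng(seed, "lfp", zlib.crc32(band_name.encode()) % 1000)
                 .uniform(0, 2 * np.pi))
    def phase(t):
        return np.mod(2 * np.pi * f * np.asarray(t) + phi0 + np.pi, 2 * np.pi) - np.pi
    return phase


def _spike_train_for_cell(
    cell: int,
    scheme: str,
    pref,
    trials: TrialTable,
    config: SelectivityConfig,
    duration: float,
    seq_latency: Optional[float],
    drift: Optional[tuple[float, float]],
    plock: Optional[tuple],
    band_phases: dict,
    rotation: Optional[RotationSpec],
    pref_post,
) -> np.ndarray:
    """Inhomogeneous-Poisson train by thinning against the cell's rate bound."""
    rng = _rng(config.seed, "spikes", cell)
    base = config.base_rate
    r0, r1 = drift if drift is not None else (base, base)
    max_drift = max(r0, r1) / base
    kappa = plock[2] if plock is not None else 0.0
    phase_max = float(np.exp(kappa) / i0(kappa)) if kappa > 0 else 1.0
    bound = base * max_drift * config.gain * phase_max + 1e-9

    n_cand = rng.poisson(bound * duration)
    t = np.sort(rng.uniform(0, duration, n_cand))
    u = rng.random(n_cand)

    rate = np.full(n_cand, base)
    if drift is not None:
        rate = r0 + (r1 - r0) * (t / duration)

    d_on, d_off = trials.delay_on, trials.delay_off
    idx = np.searchsorted(d_on, t, side="right") - 1
    in_delay = (idx >= 0) & (t < d_off[np.clip(idx, 0, None)])
    rot_at = rotation.at_trial if rotation is not None else None

    for k in np.flatnonzero(in_delay):
        trial = trials[int(idx[k])]
        p = pref
        if rot_at is not None and trial.index >= rot_at:
            p = pref_post
        if scheme in ("goal", "start", "ego", "conj"):
            if _delay_label_match(scheme, p, trial, config.ego_offset):
                rate[k] *= config.gain
        elif scheme == "seq":
            if p is None or trial.goal == p:
                tau = t[k] - trial.t_delay_on
                bump = (config.gain - 1.0) * np.exp(
                    -0.5 * ((tau - seq_latency) / config.sequence_sigma) ** 2)
                rate[k] *= (1.0 + bump)
        if plock is not None:
            _, band_name, kap, mu, goal_specific = plock
            if kap > 0:
                mu_t = mu + (2 * np.pi / 3) * (trial.goal - 1) if goal_specific else mu
                theta = band_phases[band_name](t[k])
                rate[k] *= np.exp(kap * np.cos(theta - mu_t)) / i0(kap)

    if scheme == "goal" and config.goal_arrival_gain:
        # place-like firing at the preferred goal location in both task
        # phases: the sample-phase arrival is at the instructed goal, the
        # test-phase arrival at the goal the subject actually chose
        for field, label in (("t_sample_goal_arrival", "goal"),
                             ("t_test_goal_arrival", "test_choice")):
            a_on = trials.field(field)
            jdx = np.searchsorted(a_on, t, side="right") - 1
            in_arrival = (jdx >= 0) & (t < a_on[np.clip(jdx, 0, None)]
                                       + config.goal_arrival_window)
            for k in np.flatnonzero(in_arrival & ~in_delay):
                trial = trials[int(jdx[k])]
                p = pref
                if rot_at is not None and trial.index >= rot_at:
                    p = pref_post
                if getattr(trial, label) == p:
                    rate[k] *= config.gain

    accept = u < rate / bound
    return t[accept]


def _pink_noise(n: int, rng: Generator) -> np.ndarray:
    # classic 1/f shaping filter (Kasdin-style pole-zero approximation)
    b = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
    a = [1.0, -2.494956002, 2.017265875, -0.522189400]
    return lfilter(b, a, rng.standard_normal(n)).astype(np.float32)


def _generate_lfp(trials: TrialTable, config: SelectivityConfig,
                  duration: float, band_phases: dict) -> LFPSignal:
    fs = config.lfp_fs
    n = int(np.ceil(duration * fs))
    t = np.arange(n, dtype=np.float64) / fs

    # amplitude gate: elevated during delays, cosine-tapered edges
    gate = np.full(n, 0.3, dtype=np.float32)
    ramp = 0.25
    for trial in trials:
        i0_, i1 = int(trial.t_delay_on * fs), int(trial.t_delay_off * fs)
        gate[i0_:i1] = 1.0
        nr = int(ramp * fs)
        if i0_ - nr >= 0:
            gate[i0_ - nr:i0_] = np.maximum(
                gate[i0_ - nr:i0_], 0.3 + 0.7 * 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr)))
        if i1 + nr <= n:
            gate[i1:i1 + nr] = np.maximum(
                gate[i1:i1 + nr], 0.3 + 0.7 * 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr)))

    osc = np.zeros(n, dtype=np.float32)
    for name in BANDS:
        osc += np.sin(band_phases[name](t)).astype(np.float32)
    osc *= gate

    rng = _rng(config.seed, "lfp")
    n_ch = config.n_lfp_channels
    samples = np.empty((n_ch, n), dtype=np.float32)
    offsets = rng.uniform(-0.02, 0.02, n_ch)  # small per-channel lags (s)
    for c in range(n_ch):
        shift = int(round(offsets[c] * fs))
        samples[c] = np.roll(osc, shift) + 0.5 * _pink_noise(n, rng)
    channel_indices = np.arange(n_ch) * config.lfp_channel_spacing
    return LFPSignal(fs=fs, samples=samples, channel_indices=channel_indices)


# maze geometry (cm): starts on an inner ring, goals on the outer ring
_CENTER = np.array([0.0, 0.0])
_START_XY = {k + 1: 30.0 * np.array([np.cos(a), np.sin(a)])
             for k, a in enumerate(np.deg2rad([90, 210, 330]))}
_GOAL_XY = {k + 1: 60.0 * np.array([np.cos(a), np.sin(a)])
            for k, a in enumerate(np.deg2rad([30, 150, 270]))}


def _generate_tracking(trials: TrialTable, config: SelectivityConfig,
                       duration: float) -> TrackingData:
    fs = config.tracking_fs
    t = np.arange(0, duration, 1.0 / fs)
    waypoints = [(0.0, _CENTER)]
    for trial in trials:
        g = _GOAL_XY[trial.goal]
        s = _START_XY[trial.start]
        c = _GOAL_XY[trial.test_choice]
        ring = 45.0 * c / np.linalg.norm(c)  # outer-ring entry toward chosen goal
        waypoints += [
            (trial.t_sample_goal_arrival, g),
            (trial.t_sample_goal_arrival + 0.8, g),          # reward dwell
            (trial.t_center_arrival, _CENTER),
            (trial.t_delay_on - 0.2, s),                     # found start port
            (trial.t_delay_off, s),                          # stationary delay
            (trial.t_choice_entry, ring),
            (trial.t_test_goal_arrival, c),
            (trial.t_test_goal_arrival + 0.8, c),
        ]
    waypoints.append((duration, _CENTER))
    wt = np.asarray([w[0] for w in waypoints])
    wxy = np.asarray([w[1] for w in waypoints])
    keep = np.concatenate([[True], np.diff(wt) > 1e-6])
    wt, wxy = wt[keep], wxy[keep]
    head = np.column_stack([np.interp(t, wt, wxy[:, 0]), np.interp(t, wt, wxy[:, 1])])

    rng = _rng(config.seed, "tracking")
    # heading toward next waypoint; LEDs 3 cm apart along the head axis
    vel = np.gradient(head, axis=0)
    norm = np.linalg.norm(vel, axis=1, keepdims=True)
    heading = np.where(norm > 1e-9, vel / np.maximum(norm, 1e-9), [1.0, 0.0])
    noise = lambda: np.clip(rng.normal(0, config.tracking_noise, head.shape), -0.3, 0.3)
    led1 = head + 1.5 * heading + noise()
    led2 = head - 1.5 * heading + noise()
    return TrackingData(fs=fs, t=t, led1_xy=led1, led2_xy=led2)


def generate_session(
    trials: TrialTable,
    config: SelectivityConfig,
    rotation: Optional[RotationSpec] = None,
) -> tuple[Session, GroundTruth]:
    """Generate a synthetic session with known ground truth.

    Delay-period rates follow ``base_rate * gain`` on trials matching each
    selective cell's preferred label; sequence cells carry a Gaussian rate
    bump at a cell-specific latency from delay onset (goal-gated); drift
    cells ramp linearly across the session; sync pairs receive shared excess
    spikes with independent Gaussian jitter; phase-locked cells fire with a
    von Mises phase preference relative to the configured band's oscillation.
    """
    config.validate()
    truth_rng = _rng(config.seed, "truth")
    cell_class, preferred = _assign_cells(config, truth_rng)

    pref_post: dict = {}
    if rotation is not None:
        if not (0 < rotation.at_trial < len(trials)):
            raise ValueError(f"rotation at_trial {rotation.at_trial} out of range")
        for c, scheme in cell_class.items():
            if scheme in ("goal", "start", "ego", "seq"):
                pref_post[c] = int(truth_rng.integers(1, 4))
            elif scheme == "conj":
                pref_post[c] = (int(truth_rng.integers(1, 4)), int(truth_rng.integers(1, 4)))
        trials = _redraw_outcomes(trials, config, rotation)

    seq_latency = {}
    delay = trials.delay_duration
    for c, scheme in cell_class.items():
        if scheme == "seq":
            seq_latency[c] = float(truth_rng.uniform(0.3, delay - 0.3))

    drift = {int(e[0]): (float(e[1]), float(e[2])) for e in config.drift_cells}
    plock = {int(e[0]): e for e in config.phase_lock}
    band_phases = {name: _band_phase_fn(name, config.seed) for name in BANDS}

    duration = trials[-1].t_test_goal_arrival + 3.0
    spike_trains = {}
    for c in range(config.n_cells):
        spike_trains[c] = _spike_train_for_cell(
            c, cell_class[c], preferred[c], trials, config, duration,
            seq_latency.get(c), drift.get(c), plock.get(c), band_phases,
            rotation, pref_post.get(c),
        )

    sync_resolved = []
    for p_idx, entry in enumerate(config.sync_pairs):
        a, b, ev_rate, jit, pref_only = entry
        pair_goal = preferred[a] if cell_class[a] == "goal" else 1
        sync_resolved.append((int(a), int(b), float(ev_rate), float(jit),
                              bool(pref_only), int(pair_goal)))
        extra_a, extra_b = [], []
        for trial in trials:
            prng = _rng(config.seed, "sync", p_idx, trial.index)
            if pref_only and trial.goal != pair_goal:
                continue
            n_ev = prng.poisson(ev_rate * delay)
            ev = prng.uniform(trial.t_delay_on, trial.t_delay_off, n_ev)
            extra_a.append(ev + prng.normal(0, jit, n_ev))
            extra_b.append(ev + prng.normal(0, jit, n_ev))
        if extra_a:
            spike_trains[a] = np.sort(np.concatenate([spike_trains[a], *extra_a]))
            spike_trains[b] = np.sort(np.concatenate([spike_trains[b], *extra_b]))

    units = []
    width_rng = _rng(config.seed, "truth", 999)
    n_pc = config.n_cells
    probe_span = max(config.n_lfp_channels * config.lfp_channel_spacing, 64)
    for c in range(n_pc):
        st = np.clip(spike_trains[c], 0, duration - 1e-9)
        st = np.sort(st)
        units.append(Unit(
            unit_id=c, spike_times=st,
            waveform_width=float(max(0.45, width_rng.normal(config.principal_width, 0.05))),
            mean_rate=st.size / duration,
            subarea=("ACC", "PL", "IL")[c % 3],
            channel_index=int(width_rng.integers(0, probe_span)),
        ))
    for k in range(config.n_interneurons):
        c = n_pc + k
        irng = _rng(config.seed, "spikes", c)
        n_sp = irng.poisson(config.interneuron_rate * duration)
        st = np.sort(irng.uniform(0, duration, n_sp))
        units.append(Unit(
            unit_id=c, spike_times=st,
            waveform_width=float(max(0.12, width_rng.normal(config.interneuron_width, 0.03))),
            mean_rate=st.size / duration,
            subarea="PL", channel_index=int(width_rng.integers(0, probe_span)),
        ))
        cell_class[c] = "interneuron"
        preferred[c] = None

    lfp = _generate_lfp(trials, config, duration, band_phases) if config.with_lfp else None
    tracking = _generate_tracking(trials, config, duration)

    session = Session(
        trial_table=trials, units=units, lfp=lfp, tracking=tracking,
        meta={"seed": config.seed, "duration": duration,
              "generator": "flexgoal.synthetic_session",
              "ego_offset": config.ego_offset},
    )
    session.validate()
    truth = GroundTruth(
        cell_class=cell_class, preferred=preferred, sequence_latency=seq_latency,
        phase_lock=tuple(config.phase_lock), sync_pairs=tuple(sync_resolved),
        ego_offset=config.ego_offset, config=config, rotation=rotation,
        preferred_post=pref_post,
    )
    return session, truth


def _redraw_outcomes(trials: TrialTable, config: SelectivityConfig,
                     rotation: RotationSpec) -> TrialTable:
    """Re-draw correctness for post-rotation trials under the drop-and-ramp model.

    Each trial uses its own seeded uniform, so pre-rotation trials are
    untouched and the coupling is reproducible.
    """
    pre_acc = 0.7737
    new_trials = []
    for trial in trials:
        if trial.index < rotation.at_trial:
            new_trials.append(trial)
            continue
        prng = _rng(config.seed, "trials", 7000 + trial.index)
        p = rotation.accuracy(trial.index, pre_acc)
        correct = bool(prng.random() < p)
        if correct:
            choice = trial.goal
        else:
            wrong = [g for g in (1, 2, 3) if g != trial.goal]
            choice = wrong[int(prng.integers(2))]
        new_trials.append(dataclasses.replace(trial, correct=correct, test_choice=choice))
    return TrialTable(tuple(new_trials), trials.delay_duration)


def apply_rotation(
    session: Session,
    truth: GroundTruth,
    at_trial: int,
    rotation: Optional[RotationSpec] = None,
) -> tuple[Session, GroundTruth]:
    """Mid-session maze rotation: remap spatial tuning and drop-then-ramp accuracy.

    From ``at_trial`` onward, spatially tuned cells switch to new random
    preferred labels and correctness follows the rotation accuracy model;
    trial labels and all pre-rotation data are unchanged (verified by the
    generator's per-trial, per-cell RNG streams).
    """
    n = len(session.trial_table)
    if not (0 < at_trial < n):
        raise ValueError(f"at_trial {at_trial} out of range (0, {n})")
    spec = rotation if rotation is not None else RotationSpec(at_trial=at_trial)
    spec = dataclasses.replace(spec, at_trial=at_trial)
    return generate_session(session.trial_table, truth.config, rotation=spec)
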