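"""LFP phase-of-firing analyses: band phase, locking statistics, decoding.

The per-unit reference LFP is the mean of 10 channels at least eight probe
sites away from the unit (5/5 above/below when available, shifted near
array edges).  Band-pass filtering uses a zero-phase linear-phase FIR
(symmetric kernel applied centered, Hamming design, ~53 dB stop-band);
instantaneous phase is the Hilbert angle.  Oscillation cycles in which the
phase does not increase monotonically are rejected whole, and all phase
statistics use only valid samples, with the rejected time per delay
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, filtfilt, firwin, hilbert, iirnotch, welch

from .core_model import LFPSignal, Session, TrialTable, Unit
from .decoding import ClassifierSpec, DecodingResult, loo_cv, standardize_columns
from .synthetic_session import BANDS

__all__ = [
    "PhaseSeries",
    "PhaseStats",
    "lfp_channel_qc",
    "reference_lfp_for_unit",
    "band_phase",
    "delay_spectrogram",
    "spike_phases",
    "phase_locking_stats",
    "rayleigh_test",
    "goal_phase_shuffle_test",
    "phase_bin_decoding",
    "unit_phase_series",
]

#: minimum probe-site distance between a unit and its reference channels
REFERENCE_MIN_DISTANCE = 8
REFERENCE_N_CHANNELS = 10


def lfp_channel_qc(lfp: LFPSignal) -> np.ndarray:
    """Retained channel positions after the sd-based quality screen.

    Channels whose sample standard deviation is below 1/4 of the mean sd
    (flat/reference channels) or above 4x the mean sd (noisy channels) are
    removed.
    """
    if lfp.samples.shape[0] < 2:
        raise ValueError("need at least 2 LFP channels")
    sd = lfp.samples.std(axis=1)
    mean_sd = sd.mean()
    keep = (sd >= mean_sd / 4.0) & (sd <= 4.0 * mean_sd)
    if not keep.any():
        raise ValueError("channel QC removed every channel")
    return np.flatnonzero(keep)


def reference_lfp_for_unit(
    lfp: LFPSignal,
    unit: Unit,
    retained: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of 10 QC-passing channels >= 8 sites from the unit's channel.

    The split is 5 above / 5 below when possible; near an array edge the
    split shifts (e.g. 8 above / 2 below) while keeping 10 channels total.
    """
    if retained is None:
        retained = lfp_channel_qc(lfp)
    sites = lfp.channel_indices[retained]
    delta = sites - unit.channel_index
    above = retained[delta >= REFERENCE_MIN_DISTANCE]
    below = retained[delta <= -REFERENCE_MIN_DISTANCE]
    # nearest-first within each side
    above = above[np.argsort(np.abs(lfp.channel_indices[above] - unit.channel_index))]
    below = below[np.argsort(np.abs(lfp.channel_indices[below] - unit.channel_index))]
    if above.size + below.size < REFERENCE_N_CHANNELS:
        raise ValueError(
            f"unit {unit.unit_id}: only {above.size} channels above and "
            f"{below.size} below at distance >= {REFERENCE_MIN_DISTANCE}; "
            f"need {REFERENCE_N_CHANNELS}")
    half = REFERENCE_N_CHANNELS // 2
    n_above = min(above.size, max(half, REFERENCE_N_CHANNELS - below.size))
    n_below = REFERENCE_N_CHANNELS - n_above
    chosen = np.concatenate([above[:n_above], below[:n_below]])
    return lfp.samples[chosen].mean(axis=0)


@dataclass
class PhaseSeries:
    """Per-delay instantaneous phase (radians, (-pi, pi]) with validity mask."""

    band: tuple[float, float]
    fs: float
    delay_on: np.ndarray            # absolute start time of each delay (s)
    phase: list                     # per delay, (n_samples,) wrapped phase
    valid: list                     # per delay, boolean mask
    valid_duration: np.ndarray      # s per delay

    @property
    def n_delays(self) -> int:
        return len(self.phase)

    def rejected_duration(self) -> np.ndarray:
        return np.asarray([p.size / self.fs for p in self.phase]) - self.valid_duration


def _fir_kernel(band: tuple[float, float], fs: float, pad: float) -> np.ndarray:
    low, high = band
    if high >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist for fs={fs}")
    transition = max(0.5, 0.4 * low)
    numtaps = int(round(3.3 * fs / transition))
    numtaps = min(numtaps, 2 * int(pad * fs) - 1)  # kernel must fit in the padding
    numtaps |= 1
    return firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def _reject_nonmonotonic(theta: np.ndarray) -> np.ndarray:
    """Validity mask: whole cycles containing any phase decrease are rejected.

    Cycle boundaries are the phase wrap points; a sample where the unwrapped
    phase does not strictly increase marks its whole cycle invalid.
    """
    valid = np.ones(theta.size, dtype=bool)
    if theta.size < 2:
        return valid
    d = np.diff(theta)
    wraps = np.flatnonzero(d < -np.pi)  # boundary between cycles
    bad = np.flatnonzero((d <= 0) & (d >= -np.pi))  # genuine decrease, not a wrap
    if bad.size == 0:
        return valid
    bounds = np.concatenate([[0], wraps + 1, [theta.size]])
    bad_cycle = np.searchsorted(bounds, bad, side="right") - 1
    for c in np.unique(bad_cycle):
        valid[bounds[c]:bounds[c + 1]] = False
    return valid


def band_phase(
    trace: np.ndarray,
    band: tuple[float, float],
    trials: TrialTable,
    fs: float,
    pad: float = 3.0,
) -> PhaseSeries:
    """Band-limited instantaneous phase of each delay period.

    Each delay is filtered with padding on both sides (only the unpadded
    delay is retained), the Hilbert angle gives the phase, and
    non-monotonic cycles are masked invalid.
    """
    kernel = _fir_kernel(band, fs, pad)
    phases, valids, durations = [], [], []
    for trial in trials:
        i0 = int(round((trial.t_delay_on - pad) * fs))
        i1 = int(round((trial.t_delay_off + pad) * fs))
        if i0 < 0 or i1 > trace.size:
            raise ValueError(f"trace does not cover padded delay of trial {trial.index}")
        seg = fftconvolve(trace[i0:i1].astype(float), kernel, mode="same")
        theta = np.angle(hilbert(seg))
        cut0 = int(round(pad * fs))
        cut1 = cut0 + int(round(trials.delay_duration * fs))
        theta = theta[cut0:cut1]
        mask = _reject_nonmonotonic(theta)
        phases.append(theta)
        valids.append(mask)
        durations.append(mask.sum() / fs)
    return PhaseSeries(band=band, fs=fs, delay_on=trials.delay_on,
                       phase=phases, valid=valids,
                       valid_duration=np.asarray(durations))


def delay_spectrogram(
    lfp: LFPSignal,
    trials: TrialTable,
    n_bins: int = 31,
    freq_range: tuple[float, float] = (1.0, 100.0),
    channel: int | None = None,
) -> pd.DataFrame:
    """Mean delay-period power in logarithmically spaced frequency bins.

    The trace (one channel, or the mean of QC-retained channels) is
    60 Hz notch-filtered, Welch power spectra are computed per delay and
    averaged, then pooled into ``n_bins`` log-spaced bins.
    """
    if channel is None:
        trace = lfp.samples[lfp_channel_qc(lfp)].mean(axis=0)
    else:
        trace = lfp.samples[channel].astype(float)
    b, a = iirnotch(60.0, Q=30.0, fs=lfp.fs)
    trace = filtfilt(b, a, trace)
    psds = []
    for trial in trials:
        i0 = int(round(trial.t_delay_on * lfp.fs))
        i1 = int(round(trial.t_delay_off * lfp.fs))
        seg = trace[i0:i1]
        nper = min(seg.size, int(2 * lfp.fs))
        f, p = welch(seg, fs=lfp.fs, nperseg=nper)
        psds.append(p)
    psd = np.mean(psds, axis=0)
    edges = np.logspace(np.log10(freq_range[0]), np.log10(freq_range[1]), n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    power = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = (f >= edges[k]) & (f < edges[k + 1])
        if sel.any():
            power[k] = psd[sel].mean()
    return pd.DataFrame({"freq_hz": centers, "power": power})


def spike_phases(
    unit: Unit, series: PhaseSeries, trials: TrialTable
) -> list[np.ndarray]:
    """Per-delay arrays of valid spike phases for one unit."""
    out = []
    for k, trial in enumerate(trials):
        sel = (unit.spike_times >= trial.t_delay_on) & \
              (unit.spike_times < trial.t_delay_off)
        idx = np.floor((unit.spike_times[sel] - trial.t_delay_on) * series.fs).astype(int)
        idx = np.clip(idx, 0, series.phase[k].size - 1)
        ok = series.valid[k][idx]
        out.append(series.phase[k][idx[ok]])
    return out


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: (r, p).

    Uses the standard small-sample-corrected approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = n*r.
    """
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        return np.nan, np.nan
    r = float(np.abs(np.mean(np.exp(1j * phases))))
    R = n * r
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))
    return r, min(p, 1.0)


@dataclass
class PhaseStats:
    """Resultant vector lengths and mean phases, overall and per goal."""

    unit_id: int
    r_overall: float
    mean_phase: float
    p_rayleigh: float
    n_spikes: int
    r_by_goal: dict
    mean_phase_by_goal: dict


def _resultant(phases: np.ndarray) -> tuple[float, float]:
    if phases.size == 0:
        return np.nan, np.nan
    v = np.mean(np.exp(1j * phases))
    return float(np.abs(v)), float(np.angle(v))


def phase_locking_stats(
    unit: Unit,
    series: PhaseSeries,
    trials: TrialTable,
    by_goal: bool = True,
) -> PhaseStats:
    """Resultant vector length of a unit's delay spike phases.

    r in [0, 1] is the magnitude of the mean unit phase vector; 1 means
    perfect locking.  Overall locking significance is the Rayleigh test.
    Classes with zero spikes get NaN (missing), not zero.
    """
    per_delay = spike_phases(unit, series, trials)
    all_phases = np.concatenate(per_delay) if per_delay else np.array([])
    r, mu = _resultant(all_phases)
    _, p = rayleigh_test(all_phases)
    r_by_goal, mu_by_goal = {}, {}
    if by_goal:
        goals = trials.goals
        for g in (1, 2, 3):
            ph = [per_delay[k] for k in np.flatnonzero(goals == g)]
            ph = np.concatenate(ph) if ph else np.array([])
            r_by_goal[g], mu_by_goal[g] = _resultant(ph)
    return PhaseStats(unit_id=unit.unit_id, r_overall=r, mean_phase=mu,
                      p_rayleigh=p, n_spikes=int(all_phases.size),
                      r_by_goal=r_by_goal, mean_phase_by_goal=mu_by_goal)


def goal_phase_shuffle_test(
    phases_by_cell_delay: list,
    goals: np.ndarray,
    n_shuffle: int = 100,
    seed: int = 0,
) -> float:
    """Shuffle test of goal-specific phase locking.

    ``phases_by_cell_delay[c][k]`` holds the valid spike phases of cell
    ``c`` in delay ``k``.  The observed per-(cell, goal) resultant vector
    lengths are compared (two-sample Kolmogorov-Smirnov) with the pooled
    distribution obtained after shuffling the delay goal labels (one label
    permutation per shuffle, applied to all cells).
    """
    from scipy.stats import ks_2samp

    goals = np.asarray(goals)
    if np.unique(goals).size < 2:
        raise ValueError("need >= 2 goal classes")
    rng = np.random.default_rng(seed)

    def r_values(labels):
        vals = []
        for per_delay in phases_by_cell_delay:
            for g in np.unique(labels):
                ph = [per_delay[k] for k in np.flatnonzero(labels == g)]
                ph = np.concatenate(ph) if ph else np.array([])
                if ph.size:
                    vals.append(np.abs(np.mean(np.exp(1j * ph))))
        return np.asarray(vals)

    actual = r_values(goals)
    shuffled = np.concatenate([r_values(rng.permutation(goals))
                               for _ in range(n_shuffle)])
    if actual.size == 0 or shuffled.size == 0 or \
            (np.ptp(actual) == 0 and np.ptp(shuffled) == 0):
        warnings.warn("degenerate resultant-length distributions; p = 1")
        return 1.0
    return float(ks_2samp(actual, shuffled).pvalue)


def unit_phase_series(
    session: Session,
    band: tuple[float, float],
    pad: float = 3.0,
) -> dict[int, PhaseSeries]:
    """Per-unit delay phase series using each unit's reference LFP.

    Units whose probe geometry does not admit the 10-channel reference rule
    (small synthetic arrays) fall back to the mean of all QC-retained
    channels as a single shared reference trace.
    """
    if session.lfp is None:
        raise ValueError("session has no LFP; phase analysis unavailable")
    lfp = session.lfp
    retained = lfp_channel_qc(lfp)
    trials = session.trial_table
    out: dict[int, PhaseSeries] = {}
    shared: PhaseSeries | None = None
    for u in session.units:
        try:
            trace = reference_lfp_for_unit(lfp, u, retained)
            out[u.unit_id] = band_phase(trace, band, trials, lfp.fs, pad)
        except ValueError:
            if shared is None:
                trace = lfp.samples[retained].mean(axis=0)
                shared = band_phase(trace, band, trials, lfp.fs, pad)
            out[u.unit_id] = shared
    return out


def _phase_bin_index(theta: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index with bins centered so bin 0 spans [-pi/n, pi/n)."""
    width = 2 * np.pi / n_bins
    return (np.floor((theta + width / 2) / width).astype(int)) % n_bins


def phase_bin_decoding(
    session: Session,
    band: tuple[float, float],
    n_bins: int = 6,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    correct_only: bool = True,
    series_by_unit: dict | None = None,
) -> DecodingResult:
    """Goal decoding from duration-normalized phase-binned spike counts.

    Features are, per cell and phase bin, the number of delay spikes at
    phases in that bin divided by the delay's total valid duration, then
    z-scored over delays; classification is logistic-regression LOO-CV with
    balancing.  Delays with zero valid duration are dropped with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    trials = session.trial_table
    if series_by_unit is None:
        series_by_unit = unit_phase_series(session, band)
    n_trials = len(trials)
    n_cells = len(session.units)
    feats = np.zeros((n_trials, n_cells * n_bins))
    valid_dur = None
    for j, u in enumerate(session.units):
        series = series_by_unit[u.unit_id]
        if valid_dur is None:
            valid_dur = series.valid_duration
        per_delay = spike_phases(u, series, trials)
        for k in range(n_trials):
            if series.valid_duration[k] <= 0:
                continue
            idx = _phase_bin_index(per_delay[k], n_bins)
            counts = np.bincount(idx, minlength=n_bins)
            feats[k, j * n_bins:(j + 1) * n_bins] = counts / series.valid_duration[k]

    keep = valid_dur > 0
    mask = trials.correct if correct_only else np.ones(n_trials, bool)
    dropped = int(np.sum(mask & ~keep))
    if dropped:
        warnings.warn(f"dropping {dropped} delay(s) with zero valid duration")
    mask = mask & keep
    X, _, _ = standardize_columns(feats[mask])
    labels = trials.goals[mask]
    return loo_cv(X, labels, spec or ClassifierSpec("lr"), seed=seed,
                  trial_indices=np.flatnonzero(mask),
                  groups=trials.starts[mask])
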