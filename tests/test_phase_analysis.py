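"""phase_analysis: filtering/phase oracles, reference geometry, statistics."""

import dataclasses

import numpy as np
import pytest

import flexgoal as fg
from flexgoal.phase_analysis import (
    REFERENCE_MIN_DISTANCE,
    _phase_bin_index,
    _reject_nonmonotonic,
    band_phase,
    delay_spectrogram,
    goal_phase_shuffle_test,
    lfp_channel_qc,
    phase_bin_decoding,
    phase_locking_stats,
    rayleigh_test,
    reference_lfp_for_unit,
    spike_phases,
    unit_phase_series,
)

FS = 1000.0


def _one_trial_table(trials108, on=6.0, off=9.0):
    t = dataclasses.replace(
        trials108[0], t_sample_goal_arrival=2.0, t_center_arrival=4.0,
        t_delay_on=on, t_delay_off=off, t_choice_entry=off + 1.0,
        t_test_goal_arrival=off + 2.0)
    return fg.TrialTable([t], off - on)


def _unit(spikes, unit_id=0, channel=0):
    spikes = np.sort(np.asarray(spikes, float))
    return fg.Unit(unit_id=unit_id, spike_times=spikes, waveform_width=0.6,
                   mean_rate=1.0, channel_index=channel)


# ---------------------------------------------------------------------------
# band phase on a pure sinusoid
# ---------------------------------------------------------------------------

def test_band_phase_pure_sinusoid(trials108):
    f0 = 8.0
    t = np.arange(0.0, 15.0, 1.0 / FS)
    trace = np.sin(2 * np.pi * f0 * t)
    table = _one_trial_table(trials108)
    series = band_phase(trace, (5.0, 12.0), table, FS)
    assert series.n_delays == 1
    theta = series.phase[0]
    assert theta.size == 3000
    # no cycle rejected on a clean oscillation
    assert series.valid[0].all()
    assert series.valid_duration[0] == pytest.approx(3.0)
    assert series.rejected_duration()[0] == pytest.approx(0.0)
    # instantaneous frequency: mean unwrapped slope = 2*pi*f0
    slope = np.diff(np.unwrap(theta)).mean() * FS
    assert slope == pytest.approx(2 * np.pi * f0, rel=1e-3)
    # analytic phase of sin(w t) is w t - pi/2 (Hilbert convention)
    k = 1500  # delay midpoint, far from filter edges
    expected = (2 * np.pi * f0 * (6.0 + k / FS) - np.pi / 2 + np.pi) \
        % (2 * np.pi) - np.pi
    assert theta[k] == pytest.approx(expected, abs=0.02)


def test_band_phase_errors(trials108):
    table = _one_trial_table(trials108)
    with pytest.raises(ValueError, match="Nyquist"):
        band_phase(np.zeros(15000), (5.0, 600.0), table, FS)
    with pytest.raises(ValueError, match="cover"):
        band_phase(np.zeros(100), (5.0, 12.0), table, FS)


# ---------------------------------------------------------------------------
# non-monotonic cycle rejection
# ---------------------------------------------------------------------------

def _sawtooth(n_cycles, per_cycle):
    ramp = np.linspace(-np.pi, np.pi, per_cycle, endpoint=False)
    return np.tile(ramp, n_cycles)


def test_reject_nonmonotonic_clean():
    theta = _sawtooth(5, 40)
    assert _reject_nonmonotonic(theta).all()
    assert _reject_nonmonotonic(np.array([0.1])).all()


def test_reject_nonmonotonic_masks_whole_cycle():
    theta = _sawtooth(5, 40).copy()
    theta[85] = theta[84] - 0.3  # one decrease inside the third cycle
    mask = _reject_nonmonotonic(theta)
    assert not mask[80:120].any()          # whole offending cycle rejected
    assert mask[:80].all() and mask[120:].all()


def test_reject_nonmonotonic_wrap_not_a_slip():
    # a wrap (drop by ~2*pi) separates cycles and is not itself a decrease
    theta = _sawtooth(3, 40)
    assert _reject_nonmonotonic(theta).all()


# ---------------------------------------------------------------------------
# channel QC and reference geometry
# ---------------------------------------------------------------------------

def test_lfp_channel_qc_rules():
    rng = np.random.default_rng(12)
    samples = rng.normal(size=(12, 2000))
    samples[3] *= 0.01   # flat channel
    samples[7] *= 30.0   # noisy channel
    lfp = fg.LFPSignal(fs=FS, samples=samples, channel_indices=np.arange(12))
    keep = lfp_channel_qc(lfp)
    assert 3 not in keep and 7 not in keep
    assert keep.size == 10
    with pytest.raises(ValueError):
        lfp_channel_qc(fg.LFPSignal(fs=FS, samples=samples[:1],
                                    channel_indices=np.arange(1)))


def _constant_lfp(n_channels):
    # channel c holds the constant value c: reference means are readable
    samples = np.repeat(np.arange(n_channels, dtype=float)[:, None], 100, axis=1)
    return fg.LFPSignal(fs=FS, samples=samples,
                        channel_indices=np.arange(n_channels))


def test_reference_lfp_balanced_split():
    lfp = _constant_lfp(40)
    ref = reference_lfp_for_unit(lfp, _unit([1.0], channel=20),
                                 retained=np.arange(40))
    # 5 above (28..32) and 5 below (12..8), nearest-first
    assert ref[0] == pytest.approx(np.mean([28, 29, 30, 31, 32, 12, 11, 10, 9, 8]))


def test_reference_lfp_edge_shifted_split():
    lfp = _constant_lfp(40)
    # unit at channel 2: nothing >= 8 sites below -> 10 channels from above
    ref = reference_lfp_for_unit(lfp, _unit([1.0], channel=2),
                                 retained=np.arange(40))
    assert ref[0] == pytest.approx(np.mean(np.arange(10, 20)))
    # mirrored at the top edge
    ref2 = reference_lfp_for_unit(lfp, _unit([1.0], channel=37),
                                  retained=np.arange(40))
    assert ref2[0] == pytest.approx(np.mean(np.arange(20, 30)))


def test_reference_lfp_too_few_channels():
    lfp = _constant_lfp(12)
    with pytest.raises(ValueError, match=f">= {REFERENCE_MIN_DISTANCE}"):
        reference_lfp_for_unit(lfp, _unit([1.0], channel=6),
                               retained=np.arange(12))


def test_unit_phase_series_shared_fallback(lfp_session):
    # units whose probe position cannot satisfy the 10-channel reference
    # rule all share one fallback series; the rest get their own
    session, _ = lfp_session
    from flexgoal.phase_analysis import lfp_channel_qc as qc
    retained = qc(session.lfp)
    series = unit_phase_series(session, (5.0, 12.0))
    assert set(series) == set(session.cell_ids)
    fallback, own = [], []
    for u in session.units:
        try:
            reference_lfp_for_unit(session.lfp, u, retained)
            own.append(series[u.unit_id])
        except ValueError:
            fallback.append(series[u.unit_id])
    assert fallback, "fixture should have at least one fallback unit"
    assert all(s is fallback[0] for s in fallback)
    for s in own:
        assert s is not fallback[0]


# ---------------------------------------------------------------------------
# Rayleigh test and locking stats
# ---------------------------------------------------------------------------

def test_rayleigh_uniform_vs_concentrated():
    grid = np.linspace(-np.pi, np.pi, 60, endpoint=False)
    r, p = rayleigh_test(grid)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=0.05)
    r2, p2 = rayleigh_test(np.full(40, 1.2) + 0.05 * np.random.default_rng(1).normal(size=40))
    assert r2 > 0.99 and p2 < 1e-10
    r3, p3 = rayleigh_test(np.array([]))
    assert np.isnan(r3) and np.isnan(p3)


def test_rayleigh_matches_formula():
    rng = np.random.default_rng(13)
    phases = rng.vonmises(0.0, 1.0, 50)
    r, p = rayleigh_test(phases)
    n = phases.size
    R = n * np.abs(np.mean(np.exp(1j * phases)))
    assert r == pytest.approx(R / n)
    assert p == pytest.approx(
        np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))


def test_phase_locking_spikes_at_peaks(trials108):
    f0 = 8.0
    t = np.arange(0.0, 15.0, 1.0 / FS)
    trace = np.sin(2 * np.pi * f0 * t)
    table = _one_trial_table(trials108)
    series = band_phase(trace, (5.0, 12.0), table, FS)
    # spikes at every oscillation peak inside the delay
    peaks = 6.0 + (np.arange(2, 22) + 0.25) / f0
    locked = _unit(peaks)
    stats = phase_locking_stats(locked, series, table, by_goal=False)
    assert stats.r_overall > 0.99
    assert stats.p_rayleigh < 1e-6
    assert stats.n_spikes == 20
    # uniformly spread spikes: weak resultant
    uniform = _unit(np.linspace(6.01, 8.99, 200))
    stats_u = phase_locking_stats(uniform, series, table, by_goal=False)
    assert stats_u.r_overall < 0.2


def test_spike_phases_respect_validity(trials108):
    table = _one_trial_table(trials108)
    series = band_phase(np.sin(2 * np.pi * 8.0 * np.arange(0, 15, 1 / FS)),
                        (5.0, 12.0), table, FS)
    series.valid[0][:] = False  # reject everything
    out = spike_phases(_unit([6.5, 7.0]), series, table)
    assert out[0].size == 0


def test_phase_locking_empty_goal_nan(trials108):
    table = _one_trial_table(trials108)  # single trial -> two goals unseen
    series = band_phase(np.sin(2 * np.pi * 8.0 * np.arange(0, 15, 1 / FS)),
                        (5.0, 12.0), table, FS)
    stats = phase_locking_stats(_unit([6.5]), series, table)
    seen = table.goals[0]
    for g in (1, 2, 3):
        if g != seen:
            assert np.isnan(stats.r_by_goal[g])


# ---------------------------------------------------------------------------
# spectrogram
# ---------------------------------------------------------------------------

def test_delay_spectrogram_peak_and_notch(trials108):
    t = np.arange(0.0, 15.0, 1.0 / FS)
    trace = np.sin(2 * np.pi * 8.0 * t) + np.sin(2 * np.pi * 60.0 * t)
    lfp = fg.LFPSignal(fs=FS, samples=np.vstack([trace, trace]),
                       channel_indices=np.array([0, 1]))
    table = _one_trial_table(trials108)
    df = delay_spectrogram(lfp, table, channel=0)
    assert list(df.columns) == ["freq_hz", "power"]
    assert len(df) == 31
    peak_bin = df.loc[df["power"].idxmax()]
    assert 6.0 < peak_bin["freq_hz"] < 10.0
    # the 60 Hz line is notched out: far below the theta peak
    at60 = df.iloc[(df["freq_hz"] - 60.0).abs().idxmin()]["power"]
    assert at60 < 1e-3 * peak_bin["power"]


# ---------------------------------------------------------------------------
# goal-phase shuffle test
# ---------------------------------------------------------------------------

def _phases_with_goal_effect(goals, kappa_preferred, seed=0):
    rng = np.random.default_rng(seed)
    cells = []
    for c in range(6):
        per_delay = []
        for g in goals:
            if g == 1 and kappa_preferred > 0:
                per_delay.append(rng.vonmises(0.0, kappa_preferred, 30))
            else:
                per_delay.append(rng.uniform(-np.pi, np.pi, 30))
        cells.append(per_delay)
    return cells


def test_shuffle_test_detects_goal_specific_locking(trials108):
    goals = trials108.goals[:30]
    p = goal_phase_shuffle_test(_phases_with_goal_effect(goals, 4.0), goals,
                                n_shuffle=60, seed=1)
    assert p < 0.05


def test_shuffle_test_deterministic_and_degenerate(trials108):
    goals = trials108.goals[:30]
    cells = _phases_with_goal_effect(goals, 0.0)
    p1 = goal_phase_shuffle_test(cells, goals, n_shuffle=40, seed=5)
    p2 = goal_phase_shuffle_test(cells, goals, n_shuffle=40, seed=5)
    assert p1 == p2
    empty = [[np.array([])] * 30]
    with pytest.warns(UserWarning, match="degenerate"):
        assert goal_phase_shuffle_test(empty, goals, n_shuffle=5) == 1.0
    with pytest.raises(ValueError):
        goal_phase_shuffle_test(cells, np.ones(30, int))


# ---------------------------------------------------------------------------
# phase-bin features and decoding
# ---------------------------------------------------------------------------

def test_phase_bin_index_convention():
    # bin 0 is centered on phase 0: [-pi/6, pi/6) for 6 bins
    width = 2 * np.pi / 6
    theta = np.array([0.0, width / 2 - 1e-9, -width / 2,
                      -width / 2 - 1e-9, np.pi - 1e-9, -np.pi])
    idx = _phase_bin_index(theta, 6)
    assert idx[0] == 0 and idx[1] == 0
    assert idx[2] == 0  # lower edge is inclusive
    assert idx[3] == 5  # just below the lower edge wraps to the top bin
    assert idx[4] == 3 and idx[5] == 3  # +-pi land in the opposite bin
    assert set(_phase_bin_index(np.linspace(-np.pi, np.pi, 1000), 6)) == set(range(6))


def test_phase_bin_decoding_runs(lfp_session):
    session, _ = lfp_session
    res = phase_bin_decoding(session, (5.0, 12.0), seed=4)
    assert 0.0 <= res.accuracy <= 1.0
    assert res.trial_indices.size == session.trial_table.correct.sum()
    with pytest.raises(ValueError, match="n_bins"):
        phase_bin_decoding(session, (5.0, 12.0), n_bins=1)
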