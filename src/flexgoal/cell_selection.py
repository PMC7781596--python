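"""Preprocessing filters selecting stable, active, putative principal cells.

The filter battery runs in a fixed order: trial trimming, session-wide rate
stability, delay-period rate stability, minimum delay activity, and putative
interneuron exclusion.  Stability is assessed with ordinary least-squares
fits so that a cell selective for a single (pseudorandomly ordered) label is
not excluded, while cells with monotone drifts are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Session, TrialTable, Unit

__all__ = [
    "trim_initial_trials",
    "session_rate_stability",
    "delay_rate_stability",
    "delay_activity_minimum",
    "exclude_interneurons",
    "select_cells",
    "SelectionReport",
]

#: max |fit(last) - fit(first)| of the standardized 10 s-binned session rate
SESSION_STABILITY_THRESH = 1.0
SESSION_BIN = 10.0  # s

#: max |fit(last) - fit(first)| of the raw per-delay spike count regression
DELAY_STABILITY_THRESH = 1.4

#: defaults for interneuron exclusion; the conjunction of a short
#: peak-to-trough width and a high session rate.  These are package
#: defaults, configurable per dataset.
DEFAULT_WIDTH_MAX = 0.4   # ms
DEFAULT_RATE_MIN = 10.0   # Hz


def trim_initial_trials(session: Session, n_trim: int) -> Session:
    """Drop the first ``n_trim`` trials (settling-in period); data untouched."""
    n = len(session.trial_table)
    if not 0 <= n_trim < n:
        raise ValueError(f"n_trim {n_trim} out of range [0, {n})")
    if n_trim == 0:
        return session
    table = session.trial_table.subset(np.arange(n_trim, n))
    table.validate()
    return Session(trial_table=table, units=session.units, lfp=session.lfp,
                   tracking=session.tracking,
                   meta={**session.meta, "n_trimmed": n_trim})


def _ols_endpoint_diff(y: np.ndarray) -> float:
    """|fitted(last) - fitted(first)| of an OLS line of y on its index."""
    n = y.size
    if n < 2:
        return 0.0
    x = np.arange(n, dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(abs(slope) * (n - 1))


def session_rate_stability(
    unit: Unit, session_span: tuple[float, float]
) -> tuple[bool, float]:
    """Session-wide rate stability of one unit.

    The firing rate is computed in 10 s bins over the session, standardized
    (mean 0, sd 1 over bins), and an OLS line is fitted over the bin index;
    the unit passes iff the absolute difference between the fitted values at
    the last and first bin is at most 1.  A perfectly flat cell (sd 0) is
    maximally stable and passes with ``z_diff = 0``.
    """
    t0, t1 = session_span
    if t1 - t0 < 2 * SESSION_BIN:
        raise ValueError("session span must be at least 20 s")
    edges = np.arange(t0, t1 + 1e-9, SESSION_BIN)
    if edges[-1] < t1 - 1e-9:
        edges = np.append(edges, t1)  # final partial bin still a rate estimate
    counts = np.diff(np.searchsorted(unit.spike_times, edges))
    rates = counts / np.diff(edges)
    if np.ptp(rates) == 0:  # exactly flat; std() can return ~1e-17 here
        return True, 0.0
    sd = rates.std()
    z = (rates - rates.mean()) / sd
    z_diff = _ols_endpoint_diff(z)
    return z_diff <= SESSION_STABILITY_THRESH, z_diff


def delay_rate_stability(unit: Unit, trials: TrialTable) -> tuple[bool, float]:
    """Delay-period rate stability: OLS on raw per-delay spike counts.

    Counts are *not* standardized; the unit passes iff the fitted count
    difference between the last and first delay is at most 1.4 spikes.
    Because labels are pseudorandomly ordered, a stationary label-selective
    cell has near-zero slope and passes.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 delay periods")
    counts = (np.searchsorted(unit.spike_times, trials.delay_off)
              - np.searchsorted(unit.spike_times, trials.delay_on))
    fit_diff = _ols_endpoint_diff(counts.astype(float))
    return fit_diff <= DELAY_STABILITY_THRESH, fit_diff


def delay_activity_minimum(unit: Unit, trials: TrialTable) -> bool:
    """At least one spike in at least one-sixth of all delay periods (inclusive)."""
    n = len(trials)
    if n < 6:
        raise ValueError("need at least 6 delay periods")
    active = np.count_nonzero(
        np.searchsorted(unit.spike_times, trials.delay_off)
        > np.searchsorted(unit.spike_times, trials.delay_on))
    return active >= n / 6.0


def exclude_interneurons(
    units: list[Unit],
    width_max: float = DEFAULT_WIDTH_MAX,
    rate_min: float = DEFAULT_RATE_MIN,
) -> list[Unit]:
    """Remove putative fast-spiking interneurons.

    A unit is excluded only when *both* criteria hold: peak-to-trough
    waveform width below ``width_max`` and session mean rate above
    ``rate_min`` (the conjunction keeps narrow-but-slow and fast-but-broad
    cells).
    """
    if width_max <= 0 or rate_min <= 0:
        raise ValueError("thresholds must be positive")
    return [u for u in units
            if not (u.waveform_width < width_max and u.mean_rate > rate_min)]


@dataclass
class SelectionReport:
    """Per-stage unit counts and per-unit filter outcomes."""

    n_input: int
    n_after_stability: int
    n_principal: int
    session_stability: dict
    delay_stability: dict
    delay_activity: dict
    excluded_interneurons: list


def select_cells(
    session: Session,
    n_trim: int = 0,
    width_max: float = DEFAULT_WIDTH_MAX,
    rate_min: float = DEFAULT_RATE_MIN,
) -> tuple[Session, SelectionReport]:
    """Run the full filter battery; returns the filtered session and a report.

    Order is fixed: trim -> session stability -> delay stability -> delay
    activity -> interneuron exclusion.  The surviving unit set is invariant
    to the input unit ordering.
    """
    session = trim_initial_trials(session, n_trim)
    trials = session.trial_table
    duration = session.recording_duration()
    span = (0.0, duration)

    sess_res, delay_res, act_res = {}, {}, {}
    survivors = []
    for u in session.units:
        ok1, z = session_rate_stability(u, span)
        ok2, fd = delay_rate_stability(u, trials)
        ok3 = delay_activity_minimum(u, trials)
        sess_res[u.unit_id] = (ok1, z)
        delay_res[u.unit_id] = (ok2, fd)
        act_res[u.unit_id] = ok3
        if ok1 and ok2 and ok3:
            survivors.append(u)

    principal = exclude_interneurons(survivors, width_max, rate_min)
    excluded = [u.unit_id for u in survivors if u not in principal]
    report = SelectionReport(
        n_input=len(session.units),
        n_after_stability=len(survivors),
        n_principal=len(principal),
        session_stability=sess_res,
        delay_stability=delay_res,
        delay_activity=act_res,
        excluded_interneurons=excluded,
    )
    out = Session(trial_table=trials, units=principal, lfp=session.lfp,
                  tracking=session.tracking, meta=dict(session.meta))
    return out, report
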