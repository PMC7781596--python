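"""'Activity-silent' memory statistics: jitter-corrected covariance and CCSI.

Spike trains of same-preferred-goal cell pairs are binned at 10 ms; the raw
cross-covariance is corrected by subtracting its expectation under
independent within-50 ms-block permutations of each train's bins (interval
jitter), which removes covariance due to co-modulation slower than the
block.  The zero-lag statistic is the mean of the three lag bins around
zero.  The cross-correlation selectivity index (CCSI) is, per sign-
consistent pair class, the mean difference of this statistic between a
pair's preferred-goal trials and a matched subsample of the other trials.

The correction expectation can be computed exactly: the mean over
within-block permutations of a train equals its block-averaged version, so
the expected shuffled cross-covariance is the cross-covariance of the two
block-averaged trains (``method='exact'``).  ``method='permutation'`` draws
``n_shuffle`` explicit surrogates; its mean converges to the exact value.
"""

from __future__ import annotations

from dataclasses import dataclass

import zlib

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .core_model import Session, delay_windows, goal_arrival_windows, population_vector
from .single_cell_stats import kruskal_wallis_h_matrix

__all__ = [
    "PairStats",
    "goal_modulated_cells",
    "candidate_pairs",
    "jitter_corrected_xcov",
    "classify_pair_sign",
    "pair_covariances",
    "ccsi",
    "time_resolved_ccsi",
]

BINWIDTH = 0.010     # s, spike-count bins
JITTER = 0.050       # s, permutation block
ZERO_LAG_BINS = 1    # scalar = mean of lags -1..+1


def goal_modulated_cells(
    session: Session,
    alpha: float = 0.05,
    window_duration: float = 3.0,
    correct_only: bool = True,
) -> list[tuple[int, int]]:
    """Cells significantly goal-modulated at the sample goal, with preference.

    Modulation is a Kruskal-Wallis test of goal-arrival firing rates across
    the three goals at level ``alpha``; the preferred goal is the one with
    the highest mean rate (ties to the lowest goal index).
    """
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    windows = goal_arrival_windows(trials, window_duration)[mask]
    rates = population_vector(session, windows, trial_indices=np.flatnonzero(mask)).values
    goals = trials.goals[mask]
    _, p = kruskal_wallis_h_matrix(rates, goals)
    means = np.stack([rates[goals == g].mean(axis=0) for g in (1, 2, 3)])
    preferred = np.argmax(means, axis=0) + 1  # argmax ties -> lowest index
    cell_ids = session.cell_ids
    return [(int(cell_ids[j]), int(preferred[j]))
            for j in np.flatnonzero(p < alpha)]


def candidate_pairs(cells: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All unordered pairs sharing the same preferred goal: (a, b, goal)."""
    if len(cells) < 2:
        raise ValueError("need >= 2 selected cells")
    pairs = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if cells[i][1] == cells[j][1]:
                pairs.append((cells[i][0], cells[j][0], cells[i][1]))
    return pairs


def _bin_counts(spikes: np.ndarray, windows: np.ndarray, binwidth: float) -> np.ndarray:
    """(n_trials, n_bins) spike counts; final partial bin dropped."""
    nb = int(np.floor((windows[0, 1] - windows[0, 0]) / binwidth + 1e-9))
    edges = windows[:, 0:1] + binwidth * np.arange(nb + 1)[None, :]
    pos = np.searchsorted(spikes, edges.ravel()).reshape(edges.shape)
    return np.diff(pos, axis=1).astype(float)


def _block_average(X: np.ndarray, block: int) -> np.ndarray:
    """Replace each bin by its within-block mean (blocks of ``block`` bins)."""
    n = X.shape[1]
    out = np.empty_like(X)
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        out[:, sl] = X[:, sl].mean(axis=1, keepdims=True)
    return out


def _xcov_mat(A: np.ndarray, B: np.ndarray, max_lag: int) -> np.ndarray:
    """(n_trials, 2*max_lag+1) cross-covariance of centered rows, 1/N norm."""
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    out = np.empty((A.shape[0], 2 * max_lag + 1))
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            out[:, k] = np.einsum("ij,ij->i", Ac[:, :n - lag], Bc[:, lag:]) / n
        else:
            out[:, k] = np.einsum("ij,ij->i", Ac[:, -lag:], Bc[:, :n + lag]) / n
    return out


def _permute_within_blocks(X: np.ndarray, block: int, rng) -> np.ndarray:
    out = X.copy()
    n = X.shape[1]
    for start in range(0, n, block):
        end = min(start + block, n)
        perm = rng.permutation(end - start)
        out[:, start:end] = X[:, start + perm]
    return out


def jitter_corrected_xcov(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    windows: np.ndarray,
    binwidth: float = BINWIDTH,
    jitter: float = JITTER,
    n_shuffle: int = 1000,
    seed: int = 0,
    max_lag: int = 10,
    method: str = "exact",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial jitter-corrected cross-covariance and zero-lag scalar.

    Returns ``(traces, lags, scalars)``: corrected covariance at lags
    ``-max_lag..max_lag`` (bins of ``binwidth``) per trial, the lag axis in
    seconds, and the per-trial scalar (mean of the three bins around zero
    lag).  ``method='exact'`` uses the closed-form permutation expectation
    (block-averaged trains); ``'permutation'`` averages ``n_shuffle``
    explicit within-block bin permutations, drawn independently per cell.
    Empty trains give zero covariance.
    """
    windows = np.asarray(windows, float)
    if np.any(windows[:, 1] - windows[:, 0] < 0.5):
        raise ValueError("windows must be at least 0.5 s")
    block = int(round(jitter / binwidth))
    A = _bin_counts(np.asarray(spikes_a, float), windows, binwidth)
    B = _bin_counts(np.asarray(spikes_b, float), windows, binwidth)
    raw = _xcov_mat(A, B, max_lag)
    if method == "exact":
        correction = _xcov_mat(_block_average(A, block), _block_average(B, block),
                               max_lag)
    elif method == "permutation":
        rng = default_rng(seed)
        acc = np.zeros_like(raw)
        for _ in range(n_shuffle):
            As = _permute_within_blocks(A, block, rng)
            Bs = _permute_within_blocks(B, block, rng)
            acc += _xcov_mat(As, Bs, max_lag)
        correction = acc / n_shuffle
    else:
        raise ValueError("method must be 'exact' or 'permutation'")
    corrected = raw - correction
    lags = binwidth * np.arange(-max_lag, max_lag + 1)
    center = max_lag
    scalars = corrected[:, center - ZERO_LAG_BINS:center + ZERO_LAG_BINS + 1].mean(axis=1)
    return corrected, lags, scalars


def classify_pair_sign(
    pref_scalars: np.ndarray, nonpref_scalars: np.ndarray
) -> str:
    """'excitatory' (both means > 0), 'inhibitory' (both < 0), else 'discard'."""
    mp = float(np.mean(pref_scalars))
    mn = float(np.mean(nonpref_scalars))
    if mp > 0 and mn > 0:
        return "excitatory"
    if mp < 0 and mn < 0:
        return "inhibitory"
    return "discard"


@dataclass
class PairStats:
    """One pair's corrected covariance scalars and sign classification."""

    pair: tuple[int, int]
    preferred_goal: int
    scalars: np.ndarray          # per analyzed trial
    preferred_mask: np.ndarray   # per analyzed trial
    sign_class: str


def pair_covariances(
    session: Session,
    pairs: list[tuple[int, int, int]],
    windows: np.ndarray | None = None,
    correct_only: bool = True,
    sign_windows: np.ndarray | None = None,
    **xcov_kwargs,
) -> list[PairStats]:
    """Per-pair delay-window corrected covariances with sign classification.

    ``sign_windows`` (e.g. the extended -2..+5 s windows of the
    time-resolved variant) may differ from the analysis ``windows``; sign
    classes are computed from them, defaulting to ``windows`` themselves.
    """
    trials = session.trial_table
    mask = trials.correct if correct_only else np.ones(len(trials), bool)
    if windows is None:
        windows = delay_windows(trials)
    windows = np.asarray(windows)[mask]
    goals = trials.goals[mask]
    out = []
    for a, b, g in pairs:
        sa = session.unit_by_id(a).spike_times
        sb = session.unit_by_id(b).spike_times
        _, _, scalars = jitter_corrected_xcov(sa, sb, windows, **xcov_kwargs)
        pref = goals == g
        if sign_windows is not None:
            _, _, s_sign = jitter_corrected_xcov(
                sa, sb, np.asarray(sign_windows)[mask], **xcov_kwargs)
        else:
            s_sign = scalars
        sign = classify_pair_sign(s_sign[pref], s_sign[~pref]) \
            if pref.any() and (~pref).any() else "discard"
        out.append(PairStats(pair=(a, b), preferred_goal=g, scalars=scalars,
                             preferred_mask=pref, sign_class=sign))
    return out


def _pair_ccsi(p: PairStats, rng) -> float:
    pref = p.scalars[p.preferred_mask]
    nonpref = p.scalars[~p.preferred_mask]
    if nonpref.size > pref.size:
        nonpref = rng.choice(nonpref, size=pref.size, replace=False)
    elif pref.size > nonpref.size:
        pref = rng.choice(pref, size=nonpref.size, replace=False)
    return float(pref.mean() - nonpref.mean())


def ccsi(
    pairs: list[PairStats],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """CCSI per sign class with a bootstrap-over-pairs 95% CI.

    Per pair: mean preferred-trial scalar minus the mean of a trial-count-
    matched random subsample of non-preferred scalars.  The class CCSI is
    the mean over its pairs; the CI resamples pairs with replacement,
    redrawing the matching subsample each replicate.  Empty classes are
    reported as missing (NaN).
    """
    out = {}
    for sign in ("excitatory", "inhibitory"):
        members = [p for p in pairs if p.sign_class == sign]
        if not members:
            out[sign] = {"ccsi": np.nan, "ci": (np.nan, np.nan), "n_pairs": 0}
            continue
        rng = default_rng(SeedSequence((seed, zlib.crc32(sign.encode()) % 2 ** 16)))
        point = float(np.mean([_pair_ccsi(p, rng) for p in members]))
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(members), len(members))
            boot[b] = np.mean([_pair_ccsi(members[i], rng) for i in idx])
        out[sign] = {"ccsi": point,
                     "ci": (float(np.percentile(boot, 2.5)),
                            float(np.percentile(boot, 97.5))),
                     "n_pairs": len(members)}
    return out


def time_resolved_ccsi(
    session: Session,
    pairs: list[tuple[int, int, int]],
    window: float = 1.0,
    step: float = 0.050,
    t_range: tuple[float, float] = (-2.0, 5.0),
    correct_only: bool = True,
    n_boot: int = 200,
    seed: int = 0,
    **xcov_kwargs,
) -> pd.DataFrame:
    """CCSI in sliding windows around delay onset (t = 0 at nose poke).

    Sign classes come from the extended window covering the whole range, as
    in the time-resolved variant of the analysis.  Returns a frame of
    window start times and per-class CCSI with CIs; window count is
    ``floor((range - window)/step) + 1``.
    """
    trials = session.trial_table
    on = trials.delay_on
    extended = np.column_stack([on + t_range[0], on + t_range[1]])
    base = pair_covariances(session, pairs, windows=extended,
                            correct_only=correct_only, **xcov_kwargs)
    sign_by_pair = {p.pair: p.sign_class for p in base}

    n_windows = int(np.floor((t_range[1] - t_range[0] - window) / step + 1e-9)) + 1
    rows = []
    for k in range(n_windows):
        t0 = t_range[0] + k * step
        win = np.column_stack([on + t0, on + t0 + window])
        stats = pair_covariances(session, pairs, windows=win,
                                 correct_only=correct_only, **xcov_kwargs)
        for p in stats:
            p.sign_class = sign_by_pair[p.pair]
        res = ccsi(stats, n_boot=n_boot, seed=seed + k)
        rows.append({"t_start": t0,
                     "ccsi_excitatory": res["excitatory"]["ccsi"],
                     "ci_low_excitatory": res["excitatory"]["ci"][0],
                     "ci_high_excitatory": res["excitatory"]["ci"][1],
                     "ccsi_inhibitory": res["inhibitory"]["ccsi"],
                     "ci_low_inhibitory": res["inhibitory"]["ci"][0],
                     "ci_high_inhibitory": res["inhibitory"]["ci"][1]})
    return pd.DataFrame(rows)
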