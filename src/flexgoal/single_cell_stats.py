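"""Single-cell selectivity screen across task coding schemes.

Each (cell, time-bin) delay spike count is treated as one feature; its
distribution across trials is compared between classes (start, allocentric
goal, egocentric goal, or start x goal) with the Kruskal-Wallis rank test,
and discoveries are controlled per binwidth with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import Session, TrialTable, bin_aligned_counts
from .synthetic_session import ego_class

__all__ = [
    "class_labels",
    "kruskal_wallis_h",
    "kruskal_wallis_h_matrix",
    "fdr_bh",
    "hscore_screen",
    "HScoreResult",
    "default_binwidths",
]

SCHEMES = ("start", "goal", "ego", "start_x_goal")


def class_labels(trials: TrialTable, scheme: str, ego_offset: int = 0) -> np.ndarray:
    """Per-trial class labels for a coding scheme.

    ``start``/``goal``/``ego`` give 3 classes; ``start_x_goal`` gives the 9
    conjunction classes (encoded as ``3*(start-1) + goal``).  The egocentric
    class is ``(goal - start) mod 3`` under the identity-offset convention
    and is invariant to joint rotation of start and goal.
    """
    if scheme == "start":
        return trials.starts
    if scheme == "goal":
        return trials.goals
    if scheme == "ego":
        return ego_class(trials.goals, trials.starts, ego_offset)
    if scheme == "start_x_goal":
        return 3 * (trials.starts - 1) + trials.goals
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def kruskal_wallis_h(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p for lists of counts.

    H = 12 / (N(N+1)) * sum_g R_g^2 / n_g - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1
    degrees of freedom.  All-identical observations give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    sizes = np.asarray([g.size for g in groups])
    labels = np.repeat(np.arange(len(groups)), sizes)
    x = np.concatenate(groups)
    H, p = kruskal_wallis_h_matrix(x[:, None], labels)
    return float(H[0]), float(p[0])


def kruskal_wallis_h_matrix(
    X: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kruskal-Wallis over the columns of ``X``.

    Parameters
    ----------
    X : (n_samples, n_features)
    labels : (n_samples,) group labels (>= 2 distinct values).

    Returns per-feature (H, p).  Degenerate features whose tie correction is
    zero (every value identical) get H = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    k = classes.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = X.shape[0]
    ranks = stats.rankdata(X, axis=0)  # average ranks handle ties

    rank_sums = np.zeros((k, X.shape[1]))
    np.add.at(rank_sums, inv, ranks)
    counts = np.bincount(inv, minlength=k).astype(float)
    H = 12.0 / (n * (n + 1)) * ((rank_sums ** 2) / counts[:, None]).sum(axis=0) \
        - 3.0 * (n + 1)

    # tie correction per column: 1 - sum(t^3 - t) / (n^3 - n)
    Xs = np.sort(X, axis=0)
    new = np.vstack([np.ones((1, X.shape[1]), bool), np.diff(Xs, axis=0) != 0])
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):  # per-column run lengths
        idx = np.flatnonzero(new[:, j])
        t = np.diff(np.append(idx, n))
        tie_term[j] = np.sum(t ** 3 - t)
    corr = 1.0 - tie_term / (n ** 3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(corr > 0, H / corr, 0.0)
    H = np.maximum(H, 0.0)
    p = np.where(corr > 0, stats.chi2.sf(H, k - 1), 1.0)
    return H, p


def fdr_bh(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def default_binwidths(delay_duration: float) -> tuple[float, ...]:
    """Binwidth grid from 0.1 s doubling up to the full delay duration."""
    widths = []
    w = 0.1
    while w < delay_duration - 1e-9:
        widths.append(round(w, 4))
        w *= 2
    widths.append(delay_duration)
    return tuple(widths)


@dataclass
class HScoreResult:
    """Tidy (cell, bin, binwidth) table of H statistics and FDR calls."""

    table: pd.DataFrame  # columns: cell_id, bin, binwidth, H, p, significant
    scheme: str
    alpha: float

    def significant_cells(self, binwidth: float | None = None) -> np.ndarray:
        t = self.table
        if binwidth is not None:
            t = t[np.isclose(t["binwidth"], binwidth)]
        return np.unique(t.loc[t["significant"], "cell_id"])


def hscore_screen(
    session: Session,
    scheme: str,
    binwidths=None,
    alpha: float = 0.05,
    ego_offset: int | None = None,
) -> HScoreResult:
    """Kruskal-Wallis screen of delay spike counts across trial classes.

    For each binwidth, delay spikes are binned, each (cell, bin) feature is
    tested across the scheme's trial classes, and the BH mask is computed
    within that binwidth's family of tests.
    """
    trials = session.trial_table
    if ego_offset is None:
        ego_offset = int(session.meta.get("ego_offset", 0))
    labels = class_labels(trials, scheme, ego_offset)
    if binwidths is None:
        binwidths = default_binwidths(trials.delay_duration)
    cell_ids = session.cell_ids

    frames = []
    for bw in binwidths:
        counts = bin_aligned_counts(session.units, trials.delay_on,
                                    (0.0, trials.delay_duration), bw)
        n_trials, n_cells, n_bins = counts.shape
        X = counts.reshape(n_trials, n_cells * n_bins)
        H, p = kruskal_wallis_h_matrix(X, labels)
        sig = fdr_bh(p, alpha)
        frames.append(pd.DataFrame({
            "cell_id": np.repeat(cell_ids, n_bins),
            "bin": np.tile(np.arange(n_bins), n_cells),
            "binwidth": bw,
            "H": H, "p": p, "significant": sig,
        }))
    return HScoreResult(table=pd.concat(frames, ignore_index=True),
                        scheme=scheme, alpha=alpha)
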