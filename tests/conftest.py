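"""Shared fixtures: synthetic sessions reused across test modules.

All fixtures are session-scoped and deterministic (fixed seeds) so the
suite's runtime is dominated by the analyses, not the generators.
"""

import numpy as np
import pytest

import flexgoal as fg


@pytest.fixture(scope="session")
def trials108():
    """Four balanced blocks = 108 trials, 3.0 s delay."""
    return fg.generate_trial_sequence(4, seed=201)


@pytest.fixture(scope="session")
def null_session(trials108):
    """No injected structure: homogeneous Poisson cells at 3 Hz."""
    cfg = fg.SelectivityConfig(n_cells=30, seed=202, with_lfp=False)
    session, truth = fg.generate_session(trials108, cfg)
    return session, truth


@pytest.fixture(scope="session")
def start_session(trials108):
    """Start-selective session: the dissociation's test bed (no goal code)."""
    cfg = fg.SelectivityConfig(n_cells=40, frac_start_cells=0.3, seed=203,
                               with_lfp=False)
    session, truth = fg.generate_session(trials108, cfg)
    return session, truth


@pytest.fixture(scope="session")
def mixed_session(trials108):
    """Goal + start cells together (screen, embedding, covariance tests)."""
    cfg = fg.SelectivityConfig(n_cells=60, frac_goal_cells=0.2,
                               frac_start_cells=0.2, seed=204, with_lfp=False)
    session, truth = fg.generate_session(trials108, cfg)
    return session, truth


@pytest.fixture(scope="session")
def lfp_session():
    """Small LFP session: 27 trials, 6 cells, 3 of them theta-locked."""
    trials = fg.generate_trial_sequence(1, seed=205)
    plock = tuple((c, "theta", 2.0, 0.5, False) for c in range(3))
    cfg = fg.SelectivityConfig(n_cells=6, base_rate=5.0, seed=205,
                               phase_lock=plock, lfp_fs=1000.0,
                               n_lfp_channels=12)
    session, truth = fg.generate_session(trials, cfg)
    return session, truth


@pytest.fixture(scope="session")
def binomial_band():
    """Central 95% binomial band for an accuracy around p0 with n trials."""
    from scipy.stats import binom

    def band(n, p0=1.0 / 3.0, level=0.95):
        lo, hi = binom.interval(level, n, p0)
        return lo / n, hi / n

    return band
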