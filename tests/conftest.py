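"""Shared fixtures and an independent, naive DFA reference implementation."""

from __future__ import annotations

import numpy as np
import pytest


def naive_dfa_alpha(x, w_min=4, w_max=None):
    """Deliberately simple loop-based DFA used as an independent oracle.

    Kept free of any code shared with the package: plain Python loops,
    np.polyfit per window, residuals summed explicitly.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    profile = np.cumsum(x - np.mean(x))
    if w_max is None:
        w_max = n // 4
    log_w, log_f = [], []
    for w in range(w_min, w_max + 1):
        k = n // w
        sq = []
        for i in range(k):
            seg = profile[i * w : (i + 1) * w]
            idx = np.arange(w)
            a, b = np.polyfit(idx, seg, 1)
            resid = seg - (a * idx + b)
            sq.append(np.sum(resid**2) / w)
        f = np.sqrt(np.mean(sq))
        log_w.append(np.log10(w))
        log_f.append(np.log10(f))
    slope = np.polyfit(log_w, log_f, 1)[0]
    return slope


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def small_experiment():
    """A small deterministic two-condition synthetic experiment."""
    from stridepower import ExperimentSpec, generate_experiment

    return generate_experiment(ExperimentSpec(n_subjects=8, seed=5))
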