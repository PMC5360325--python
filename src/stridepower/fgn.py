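"""Exact fractional Gaussian noise synthesis and trial-SD calibration.

Fractional Gaussian noise (fGn) is the stationary increment process of
fractional Brownian motion; its autocovariance is

    gamma(k) = (sigma^2 / 2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

with Hurst exponent H in (0, 1).  For fGn the DFA scaling exponent alpha is
essentially H, so simulating fGn at a target alpha and re-estimating alpha
by DFA measures the sampling variability of the estimator at a given series
length — the "trial" variance component of a gait power analysis.

Synthesis uses circulant embedding (Davies–Harte): the autocovariance out to
lag n is embedded in a length-2n circulant whose eigenvalues are obtained by
FFT, and a draw with exactly that covariance is synthesised in the frequency
domain.  The method is exact, not approximate, and O(n log n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .dfa import dfa_alpha
from .exceptions import EmbeddingFailureError, InvalidInputError

__all__ = [
    "FGnSpec",
    "TrialSDTable",
    "fgn_autocovariance",
    "davies_harte",
    "davies_harte_sample",
    "estimate_trial_sd",
    "TRIAL_SD_DEFAULTS",
]

#: Calibrated trial-to-trial SD of DFA alpha at H = 0.9 for common stride
#: counts, as recomputed by :func:`estimate_trial_sd`.  Shipped so power runs
#: do not require recalibration.
TRIAL_SD_DEFAULTS = {100: 0.16, 150: 0.12, 200: 0.10}


@dataclass(frozen=True)
class FGnSpec:
    """Specification of one fGn draw."""

    hurst: float
    length: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.hurst < 1.0:
            raise InvalidInputError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.length < 2:
            raise InvalidInputError("length must be >= 2")
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be > 0")


@dataclass(frozen=True)
class TrialSDTable:
    """Across-replicate SD of DFA alpha per series length."""

    lengths: tuple[int, ...]
    sd_alpha: tuple[float, ...]
    hurst: float
    n_replicates: int

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.lengths, self.sd_alpha))


def fgn_autocovariance(hurst: float, max_lag: int, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) for k = 0..max_lag."""
    if not 0.0 < hurst < 1.0:
        raise InvalidInputError(f"hurst must be in (0, 1), got {hurst}")
    if max_lag < 0:
        raise InvalidInputError("max_lag must be >= 0")
    k = np.arange(max_lag + 1, dtype=float)
    two_h = 2.0 * hurst
    return 0.5 * sigma**2 * (
        np.abs(k + 1) ** two_h - 2 * np.abs(k) ** two_h + np.abs(k - 1) ** two_h
    )


def davies_harte(
    hurst: float,
    n: int,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one exact length-``n`` fGn sample by circulant embedding.

    The covariance gamma(0..n) is wrapped into a length-2n circulant; its
    eigenvalues (the real FFT of the first row) are nonnegative for fGn, and
    independent complex Gaussians scaled by sqrt(eigenvalue) synthesise the
    draw in the frequency domain.  The first ``n`` values of the inverse
    transform are returned.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 2:
        raise InvalidInputError("need n >= 2")
    gamma = fgn_autocovariance(hurst, n, sigma)
    # First row of the 2n circulant: gamma(0..n) then gamma(n-1..1).
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size  # 2n
    eigenvalues = np.fft.fft(row).real
    if eigenvalues.min() < -1e-8 * eigenvalues.max():
        raise EmbeddingFailureError(
            f"negative circulant eigenvalue {eigenvalues.min():.3e} "
            "(should not happen for fGn; implementation bug)"
        )
    eigenvalues = np.clip(eigenvalues, 0.0, None)

    # Hermitian-symmetric Gaussian spectrum: V[0], V[n] real; V[k] complex
    # with total variance lambda_k; V[m-k] = conj(V[k]).
    z_real = rng.standard_normal(n + 1)
    z_imag = rng.standard_normal(n - 1)
    v = np.empty(m, dtype=complex)
    v[0] = np.sqrt(eigenvalues[0]) * z_real[0]
    v[n] = np.sqrt(eigenvalues[n]) * z_real[n]
    half = np.sqrt(eigenvalues[1:n] / 2.0)
    v[1:n] = half * (z_real[1:n] + 1j * z_imag)
    v[n + 1 :] = np.conj(v[1:n][::-1])
    return np.fft.fft(v).real[:n] / np.sqrt(m)


def davies_harte_sample(spec: FGnSpec) -> np.ndarray:
    """Deterministic fGn draw for a fully specified :class:`FGnSpec`."""
    rng = substream(spec.seed, "fgn-sample", spec.length)
    return davies_harte(spec.hurst, spec.length, spec.sigma, rng)


def estimate_trial_sd(
    hurst: float,
    lengths,
    n_replicates: int = 1000,
    seed: int = 0,
) -> TrialSDTable:
    """Calibrate the trial-to-trial SD of DFA alpha per series length.

    For each length, ``n_replicates`` independent fGn series are generated
    and alpha is estimated with the default DFA window range [4, N/4]; the
    across-replicate sample SD of alpha is returned.  Replicate ``r`` at
    length ``l`` uses the independent substream ``(seed, l, r)`` so the table
    is reproducible regardless of evaluation order.
    """
    lengths = [int(l) for l in lengths]
    if any(l < 16 for l in lengths):
        raise InvalidInputError("all lengths must be >= 16")
    if n_replicates < 100:
        raise InvalidInputError("need n_replicates >= 100")
    sds = []
    for length in lengths:
        alphas = np.empty(n_replicates)
        for r in range(n_replicates):
            rng = substream(seed, "trial-sd", length, r)
            x = davies_harte(hurst, length, rng=rng)
            alphas[r] = dfa_alpha(x).alpha
        sds.append(float(np.std(alphas, ddof=1)))
    return TrialSDTable(
        lengths=tuple(lengths),
        sd_alpha=tuple(sds),
        hurst=hurst,
        n_replicates=n_replicates,
    )
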