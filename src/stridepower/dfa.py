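"""Detrended fluctuation analysis (DFA) with first-order local detrending.

DFA quantifies long-range correlation in a time series by integrating it,
splitting the profile into non-overlapping windows of size ``w``, removing
the local linear trend in each window, and measuring how the root-mean-square
residual fluctuation ``F(w)`` grows with ``w``.  The scaling exponent
``alpha`` is the slope of ``log10 F(w)`` against ``log10 w``: 0.5 for an
uncorrelated series, above 0.5 for a persistent one, below 0.5 for an
anti-persistent one.

The estimator here is tuned for the short stride-interval recordings common
in gait research: every integer window size between 4 strides and a quarter
of the series length enters an unweighted ordinary least squares fit on the
log-log plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateSeriesError,
    InsufficientScalesError,
    InvalidInputError,
    WindowSizeError,
)

__all__ = [
    "StrideSeries",
    "FluctuationCurve",
    "DFAEstimate",
    "integrate_profile",
    "local_detrended_variance",
    "fluctuation_function",
    "dfa_alpha",
]

MIN_WINDOW = 4
# N >= 16 admits the minimum window size 4; dfa_alpha additionally requires
# at least two admissible sizes (N >= 20) and raises otherwise.
MIN_SERIES_LENGTH = 16


@dataclass(frozen=True)
class StrideSeries:
    """One trial's stride-interval series with identifying labels.

    ``values`` are seconds per stride for physical recordings, but any finite
    real sequence (e.g. synthetic fractional Gaussian noise) is accepted.
    """

    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    trial_index: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise InvalidInputError("stride series must be one-dimensional")
        if values.size < MIN_SERIES_LENGTH:
            raise InvalidInputError(
                f"stride series needs >= {MIN_SERIES_LENGTH} samples, "
                f"got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("stride series contains non-finite values")
        if self.trial_index < 0:
            raise InvalidInputError("trial_index must be nonnegative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FluctuationCurve:
    """Window sizes ``w`` and fluctuation magnitudes ``F(w)`` for one series."""

    window_sizes: np.ndarray
    fluctuations: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.window_sizes, dtype=int)
        f = np.asarray(self.fluctuations, dtype=float)
        if w.shape != f.shape or w.ndim != 1:
            raise InvalidInputError("window_sizes and fluctuations must match")
        if np.any(np.diff(w) <= 0):
            raise InvalidInputError("window sizes must be strictly increasing")
        if np.any(f < 0):
            raise InvalidInputError("fluctuations must be nonnegative")
        object.__setattr__(self, "window_sizes", w)
        object.__setattr__(self, "fluctuations", f)


@dataclass(frozen=True)
class DFAEstimate:
    """Result of a DFA fit: the scaling exponent and fit diagnostics."""

    alpha: float
    intercept: float
    r_squared: float
    n_windows_used: int
    window_range: tuple[int, int]
    curve: FluctuationCurve | None = field(default=None, repr=False)


def integrate_profile(x) -> np.ndarray:
    """Cumulatively sum the mean-centred series (the DFA 'profile').

    Returns ``y[k] = sum_{i<=k} (x[i] - mean(x))``; the last element is zero
    up to round-off.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need a 1-d series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    return np.cumsum(x - x.mean())


def local_detrended_variance(y, w: int, *, backward: bool = False) -> np.ndarray:
    """Mean squared residual about the local linear trend, one value per window.

    The profile ``y`` is split into ``K = floor(N/w)`` non-overlapping windows
    anchored at the start; the trailing remainder is discarded.  An OLS line
    over the sample index is fitted in each window and the mean squared
    residual (divisor ``w``) is returned.

    With ``backward=True`` a second pass anchored at the end of the series is
    appended, so no samples are discarded overall (off by default).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    w = int(w)
    if w < MIN_WINDOW:
        raise WindowSizeError(f"window size must be >= {MIN_WINDOW}, got {w}")
    if w > n:
        raise WindowSizeError(f"window size {w} exceeds series length {n}")
    variances = _segment_variances(y[: (n // w) * w], w)
    if backward and n % w:
        variances = np.concatenate(
            [variances, _segment_variances(y[n - (n // w) * w :], w)]
        )
    return variances


def _segment_variances(y: np.ndarray, w: int) -> np.ndarray:
    # Detrend all K windows at once: residual = (I - H) y_window with H the
    # hat matrix of the two-column design [t, 1], shared across windows.
    segments = y.reshape(-1, w)
    t = np.arange(w, dtype=float)
    t_c = t - t.mean()
    means = segments.mean(axis=1, keepdims=True)
    slopes = (segments @ t_c) / (t_c @ t_c)
    residuals = segments - means - slopes[:, None] * t_c
    return np.einsum("ij,ij->i", residuals, residuals) / w


def fluctuation_function(y, window_sizes, *, backward: bool = False) -> FluctuationCurve:
    """Root-mean-square detrended fluctuation ``F(w)`` over the given windows.

    ``F(w)`` is the square root of the mean over windows of the local
    detrended variance.
    """
    y = np.asarray(y, dtype=float)
    sizes = np.unique(np.asarray(window_sizes, dtype=int))
    sizes = sizes[(sizes >= MIN_WINDOW) & (sizes <= y.size // 4)]
    if sizes.size < 2:
        raise InsufficientScalesError(
            "need at least 2 admissible window sizes in [4, N/4]"
        )
    fluct = np.array(
        [
            np.sqrt(local_detrended_variance(y, w, backward=backward).mean())
            for w in sizes
        ]
    )
    return FluctuationCurve(window_sizes=sizes, fluctuations=fluct)


def dfa_alpha(
    series,
    w_min: int = MIN_WINDOW,
    w_max: int | None = None,
    *,
    backward: bool = False,
    log_spaced: bool = False,
    n_scales: int = 20,
    keep_curve: bool = False,
) -> DFAEstimate:
    """Estimate the DFA scaling exponent of one series.

    Parameters
    ----------
    series : StrideSeries or array-like
        The raw (un-integrated) series.  Integration is always applied, as
        appropriate for noise-like signals such as stride intervals.
    w_min, w_max : int
        Window range; defaults to every integer size in ``[4, floor(N/4)]``.
    backward : bool
        Also run windows anchored at the end of the series (default off).
    log_spaced : bool
        Use ~``n_scales`` log-spaced window sizes instead of all integers.
    keep_curve : bool
        Attach the fluctuation curve to the returned estimate.

    Returns
    -------
    DFAEstimate
        ``alpha`` is the unweighted OLS slope of ``log10 F(w)`` on
        ``log10 w``; deterministic for fixed input.
    """
    x = series.values if isinstance(series, StrideSeries) else np.asarray(series, float)
    n = x.size
    limit = n // 4
    if w_max is None:
        w_max = limit
    if w_min < MIN_WINDOW:
        raise WindowSizeError(f"w_min must be >= {MIN_WINDOW}")
    if w_max > limit:
        raise WindowSizeError(f"w_max must be <= floor(N/4) = {limit}")
    if log_spaced:
        sizes = np.unique(
            np.round(np.geomspace(w_min, w_max, n_scales)).astype(int)
        )
    else:
        sizes = np.arange(w_min, w_max + 1)
    y = integrate_profile(x)
    curve = fluctuation_function(y, sizes, backward=backward)
    if np.any(curve.fluctuations == 0.0):
        raise DegenerateSeriesError(
            "zero fluctuation (constant series?); alpha undefined"
        )
    log_w = np.log10(curve.window_sizes)
    log_f = np.log10(curve.fluctuations)
    slope, intercept = np.polyfit(log_w, log_f, 1)
    ss_res = np.sum((log_f - (slope * log_w + intercept)) ** 2)
    ss_tot = np.sum((log_f - log_f.mean()) ** 2)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not np.isfinite(slope):
        raise DegenerateSeriesError("non-finite alpha")
    if not 0.0 <= slope <= 2.0:
        warnings.warn(
            f"DFA alpha = {slope:.3f} outside [0, 2]; check the input series",
            stacklevel=2,
        )
    return DFAEstimate(
        alpha=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        n_windows_used=int(curve.window_sizes.size),
        window_range=(int(curve.window_sizes[0]), int(curve.window_sizes[-1])),
        curve=curve if keep_curve else None,
    )
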