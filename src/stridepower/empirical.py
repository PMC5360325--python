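"""Observed power from a completed two-condition stride-time experiment.

Given one long stride-interval recording per subject per condition, the
recording is cut into non-overlapping windows of a fixed stride count, DFA
alpha is estimated per window and averaged per subject-condition, and the
observed power at a target sample size is the proportion of randomly drawn
subject subsets (without replacement within a subset) for which a paired
t-test on the two conditions rejects.  Sweeping the subset size yields an
empirical power curve directly comparable to an a-priori Monte Carlo or
analytic prediction for the same design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import substream
from .dfa import StrideSeries, dfa_alpha
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidSampleSizeError,
)

__all__ = [
    "StrideDataset",
    "WindowedAlphaTable",
    "EmpiricalPowerCurve",
    "split_nonoverlapping_windows",
    "windowed_alpha_table",
    "resample_observed_power",
    "empirical_power_curve",
]


@dataclass(frozen=True)
class StrideDataset:
    """One long stride series per subject per condition (two conditions)."""

    records: tuple[StrideSeries, ...]

    def __post_init__(self):
        by_key = {}
        for rec in self.records:
            key = (rec.subject_id, rec.condition)
            if key in by_key:
                raise InvalidInputError(
                    f"duplicate series for subject {rec.subject_id!r}, "
                    f"condition {rec.condition!r}"
                )
            by_key[key] = rec
        conditions = sorted({c for _, c in by_key})
        if len(conditions) != 2:
            raise InvalidInputError(
                f"expected exactly 2 conditions, got {conditions}"
            )
        subjects = sorted({s for s, _ in by_key})
        for s in subjects:
            for c in conditions:
                if (s, c) not in by_key:
                    raise InvalidInputError(
                        f"subject {s!r} missing condition {c!r}"
                    )
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "_by_key", by_key)
        object.__setattr__(self, "_subjects", tuple(subjects))
        object.__setattr__(self, "_conditions", tuple(conditions))

    @property
    def subjects(self) -> tuple[str, ...]:
        return self._subjects

    @property
    def conditions(self) -> tuple[str, ...]:
        return self._conditions

    def series(self, subject_id: str, condition: str) -> StrideSeries:
        return self._by_key[(subject_id, condition)]


@dataclass(frozen=True)
class WindowedAlphaTable:
    """Per-window and per-subject-mean DFA alphas for a windowed reanalysis."""

    window_length: int
    alphas: dict  # (subject_id, condition) -> tuple of per-window alpha
    subjects: tuple[str, ...]
    conditions: tuple[str, ...]

    def n_windows_used(self, subject_id: str, condition: str) -> int:
        return len(self.alphas[(subject_id, condition)])

    def mean_alpha(self, subject_id: str, condition: str) -> float:
        return float(np.mean(self.alphas[(subject_id, condition)]))

    def paired_differences(self) -> np.ndarray:
        """Per-subject mean-alpha difference, first condition minus second."""
        c1, c2 = self.conditions
        return np.array(
            [self.mean_alpha(s, c1) - self.mean_alpha(s, c2) for s in self.subjects]
        )


@dataclass(frozen=True)
class EmpiricalPowerCurve:
    """Observed power as a function of resampled subject-subset size."""

    sample_sizes: tuple[int, ...]
    observed_power: tuple[float, ...]
    n_resamples: int
    window_length: int
    n_windows: int
    test_level: float = 0.05
    seed: int = 0


def split_nonoverlapping_windows(
    series: StrideSeries,
    window_length: int,
    max_windows: int,
    offset: int = 0,
) -> list[StrideSeries]:
    """Cut ``min(max_windows, floor(N/window_length))`` consecutive windows.

    Windows are anchored at ``offset`` strides from the start (default 0);
    trailing strides that do not fill a window are discarded.
    """
    if window_length < 16:
        raise InvalidInputError("window_length must be >= 16")
    n_avail = len(series) - offset
    if n_avail < window_length:
        raise InsufficientDataError(
            f"series for subject {series.subject_id!r} has {n_avail} usable "
            f"strides; need at least {window_length}"
        )
    k = min(max_windows, n_avail // window_length)
    return [
        StrideSeries(
            values=series.values[
                offset + i * window_length : offset + (i + 1) * window_length
            ],
            subject_id=series.subject_id,
            condition=series.condition,
            trial_index=i,
        )
        for i in range(k)
    ]


def windowed_alpha_table(
    data: StrideDataset,
    window_length: int,
    n_windows: int,
    offset: int = 0,
) -> WindowedAlphaTable:
    """DFA alpha per window, per subject and condition.

    When a recording holds fewer than ``n_windows`` full windows, all
    available windows are used (the shortfall is visible through
    :meth:`WindowedAlphaTable.n_windows_used`).
    """
    alphas = {}
    for rec in data.records:
        try:
            windows = split_nonoverlapping_windows(
                rec, window_length, n_windows, offset
            )
            alphas[(rec.subject_id, rec.condition)] = tuple(
                dfa_alpha(w).alpha for w in windows
            )
        except InvalidInputError as exc:
            raise type(exc)(
                f"subject {rec.subject_id!r}, condition {rec.condition!r}: {exc}"
            ) from exc
    return WindowedAlphaTable(
        window_length=window_length,
        alphas=alphas,
        subjects=data.subjects,
        conditions=data.conditions,
    )


def resample_observed_power(
    table: WindowedAlphaTable,
    sample_size: int,
    n_resamples: int = 1000,
    test_level: float = 0.05,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Observed power at one subject-subset size.

    Draws ``n_resamples`` subsets of ``sample_size`` subjects uniformly
    without replacement (the same subset may recur across resamples), runs a
    paired two-sided t-test on the per-subject mean alphas, and returns the
    rejection proportion.
    """
    n_subjects = len(table.subjects)
    if not 2 <= sample_size <= n_subjects:
        raise InvalidSampleSizeError(
            f"sample_size must be in [2, {n_subjects}], got {sample_size}"
        )
    if rng is None:
        rng = substream(seed, "observed-power", sample_size)
    diffs = table.paired_differences()
    # One permutation per resample; the first sample_size entries are the
    # drawn subset (uniform over subsets without replacement).
    idx = np.argsort(
        rng.random((n_resamples, n_subjects)), axis=1
    )[:, :sample_size]
    sub = diffs[idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean / (sd / np.sqrt(sample_size))
    crit = stats.t.ppf(1.0 - test_level / 2.0, sample_size - 1)
    rejected = np.abs(t_stat) > crit
    return float(np.count_nonzero(rejected) / n_resamples)


def empirical_power_curve(
    table: WindowedAlphaTable,
    sample_sizes=tuple(range(3, 14)),
    n_resamples: int = 1000,
    test_level: float = 0.05,
    seed: int = 0,
) -> EmpiricalPowerCurve:
    """Observed power over a range of subject-subset sizes (shared seed)."""
    sizes = tuple(int(s) for s in sample_sizes)
    powers = tuple(
        resample_observed_power(
            table, s, n_resamples=n_resamples, test_level=test_level, seed=seed
        )
        for s in sizes
    )
    n_windows = max(
        table.n_windows_used(s, c)
        for s in table.subjects
        for c in table.conditions
    )
    return EmpiricalPowerCurve(
        sample_sizes=sizes,
        observed_power=powers,
        n_resamples=n_resamples,
        window_length=table.window_length,
        n_windows=n_windows,
        test_level=test_level,
        seed=seed,
    )
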