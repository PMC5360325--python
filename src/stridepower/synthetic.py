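"""Synthetic two-condition stride-time experiments.

Emulates a treadmill study in which each subject walks under two conditions
(e.g. self-paced vs. paced by a persistent fractal metronome), producing one
long stride-interval recording per condition.  Stride dynamics are persistent
fractional Gaussian noise; each subject's pair of target scaling exponents is
drawn from a bivariate normal around the condition means, so the generated
data carry subject heterogeneity, condition correlation, and the
length-dependent DFA estimation variance organically — exactly the structure
the power model assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .dfa import StrideSeries
from .empirical import StrideDataset
from .exceptions import InvalidInputError
from .fgn import davies_harte

__all__ = [
    "ExperimentSpec",
    "generate_experiment",
    "MeasurementCalibration",
    "calibrate_measurement",
]

#: Targets are clipped to this open subinterval of (0, 1), the admissible
#: Hurst range of fGn.
_ALPHA_CLIP = (0.05, 0.99)


@dataclass(frozen=True)
class ExperimentSpec:
    """Design of one synthetic two-condition experiment.

    Defaults emulate a 15-subject treadmill study with ~800 strides
    self-paced and ~750 strides paced, condition-mean scaling exponents
    0.77 and 0.87, subject SD 0.09, within-subject correlation 0.89, and a
    stride-time scale of 1.2 s with a 3% coefficient of variation.
    """

    n_subjects: int = 15
    strides_per_condition: tuple[int, int] = (800, 750)
    condition_mean_alpha: tuple[float, float] = (0.77, 0.87)
    condition_names: tuple[str, str] = ("self_paced", "paced")
    sd_subject: float = 0.09
    within_correlation: float = 0.89
    mean_stride_s: float = 1.2
    stride_cv_percent: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidInputError("need at least 2 subjects")
        if min(self.strides_per_condition) < 16:
            raise InvalidInputError("need >= 16 strides per condition")
        if self.mean_stride_s <= 0:
            raise InvalidInputError("mean_stride_s must be > 0")
        if not all(0 < a < 1 for a in self.condition_mean_alpha):
            raise InvalidInputError("condition means must lie in (0, 1)")
        if abs(self.within_correlation) > 1:
            raise InvalidInputError("|within_correlation| must be <= 1")


def _target_alpha_pairs(spec: ExperimentSpec, rng: np.random.Generator) -> np.ndarray:
    rho = spec.within_correlation
    z = rng.standard_normal((spec.n_subjects, 2))
    pair = np.empty_like(z)
    pair[:, 0] = z[:, 0]
    pair[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    targets = np.asarray(spec.condition_mean_alpha) + spec.sd_subject * pair
    lo, hi = _ALPHA_CLIP
    if np.any((targets < lo) | (targets > hi)):
        warnings.warn(
            f"target scaling exponents clipped to [{lo}, {hi}]", stacklevel=3
        )
        targets = np.clip(targets, lo, hi)
    return targets


def generate_experiment(spec: ExperimentSpec) -> StrideDataset:
    """Generate one complete two-condition stride-time dataset.

    Per subject, a correlated pair of target scaling exponents is drawn;
    per condition, an fGn series with Hurst exponent equal to the target is
    synthesised and affinely rescaled to the requested stride-time mean and
    coefficient of variation.  Byte-identical for a fixed seed.
    """
    rng_targets = substream(spec.seed, "targets")
    targets = _target_alpha_pairs(spec, rng_targets)
    sd_stride = spec.mean_stride_s * spec.stride_cv_percent / 100.0
    records = []
    for i in range(spec.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for j, condition in enumerate(spec.condition_names):
            n = spec.strides_per_condition[j]
            rng = substream(spec.seed, "fgn", i, j)
            x = davies_harte(targets[i, j], n, rng=rng)
            # Affine rescale to the stride-time scale; DFA alpha is
            # invariant to this.
            x = (x - x.mean()) / x.std()
            values = spec.mean_stride_s + sd_stride * x
            records.append(
                StrideSeries(
                    values=values,
                    subject_id=subject_id,
                    condition=condition,
                    trial_index=0,
                )
            )
    return StrideDataset(records=tuple(records))


@dataclass(frozen=True)
class MeasurementCalibration:
    """Condition means and window-level SD of estimated alpha.

    These are the experiment-design parameters translated to the scale on
    which the analysis actually operates — the DFA *estimate* over windows of
    the chosen length.  Target clipping and the (nonlinear) small-sample bias
    of the estimator make the estimated-alpha effect differ slightly from the
    nominal difference of generating exponents, so an a-priori power
    prediction for a windowed reanalysis should be fed these values rather
    than the raw design means.
    """

    mu1: float
    mu2: float
    sd_window: float
    sd_pair_diff: float
    window_length: int
    n_windows: int
    n_subjects: int

    def variance_components(self, within_correlation: float = 0.89):
        """Variance components matched to the calibrated measurement scale.

        ``sd_trial`` is the calibrated window-level SD; the subject-effect SD
        is back-solved so that the within-design paired-difference variance
        equals the calibrated ``sd_pair_diff**2`` exactly:

            var_d = 2 sd_subject^2 (1 - rho) + 2 sd_window^2 / t.
        """
        from .power import VarianceComponents

        resid = max(
            self.sd_pair_diff**2 - 2.0 * self.sd_window**2 / self.n_windows,
            0.0,
        )
        sd_subject = np.sqrt(resid / (2.0 * (1.0 - within_correlation)))
        return VarianceComponents(
            sd_subject=float(sd_subject),
            sd_trial=self.sd_window,
            sd_error=0.0,
            within_correlation=within_correlation,
        )


def calibrate_measurement(
    spec: ExperimentSpec,
    window_length: int,
    n_windows: int,
    n_subjects: int = 400,
    seed: int = 1234,
) -> MeasurementCalibration:
    """Calibrate the windowed-DFA measurement model by simulation.

    Simulates one large experiment (``n_subjects`` subjects) under ``spec``,
    runs the windowed DFA reanalysis, and returns the per-condition grand
    means of the window-averaged alpha estimates together with the pooled
    within-subject, between-window SD.  ``mu1``/``mu2`` follow the order of
    ``spec.condition_mean_alpha``.
    """
    from .empirical import windowed_alpha_table

    big = generate_experiment(
        ExperimentSpec(
            n_subjects=n_subjects,
            strides_per_condition=spec.strides_per_condition,
            condition_mean_alpha=spec.condition_mean_alpha,
            condition_names=spec.condition_names,
            sd_subject=spec.sd_subject,
            within_correlation=spec.within_correlation,
            mean_stride_s=spec.mean_stride_s,
            stride_cv_percent=spec.stride_cv_percent,
            seed=seed,
        )
    )
    table = windowed_alpha_table(big, window_length, n_windows)
    means = {
        c: float(
            np.mean([table.mean_alpha(s, c) for s in table.subjects])
        )
        for c in table.conditions
    }
    window_sds = [
        np.std(alphas, ddof=1)
        for alphas in table.alphas.values()
        if len(alphas) > 1
    ]
    return MeasurementCalibration(
        mu1=means[spec.condition_names[0]],
        mu2=means[spec.condition_names[1]],
        sd_window=float(np.mean(window_sds)),
        sd_pair_diff=float(np.std(table.paired_differences(), ddof=1)),
        window_length=window_length,
        n_windows=n_windows,
        n_subjects=n_subjects,
    )
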