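"""Monte Carlo and analytic power for two-group DFA-alpha comparisons.

The generative model decomposes the variability of a subject's observed DFA
scaling exponent into three independent Gaussian components:

* a subject effect (inter-individual differences, SD ``sd_subject``),
* a trial effect (sampling variability of the DFA estimate at a given
  series length, SD ``sd_trial``; shrinks when trials are averaged),
* a per-measurement experimental error (SD ``sd_error``).

A subject's trial-averaged value under group mean ``mu`` is

    alpha = mu + b_subject + mean_{j=1..t}(trial_j + error_j).

Between-subjects designs draw independent subject effects per group and
compare group means with a pooled two-sample t-test; within-subject
(repeated-measures) designs draw the two subject effects from a bivariate
normal with correlation ``within_correlation`` and use a paired t-test.
Because every component is exactly Gaussian, power has a closed form via the
noncentral t distribution, which serves as the analytic cross-check for the
Monte Carlo engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import substream
from .exceptions import InvalidInputError, PowerNotAchievableError
from .fgn import TRIAL_SD_DEFAULTS

__all__ = [
    "VarianceComponents",
    "DesignSpec",
    "PowerSurface",
    "simulate_subject_alpha",
    "simulate_between_dataset",
    "simulate_within_dataset",
    "estimate_power",
    "analytic_power_oracle",
    "power_surface",
    "min_subjects_for_power",
]


@dataclass(frozen=True)
class VarianceComponents:
    """SDs of the three variance components plus the within-subject correlation.

    Defaults correspond to healthy young adults on a treadmill with
    100-stride trials: subject SD 0.09, trial SD 0.16, per-measurement error
    SD 0.018 (20% of the between-subject SD), and a within-subject
    correlation of 0.89 between the two conditions' subject effects.
    """

    sd_subject: float = 0.09
    sd_trial: float = 0.16
    sd_error: float = 0.018
    within_correlation: float = 0.89

    def __post_init__(self):
        for name in ("sd_subject", "sd_trial", "sd_error"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0")
        if abs(self.within_correlation) > 1:
            raise InvalidInputError("|within_correlation| must be <= 1")

    @classmethod
    def for_strides(cls, n_strides: int, **overrides) -> "VarianceComponents":
        """Variance components with ``sd_trial`` set by the stride-count
        calibration table (100 -> 0.16, 150 -> 0.12, 200 -> 0.10)."""
        try:
            sd_trial = TRIAL_SD_DEFAULTS[int(n_strides)]
        except KeyError:
            raise InvalidInputError(
                f"no calibrated trial SD for {n_strides} strides; "
                f"known: {sorted(TRIAL_SD_DEFAULTS)}"
            ) from None
        return cls(sd_trial=sd_trial, **overrides)

    @property
    def per_trial_sd(self) -> float:
        """SD of one trial's combined (trial + error) deviation."""
        return float(np.hypot(self.sd_trial, self.sd_error))


@dataclass(frozen=True)
class DesignSpec:
    """A two-group design and the simulation grid to evaluate it over."""

    design: str = "within"
    mu1: float = 0.8
    mu2: float = 0.70
    n_subjects_grid: tuple[int, ...] = tuple(range(3, 51))
    trials_grid: tuple[int, ...] = (1, 2, 4, 6, 8)
    n_replicates: int = 5000
    test_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("between", "within"):
            raise InvalidInputError("design must be 'between' or 'within'")
        if min(self.n_subjects_grid, default=0) < 2:
            raise InvalidInputError("need at least 2 subjects (or pairs)")
        if min(self.trials_grid, default=0) < 1:
            raise InvalidInputError("need at least 1 trial per subject")
        if self.n_replicates < 100:
            raise InvalidInputError("need n_replicates >= 100")
        if not 0 < self.test_level < 1:
            raise InvalidInputError("test_level must be in (0, 1)")

    @property
    def effect(self) -> float:
        return self.mu1 - self.mu2


@dataclass(frozen=True)
class PowerSurface:
    """Estimated power over the (subjects x trials) grid of one design."""

    design: DesignSpec
    variance: VarianceComponents
    power: np.ndarray  # shape (len(n_subjects_grid), len(trials_grid))

    def __post_init__(self):
        p = np.asarray(self.power, dtype=float)
        if p.shape != (
            len(self.design.n_subjects_grid),
            len(self.design.trials_grid),
        ):
            raise InvalidInputError("power matrix shape does not match grids")
        if np.any((p < 0) | (p > 1)):
            raise InvalidInputError("power entries must lie in [0, 1]")
        object.__setattr__(self, "power", p)

    def at(self, n: int, t: int) -> float:
        i = self.design.n_subjects_grid.index(n)
        j = self.design.trials_grid.index(t)
        return float(self.power[i, j])

    def to_records(self):
        """Long-format (n_subjects, trials, power) rows."""
        return [
            (n, t, float(self.power[i, j]))
            for i, n in enumerate(self.design.n_subjects_grid)
            for j, t in enumerate(self.design.trials_grid)
        ]


def simulate_subject_alpha(
    mu: float,
    subject_effect: float,
    vc: VarianceComponents,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    """One subject's trial-averaged DFA alpha under the generative model."""
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    trials = rng.normal(0.0, vc.sd_trial, n_trials)
    errors = rng.normal(0.0, vc.sd_error, n_trials)
    return float(mu + subject_effect + np.mean(trials + errors))


def simulate_between_dataset(
    spec: DesignSpec,
    vc: VarianceComponents,
    n: int,
    t: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One between-subjects experiment: ``n`` trial-averaged alphas per group."""
    if n < 2:
        raise InvalidInputError("need n >= 2 subjects per group")
    groups = []
    for mu in (spec.mu1, spec.mu2):
        subject = rng.normal(0.0, vc.sd_subject, n)
        trial_means = rng.normal(0.0, vc.sd_trial, (n, t)).mean(axis=1)
        error_means = rng.normal(0.0, vc.sd_error, (n, t)).mean(axis=1)
        groups.append(mu + subject + trial_means + error_means)
    return groups[0], groups[1]


def _bivariate_subject_effects(
    vc: VarianceComponents, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) subject effects with SD ``sd_subject`` and the within correlation."""
    rho = vc.within_correlation
    z = rng.standard_normal((n, 2))
    pair = np.empty_like(z)
    pair[:, 0] = z[:, 0]
    pair[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    return vc.sd_subject * pair


def simulate_within_dataset(
    spec: DesignSpec,
    vc: VarianceComponents,
    n: int,
    t: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One within-subject experiment: paired trial-averaged alphas.

    Subject effects for the two conditions come from a bivariate normal with
    equal variances ``sd_subject**2`` and correlation ``within_correlation``;
    trial and error deviations are independent across conditions.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2 subjects")
    subj = _bivariate_subject_effects(vc, n, rng)
    out = []
    for j, mu in enumerate((spec.mu1, spec.mu2)):
        trial_means = rng.normal(0.0, vc.sd_trial, (n, t)).mean(axis=1)
        error_means = rng.normal(0.0, vc.sd_error, (n, t)).mean(axis=1)
        out.append(mu + subj[:, j] + trial_means + error_means)
    return out[0], out[1]


def estimate_power(
    spec: DesignSpec,
    vc: VarianceComponents,
    n: int,
    t: int,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte Carlo power: rejection proportion over ``n_replicates`` experiments.

    Each replicate simulates the design, averages trials per subject, and
    applies a two-sided t-test (pooled two-sample for between-subjects,
    paired for within) at ``test_level``.  All replicates are drawn
    vectorised; the per-trial (trial + error) deviation is sampled as one
    normal with SD ``sqrt(sd_trial**2 + sd_error**2)``, which is
    distributionally identical to separate draws.
    """
    if rng is None:
        rng = substream(spec.seed, spec.design, n, t)
    reps = spec.n_replicates
    noise_sd = vc.per_trial_sd / np.sqrt(t)  # SD of the t-trial mean

    if vc.sd_subject == 0 and noise_sd == 0:
        if spec.effect == 0:
            warnings.warn(
                "zero variance and zero effect: test statistic undefined; "
                "returning power 0",
                stacklevel=2,
            )
            return 0.0
        return 1.0

    if spec.design == "between":
        a = (
            spec.mu1
            + rng.normal(0.0, vc.sd_subject, (reps, n))
            + rng.normal(0.0, noise_sd, (reps, n))
        )
        b = (
            spec.mu2
            + rng.normal(0.0, vc.sd_subject, (reps, n))
            + rng.normal(0.0, noise_sd, (reps, n))
        )
        df = 2 * n - 2
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        pooled = ((n - 1) * (var_a + var_b)) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(2.0 * pooled / n)
    else:
        rho = vc.within_correlation
        z = rng.standard_normal((reps, n, 2))
        subj = vc.sd_subject * np.stack(
            [z[..., 0], rho * z[..., 0] + np.sqrt(1 - rho**2) * z[..., 1]],
            axis=-1,
        )
        a = spec.mu1 + subj[..., 0] + rng.normal(0.0, noise_sd, (reps, n))
        b = spec.mu2 + subj[..., 1] + rng.normal(0.0, noise_sd, (reps, n))
        d = a - b
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))

    crit = stats.t.ppf(1.0 - spec.test_level / 2.0, df)
    rejected = np.abs(t_stat) > crit
    return float(np.count_nonzero(rejected) / reps)


def analytic_power_oracle(
    spec: DesignSpec,
    vc: VarianceComponents,
    n: int,
    t: int,
) -> float:
    """Exact power from the noncentral t distribution.

    The generative model is exactly Gaussian, so the t statistic follows a
    noncentral t.  Effect variances: between-subjects, per-group per-subject
    variance ``sd_subject^2 + (sd_trial^2 + sd_error^2)/t``; within-subject,
    paired-difference variance
    ``2 sd_subject^2 (1 - rho) + 2 (sd_trial^2 + sd_error^2)/t``.
    """
    per_trial_var = vc.sd_trial**2 + vc.sd_error**2
    if spec.design == "between":
        var = vc.sd_subject**2 + per_trial_var / t
        se = np.sqrt(2.0 * var / n)
        df = 2 * n - 2
    else:
        var_d = 2.0 * vc.sd_subject**2 * (1.0 - vc.within_correlation) + (
            2.0 * per_trial_var / t
        )
        se = np.sqrt(var_d / n)
        df = n - 1
    if se == 0:
        return 1.0 if spec.effect != 0 else spec.test_level
    ncp = spec.effect / se
    crit = stats.t.ppf(1.0 - spec.test_level / 2.0, df)
    return float(
        stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
    )


def power_surface(spec: DesignSpec, vc: VarianceComponents) -> PowerSurface:
    """Monte Carlo power over the full (subjects x trials) grid.

    Each grid cell draws from an independent substream keyed by
    ``(seed, design, n, t)``, so the surface is reproducible cell-by-cell.
    """
    power = np.empty((len(spec.n_subjects_grid), len(spec.trials_grid)))
    for i, n in enumerate(spec.n_subjects_grid):
        for j, t in enumerate(spec.trials_grid):
            power[i, j] = estimate_power(spec, vc, n, t)
    return PowerSurface(design=spec, variance=vc, power=power)


def min_subjects_for_power(
    surface: PowerSurface, t: int, threshold: float = 0.80
) -> int:
    """Smallest grid n whose power at ``t`` trials reaches ``threshold``."""
    if t not in surface.design.trials_grid:
        raise InvalidInputError(f"t={t} not in trials grid")
    j = surface.design.trials_grid.index(t)
    column = surface.power[:, j]
    reaching = [
        n
        for n, p in zip(surface.design.n_subjects_grid, column)
        if p >= threshold
    ]
    if not reaching:
        raise PowerNotAchievableError(threshold, float(column.max()))
    return min(reaching)
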