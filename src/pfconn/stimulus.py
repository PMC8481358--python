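"""Stimulus-locked statistics and permutation null for connectivity estimates.

Three pieces of evaluation machinery:

* a temporal-shuffling permutation null: rerun the particle filter on
  time-permuted copies of the series (the same permutation applied to every
  node, which destroys temporal order while preserving instantaneous
  cross-sections) and collect the time-averaged coefficient matrices;
* a stimulus-locked Welch t-test comparing coefficient values during ON vs
  OFF blocks of a binary stimulation pattern, gated by a second t-test
  against the half-period-shifted control pattern to exclude fluctuations
  not locked to the stimulus;
* the quality parameter Q = T / sigma, series length over the pooled
  standard deviation of the data, a crude figure of merit for how well a
  dataset supports the filter.

No multiple-comparison correction is applied across the R^2 coefficients;
the per-coefficient p-values are reported as-is.  Coefficient trajectories
are serially correlated, which the t-test ignores; the control gate is the
procedure's guard against the resulting spurious hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CoefficientTrajectory, TimeSeriesMatrix
from .filtering import FilterConfig, fit

__all__ = [
    "StimulusPattern",
    "ModulationTestResult",
    "PermutationNullResult",
    "stimulus_ttest",
    "permutation_null",
    "quality_parameter",
]


@dataclass
class StimulusPattern:
    """Binary ON/OFF stimulation vector with its period.

    ``period`` is the duration of one stimulation block (a single ON or OFF
    phase) in time points, so a full ON+OFF cycle lasts ``2 * period``.  The
    control pattern is the original circularly shifted by half a period
    (half a block).  For the usual 50% duty cycle this puts the control in
    quadrature with the stimulus; shifting by a half *cycle* would merely
    complement the pattern and the control t-test would duplicate the
    primary one.
    """

    on_off: np.ndarray
    period: int

    def __post_init__(self) -> None:
        self.on_off = np.asarray(self.on_off, dtype=int)
        if self.on_off.ndim != 1:
            raise ValueError("on_off must be a 1-D vector")
        if not np.isin(self.on_off, (0, 1)).all():
            raise ValueError("on_off entries must be 0 or 1")
        if self.period < 2:
            raise ValueError("period must be >= 2")

    def __len__(self) -> int:
        return len(self.on_off)

    @classmethod
    def block_design(
        cls, n_timepoints: int, block_length: int, start_on: bool = True
    ) -> "StimulusPattern":
        """Alternating ON/OFF blocks of ``block_length`` points each."""
        cycle = (np.arange(n_timepoints) // block_length) % 2
        on = (cycle == 0).astype(int) if start_on else (cycle == 1).astype(int)
        return cls(on, block_length)

    def control(self) -> "StimulusPattern":
        """Half-period-shifted (quadrature) control pattern."""
        return StimulusPattern(np.roll(self.on_off, self.period // 2), self.period)


@dataclass
class ModulationTestResult:
    """ON-vs-OFF comparison for one coefficient.

    ``significant`` requires p < 0.05 on the true pattern AND p >= 0.05 on
    the half-period-shifted control, the gate that excludes modulations not
    in phase with the stimulation.
    """

    target: int
    source: int
    p_value: float
    mean_on: float
    mean_off: float
    control_p_value: float
    significant: bool


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    # identical constant groups: no evidence of modulation
    return 1.0 if np.isnan(p) else float(p)


def stimulus_ttest(
    trajectory: CoefficientTrajectory,
    stimulus: StimulusPattern,
    alpha: float = 0.05,
    lag: int = 0,
) -> dict[tuple[int, int], ModulationTestResult]:
    """Welch t-test of each coefficient's ON vs OFF values, with control gate.

    ``lag`` optionally shifts the stimulus forward in time (hemodynamic
    delay) before aligning it with the trajectory; default 0.
    """
    T = trajectory.n_timepoints
    if len(stimulus) != T:
        raise ValueError("trajectory and stimulus must share the same length")
    on = np.roll(stimulus.on_off, lag).astype(bool)
    ctrl = np.roll(stimulus.control().on_off, lag).astype(bool)
    if on.all() or not on.any():
        raise ValueError("stimulus pattern must contain both ON and OFF points")

    out: dict[tuple[int, int], ModulationTestResult] = {}
    R = trajectory.n_nodes
    for i in range(R):
        for j in range(R):
            vals = trajectory.values[i, j]
            p = _welch_p(vals[on], vals[~on])
            p_ctrl = _welch_p(vals[ctrl], vals[~ctrl])
            out[(i, j)] = ModulationTestResult(
                target=i,
                source=j,
                p_value=p,
                mean_on=float(vals[on].mean()),
                mean_off=float(vals[~on].mean()),
                control_p_value=p_ctrl,
                significant=bool(p < alpha and p_ctrl >= alpha),
            )
    return out


@dataclass
class PermutationNullResult:
    """Null distribution of time-averaged coefficients under time shuffling."""

    observed: np.ndarray  # (R, R) time-averaged estimates on the intact series
    null: np.ndarray  # (n_permutations, R, R)
    p_values: np.ndarray | None  # two-sided empirical, add-one corrected

    def outside_central(self, level: float = 0.95) -> np.ndarray:
        """Boolean mask of coefficients outside the null's central band."""
        lo = np.quantile(self.null, (1 - level) / 2, axis=0)
        hi = np.quantile(self.null, 1 - (1 - level) / 2, axis=0)
        return (self.observed < lo) | (self.observed > hi)


def permutation_null(
    series: TimeSeriesMatrix,
    config: FilterConfig,
    n_permutations: int,
) -> PermutationNullResult:
    """Particle-filter null from temporally shuffled copies of the series.

    Each permutation reorders the time axis (one permutation shared by all
    nodes), reruns the filter, and records the time-averaged coefficient
    matrix.  The observed (unpermuted) matrix is compared against the
    collection; with more than one permutation, two-sided add-one-corrected
    empirical p-values are attached.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = fit(series, config).time_average()

    rng = np.random.default_rng((config.seed, 202406))
    T = series.n_timepoints
    null = np.empty((n_permutations, *observed.shape))
    for k in range(n_permutations):
        perm = rng.permutation(T)
        shuffled = TimeSeriesMatrix(series.values[perm], series.labels, dt=series.dt)
        cfg_k = FilterConfig(**{**config.as_dict(), "seed": int(rng.integers(2**31))})
        null[k] = fit(shuffled, cfg_k).time_average()

    p_values = None
    if n_permutations > 1:
        ge = (null >= observed).sum(axis=0)
        le = (null <= observed).sum(axis=0)
        p_values = np.minimum(
            1.0, 2.0 * np.minimum(ge + 1, le + 1) / (n_permutations + 1)
        )
    return PermutationNullResult(observed=observed, null=null, p_values=p_values)


def quality_parameter(series: TimeSeriesMatrix) -> float:
    """Q = T / sigma: series length over the pooled standard deviation.

    sigma pools all nodes and time points; invariant to reordering of the
    time axis.  Larger T helps the filter, larger noise (proxied by sigma on
    normalized data) hurts it.
    """
    if series.values.size == 0:
        raise ValueError("empty series")
    sigma = float(series.values.std())
    if sigma == 0:
        raise ValueError("zero-variance data has no defined quality parameter")
    return series.n_timepoints / sigma
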