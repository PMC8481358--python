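"""Synthetic VAR(1) network generators used to validate the particle filter.

Three regimes are produced, mirroring the validation experiments:

``stationary_random``
    a random stable coefficient matrix, constant in time, observed either
    noise-free (snr_db = inf: the series is the decaying transient from a
    random start, the "ideal" case) or at a controlled signal-to-noise ratio;

``switching``
    a 2-node network whose only nonzero coefficient a_21 alternates between
    +1 and -1 as a square wave with a given half-period;

``stimulus_modulated``
    a stationary network with one designated coefficient raised by a fixed
    effect size during the ON blocks of a binary stimulation pattern.

SNR calibration
---------------
The three modes calibrate noise differently, because the role the noise
plays differs.

*stationary_random*: the coefficient matrix is drawn once (spectral radius
0.9 * uniform(0.5, 1)) and used for every SNR.  The noise-free series is the
decaying transient from a standard-normal start; at finite SNR the per-node
noise variance is set against that transient, ``sigma_i^2 =
var_t((a x_clean(t-1))_i) / 10^(snr/10)``, and the noise is then fed back
through the recursion.  One seed thus yields the same network observed
noise-free and at any chosen SNR.  Note that the recirculated noise means
the variance ratio measured on the *noisy* series exceeds the nominal value;
the nominal SNR is a calibration against the clean transient, not an
asymptotic property of the noisy process (which is scale-invariant in the
noise and fixed by the matrix alone).

*switching*: noise is the driving process.  The source node receives
unit-variance innovations and the target node's noise is scaled so that its
realized ratio ``var(a_21 x_1(t-1)) / var(eta_2)`` equals the request
exactly (the structure is triangular, so this one is an honest asymptotic
per-node SNR).

*stimulus_modulated*: the modulated edge's target node is a sink (nothing
feeds back from it), driven by an autonomous stationary subnetwork of the
remaining nodes (spectral radius 0.5, unit driving noise).  As in the
switching mode, the triangular structure makes the target node's SNR,
``var((a x(t-1))_target) / var(eta_target)``, exactly tunable; it is
calibrated in the OFF state and holds asymptotically for any series length.
A block-design detection experiment needs this sustained, honestly-scaled
excitation — a decaying transient would leave nothing to modulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .containers import CoefficientTrajectory, TimeSeriesMatrix
from .stimulus import StimulusPattern

__all__ = [
    "SyntheticNetworkSpec",
    "GroundTruth",
    "generate",
    "generate_stationary_network",
    "generate_switching_network",
    "generate_stimulus_network",
]

_MODES = ("stationary_random", "switching", "stimulus_modulated")
_MAX_REDRAWS = 100


@dataclass
class SyntheticNetworkSpec:
    """Parameters of one synthetic network realization.

    ``snr_db`` may be ``numpy.inf`` for the noise-free case.  ``switch_period``
    is the half-period of the square wave (the number of time points each
    sign is held), matching "switched from 1 to -1 with a period of 125 time
    points" for T=250.
    """

    n_nodes: int
    n_timepoints: int
    snr_db: float = np.inf
    seed: int = 0
    coefficient_mode: str = "stationary_random"
    switch_period: int | None = None
    stimulus: StimulusPattern | None = None
    effect_size: float = 0.0
    baseline_coefficient: float = 0.2
    target_edge: tuple[int, int] = (0, 1)
    coefficient_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.coefficient_mode not in _MODES:
            raise ValueError(f"coefficient_mode must be one of {_MODES}")
        if self.coefficient_mode == "switching":
            if self.switch_period is None:
                raise ValueError("switching mode requires switch_period")
            if not (1 <= self.switch_period <= self.n_timepoints):
                raise ValueError("switch_period must be in [1, n_timepoints]")
        if self.coefficient_mode == "stimulus_modulated":
            if self.stimulus is None:
                raise ValueError("stimulus_modulated mode requires a stimulus")
            if len(self.stimulus.on_off) != self.n_timepoints:
                raise ValueError("stimulus length must equal n_timepoints")
        if self.coefficient_override is not None:
            self.coefficient_override = np.asarray(
                self.coefficient_override, dtype=float
            )


@dataclass
class GroundTruth:
    """True coefficient trajectory and the per-node noise scales used."""

    coefficients: CoefficientTrajectory
    noise_sigma: np.ndarray  # (R,)

    def __post_init__(self) -> None:
        self.noise_sigma = np.asarray(self.noise_sigma, dtype=float)
        if np.any(self.noise_sigma < 0):
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_sigma.shape != (self.coefficients.n_nodes,):
            raise ValueError("noise_sigma must have one entry per node")


# ---------------------------------------------------------------------------
# coefficient-matrix draws and noise calibration


def _draw_direction_matrix(rng: np.random.Generator, n_nodes: int) -> np.ndarray:
    """Random iid uniform(-1, 1) matrix normalized to unit spectral radius."""
    for _ in range(_MAX_REDRAWS):
        a = rng.uniform(-1.0, 1.0, size=(n_nodes, n_nodes))
        rho = np.max(np.abs(np.linalg.eigvals(a)))
        if rho > 1e-8:
            return a / rho
    raise RuntimeError(
        f"could not draw a non-degenerate coefficient matrix in {_MAX_REDRAWS} tries"
    )


def _transient_calibrated_sigma(
    coeffs: np.ndarray, x0: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-node noise std against the clean realization's predicted signal.

    Simulates the noise-free recursion from the same start and sets
    ``sigma_i^2 = var_t((a(t) x_clean(t-1))_i) / 10^(snr/10)``.
    """
    R = coeffs.shape[0]
    clean = _simulate(coeffs, np.zeros(R), x0, rng)
    pred = np.einsum("ijt,tj->ti", coeffs[:, :, 1:], clean[:-1])
    pred_var = pred.var(axis=0)
    if np.any(pred_var <= 0):
        raise ValueError(
            "finite SNR undefined: a node's noiseless predicted signal "
            "has zero variance"
        )
    return np.sqrt(pred_var / 10.0 ** (snr_db / 10.0))


def _simulate(
    coeffs: np.ndarray, sigma: np.ndarray, x0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Run x(t) = a(t) x(t-1) + eta(t); ``coeffs`` has shape (R, R, T)."""
    R, _, T = coeffs.shape
    x = np.empty((T, R))
    x[0] = x0
    noise = rng.standard_normal((T - 1, R)) * sigma
    for t in range(1, T):
        x[t] = coeffs[:, :, t] @ x[t - 1] + noise[t - 1]
    return x


def _labels(n_nodes: int) -> list[str]:
    return [f"node{k+1}" for k in range(n_nodes)]


# ---------------------------------------------------------------------------
# public generators


def generate_stationary_network(
    spec: SyntheticNetworkSpec,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """Random stable VAR(1) network with constant coefficients.

    The matrix (spectral radius 0.9 * uniform(0.5, 1)) and the
    standard-normal start are drawn identically for every SNR, so the same
    seed yields the same network observed at different noise levels.  With
    ``snr_db = inf`` the series is the noiseless decaying transient; at
    finite SNR the per-node noise std is calibrated against that transient's
    predicted-signal variance (module docstring) and fed back through the
    recursion.
    """
    if spec.coefficient_mode != "stationary_random":
        raise ValueError("spec.coefficient_mode must be 'stationary_random'")
    rng = np.random.default_rng(spec.seed)
    R, T = spec.n_nodes, spec.n_timepoints

    if spec.coefficient_override is not None:
        a = np.array(spec.coefficient_override, dtype=float).reshape(R, R)
        if R > 0 and np.max(np.abs(np.linalg.eigvals(a))) >= 1.0:
            raise ValueError("coefficient_override must have spectral radius < 1")
    else:
        a_unit = _draw_direction_matrix(rng, R)
        a = a_unit * 0.9 * rng.uniform(0.5, 1.0)
    x0 = rng.standard_normal(R)

    coeffs = np.repeat(a[:, :, None], T, axis=2)
    if np.isinf(spec.snr_db):
        sigma = np.zeros(R)
    else:
        sigma = _transient_calibrated_sigma(coeffs, x0, spec.snr_db, rng)
    x = _simulate(coeffs, sigma, x0, rng)
    series = TimeSeriesMatrix(x, _labels(R))
    truth = GroundTruth(CoefficientTrajectory(coeffs, labels=series.labels), sigma)
    return series, truth


def generate_switching_network(
    spec: SyntheticNetworkSpec,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """2-node network whose a_21 square-waves between +1 and -1.

    All coefficients are zero except ``a_21(t)``, which starts at +1 and flips
    sign every ``switch_period`` time points.  Node 1 is driven by
    unit-variance noise; node 2's noise is scaled so that its SNR,
    var(a_21 x_1(t-1)) / var(eta_2), equals the request (node 1 receives no
    signal, so per-node SNR is defined only for node 2).  Extra nodes beyond
    the first two, if requested, are independent unit-variance noise.
    """
    if spec.coefficient_mode != "switching":
        raise ValueError("spec.coefficient_mode must be 'switching'")
    if spec.n_nodes < 2:
        raise ValueError("switching mode needs at least 2 nodes")
    rng = np.random.default_rng(spec.seed)
    R, T, period = spec.n_nodes, spec.n_timepoints, int(spec.switch_period)

    sign = np.where((np.arange(T) // period) % 2 == 0, 1.0, -1.0)
    coeffs = np.zeros((R, R, T))
    coeffs[1, 0, :] = sign

    sigma = np.ones(R)
    sigma[1] = 0.0 if np.isinf(spec.snr_db) else 10.0 ** (-spec.snr_db / 20.0)

    x0 = rng.standard_normal(R) * np.sqrt(np.array([1.0] + [1.0 + sigma[1] ** 2] + [1.0] * (R - 2)))
    x = _simulate(coeffs, sigma, x0, rng)
    series = TimeSeriesMatrix(x, _labels(R))
    truth = GroundTruth(CoefficientTrajectory(coeffs, labels=series.labels), sigma)
    return series, truth


def generate_stimulus_network(
    spec: SyntheticNetworkSpec,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """Stationary network with one stimulus-modulated coefficient.

    The designated entry ``target_edge = (i, j)`` equals
    ``baseline_coefficient`` during OFF blocks and ``baseline_coefficient +
    effect_size`` during ON blocks of the stimulus.  Node ``i`` is a sink:
    its column of the coefficient matrix is zero, so nothing feeds back from
    it and its SNR is exactly tunable (module docstring).  The remaining
    nodes form an autonomous stationary subnetwork (spectral radius 0.5,
    unit driving noise) from which node ``i`` also receives random incoming
    couplings besides the designated edge.
    """
    if spec.coefficient_mode != "stimulus_modulated":
        raise ValueError("spec.coefficient_mode must be 'stimulus_modulated'")
    rng = np.random.default_rng(spec.seed)
    R, T = spec.n_nodes, spec.n_timepoints
    i, j = spec.target_edge
    if not (0 <= i < R and 0 <= j < R):
        raise ValueError("target_edge out of range")
    if R < 2:
        raise ValueError("stimulus mode needs at least 2 nodes")

    others = [k for k in range(R) if k != i]
    if spec.coefficient_override is not None:
        a = np.array(spec.coefficient_override, dtype=float).reshape(R, R)
        sub = a[np.ix_(others, others)]
    else:
        a = np.zeros((R, R))
        sub = _draw_direction_matrix(rng, R - 1) * 0.5
        a[np.ix_(others, others)] = sub
        a[i, others] = rng.uniform(-0.5, 0.5, size=R - 1)

    on = np.asarray(spec.stimulus.on_off, dtype=float)
    coeffs = np.repeat(a[:, :, None], T, axis=2)
    coeffs[i, j, :] = spec.baseline_coefficient + spec.effect_size * on

    for state_val in np.unique(on):
        m = a.copy()
        m[i, j] = spec.baseline_coefficient + spec.effect_size * state_val
        if np.max(np.abs(np.linalg.eigvals(m))) >= 1.0:
            raise ValueError(
                "effect_size makes an instantaneous coefficient matrix unstable"
            )

    sigma = np.ones(R)
    # stationary covariance of the autonomous subnetwork, unit noise
    Sigma_sub = solve_discrete_lyapunov(sub, np.eye(R - 1))
    w = a[i, others].copy()
    if j != i:
        w[others.index(j)] = spec.baseline_coefficient  # OFF-state calibration
    v_ext = float(w @ Sigma_sub @ w)
    a_self = spec.baseline_coefficient if j == i else a[i, i]
    if np.isinf(spec.snr_db):
        sigma[i] = 0.0
    else:
        r = 10.0 ** (spec.snr_db / 10.0)
        denom = r * (1.0 - a_self**2) - a_self**2
        if denom <= 0 or v_ext <= 0:
            raise ValueError(
                "requested SNR unattainable for this target-node configuration"
            )
        sigma[i] = np.sqrt(v_ext / denom)

    x0 = np.zeros(R)
    x0[others] = rng.multivariate_normal(np.zeros(R - 1), Sigma_sub)
    var_pred = (v_ext + a_self**2 * sigma[i] ** 2) / (1.0 - a_self**2)
    x0[i] = rng.standard_normal() * np.sqrt(var_pred + sigma[i] ** 2)
    x = _simulate(coeffs, sigma, x0, rng)
    series = TimeSeriesMatrix(x, _labels(R))
    truth = GroundTruth(CoefficientTrajectory(coeffs, labels=series.labels), sigma)
    return series, truth


_GENERATORS = {
    "stationary_random": generate_stationary_network,
    "switching": generate_switching_network,
    "stimulus_modulated": generate_stimulus_network,
}


def generate(spec: SyntheticNetworkSpec) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """Dispatch to the generator for ``spec.coefficient_mode``."""
    return _GENERATORS[spec.coefficient_mode](spec)


def realized_snr_db(
    series: TimeSeriesMatrix, truth: GroundTruth, node: int
) -> float:
    """Recompute a node's SNR from the realized series and the ground truth.

    Signal is the one-step prediction ``(a(t) x(t-1))_i`` and noise is the
    realized innovation ``x_i(t) - (a(t) x(t-1))_i``; their variance ratio in
    dB is the quantity the generators calibrate.
    """
    x = series.values
    a = truth.coefficients.values
    pred = np.einsum("jt,tj->t", a[node, :, 1:], x[:-1])
    eta = x[1:, node] - pred
    v_noise = eta.var()
    if v_noise == 0:
        return np.inf
    return float(10.0 * np.log10(pred.var() / v_noise))
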