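"""Stationary comparators: delayed correlation, VAR least squares, sliding window.

These are the reference analyses a time-varying estimate is judged against:

* delayed correlation ``c_ij`` = Pearson correlation of ``x_i(t)`` with
  ``x_j(t-1)``, a pairwise stationary proxy for directed coupling;
* an ordinary least-squares VAR(p) fit with constant coefficients (no
  intercept, series demeaned first);
* Schwartz/Bayesian information criterion (BIC) selection of the VAR order;
* a sliding-window VAR(1) fit over consecutive overlapping blocks, the
  conventional way to chase slow coefficient changes without a filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CoefficientTrajectory, TimeSeriesMatrix

__all__ = [
    "DelayedCorrelationMatrix",
    "StationaryAREstimate",
    "delayed_correlation",
    "fit_stationary_var",
    "select_order_bic",
    "sliding_window_fit",
]


@dataclass
class DelayedCorrelationMatrix:
    """R x R matrix of lag-1 cross-correlations; NaN marks undefined entries."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.any(finite > 1 + 1e-9) or np.any(finite < -1 - 1e-9)):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class StationaryAREstimate:
    """Constant-coefficient VAR fit: coefficients, residual stds, order."""

    coefficients: np.ndarray  # order 1: (R, R); order p: (p, R, R)
    residual_sigma: np.ndarray  # (R,)
    order: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")
        if np.any(np.asarray(self.residual_sigma) < 0):
            raise ValueError("residual_sigma must be nonnegative")


def delayed_correlation(series: TimeSeriesMatrix) -> DelayedCorrelationMatrix:
    """c_ij = Pearson correlation of x_i(t) with x_j(t-1), diagonal included.

    Invariant to affine rescaling of individual node series; zero-variance
    nodes yield NaN entries (flagged missing, not zero).
    """
    x = series.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    lead = x[1:] - x[1:].mean(axis=0)  # x_i(t), t = 2..T
    lag = x[:-1] - x[:-1].mean(axis=0)  # x_j(t-1)
    s_lead = lead.std(axis=0)
    s_lag = lag.std(axis=0)
    n = lead.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (lead.T @ lag) / n / np.outer(s_lead, s_lag)
    c[~np.isfinite(c)] = np.nan
    return DelayedCorrelationMatrix(np.clip(c, -1.0, 1.0), labels=series.labels)


def _lagged_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Response x(t) and regressors [x(t-1), ..., x(t-p)] stacked columnwise."""
    T = x.shape[0]
    y = x[order:]
    z = np.hstack([x[order - k : T - k] for k in range(1, order + 1)])
    return y, z


def fit_stationary_var(
    series: TimeSeriesMatrix, order: int = 1, demean: bool = True
) -> StationaryAREstimate:
    """Ordinary least-squares VAR(p) with constant coefficients, no intercept.

    The series is demeaned per node first (the model carries no intercept).
    Coefficients come back as (R, R) for order 1, else (p, R, R), with
    ``coefficients[..., i, j]`` the effect of node j on node i.  Residual
    stds use the OLS degrees-of-freedom correction.  A rank-deficient
    regressor matrix raises ``numpy.linalg.LinAlgError``.
    """
    x = series.values.copy()
    T, R = x.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= order * R + 1:
        raise ValueError(f"need T > order*R + 1 = {order * R + 1}, got T = {T}")
    if demean:
        x -= x.mean(axis=0)
    y, z = _lagged_design(x, order)
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient lagged regressor matrix")
    sol, *_ = np.linalg.lstsq(z, y, rcond=None)  # (p*R, R)
    resid = y - z @ sol
    dof = max(y.shape[0] - order * R, 1)
    residual_sigma = np.sqrt((resid**2).sum(axis=0) / dof)
    coeffs = np.stack([sol[k * R : (k + 1) * R].T for k in range(order)])
    if order == 1:
        coeffs = coeffs[0]
    return StationaryAREstimate(coeffs, residual_sigma, order)


def select_order_bic(series: TimeSeriesMatrix, max_order: int) -> int:
    """VAR order minimizing the Schwartz criterion.

    All candidate orders are fit on the common sample that drops the first
    ``max_order`` observations; BIC = log det(Sigma_ML) + log(n)/n * p * R^2,
    with p * R^2 mean parameters per model.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    x = series.values - series.values.mean(axis=0)
    T, R = x.shape
    n = T - max_order
    if n <= max_order * R + 1:
        raise ValueError("series too short for max_order")
    bics = []
    for p in range(1, max_order + 1):
        y = x[max_order:]
        z = np.hstack([x[max_order - k : T - k] for k in range(1, p + 1)])
        sol, *_ = np.linalg.lstsq(z, y, rcond=None)
        resid = y - z @ sol
        sigma_ml = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            logdet = -np.inf  # perfect fit; favoured maximally
        bics.append(logdet + np.log(n) / n * p * R * R)
    return int(np.argmin(bics)) + 1


def sliding_window_fit(
    series: TimeSeriesMatrix, window: int = 20, stride: int = 1, demean: bool = True
) -> CoefficientTrajectory:
    """VAR(1) refit on consecutive overlapping blocks of the series.

    Each window of ``window`` points gets its own stationary fit; the
    coefficient matrix is indexed to the window's center time point and held
    constant (nearest-center) between and beyond centers, so the returned
    trajectory covers all T points.
    """
    T, R = series.values.shape
    if window > T:
        raise ValueError("window longer than the series")
    if window < R + 2:
        raise ValueError(f"window must be at least R + 2 = {R + 2}")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    starts = list(range(0, T - window + 1, stride))
    centers = np.array([s + window // 2 for s in starts])
    mats = np.empty((len(starts), R, R))
    for k, s in enumerate(starts):
        block = TimeSeriesMatrix(series.values[s : s + window], series.labels)
        mats[k] = fit_stationary_var(block, order=1, demean=demean).coefficients

    # hold each time point at the nearest window center
    t_axis = np.arange(T)
    nearest = np.abs(t_axis[:, None] - centers[None, :]).argmin(axis=1)
    values = np.moveaxis(mats[nearest], 0, 2)  # (R, R, T)
    return CoefficientTrajectory(
        values,
        labels=series.labels,
        meta={"window": window, "stride": stride, "centers": centers.tolist()},
    )
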