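"""In-memory containers for multivariate ROI time series and coefficient trajectories.

The two central objects of the package are

``TimeSeriesMatrix``
    an R-node multivariate signal sampled at T time points, the observed
    ``x(t)`` of a first-order vector-autoregressive (VAR) model
    ``x(t) = a(t) x(t-1) + eta(t)``;

``CoefficientTrajectory``
    the (possibly time-varying) coefficient matrix ``a(t)`` as an R x R x T
    array, together with a per-entry uncertainty of the same shape.

Both are thin dataclasses around numpy arrays with labeled axes; pandas is
used only at the I/O boundary (see :mod:`pfconn.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesMatrix", "CoefficientTrajectory"]


@dataclass
class TimeSeriesMatrix:
    """R-node multivariate time series, rows = time points, columns = nodes.

    Parameters
    ----------
    values
        Array of shape ``(T, R)``; ``values[t, j]`` is node ``j`` at time ``t``.
    labels
        R node (ROI) labels, unique.
    dt
        Sampling interval in seconds (fMRI repetition time), optional.
    """

    values: np.ndarray
    labels: list[str]
    dt: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T, R), got shape {self.values.shape}")
        self.labels = [str(lab) for lab in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate node labels")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dt: float | None = None) -> "TimeSeriesMatrix":
        return cls(frame.to_numpy(dtype=float), list(map(str, frame.columns)), dt=dt)


@dataclass
class CoefficientTrajectory:
    """Time-resolved VAR(1) coefficient matrix with per-entry uncertainty.

    ``values[i, j, t]`` is the coefficient :math:`a_{ij}(t)`, the influence of
    node ``j`` at time ``t-1`` on node ``i`` at time ``t``.  ``spread`` holds a
    nonnegative dispersion for each entry (across-repetition standard
    deviation for particle-filter estimates, zeros for exact ground truth).
    """

    values: np.ndarray
    spread: np.ndarray | None = None
    labels: list[str] | None = None
    config_echo: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"values must have shape (R, R, T), got {self.values.shape}"
            )
        if self.spread is None:
            self.spread = np.zeros_like(self.values)
        self.spread = np.asarray(self.spread, dtype=float)
        if self.spread.shape != self.values.shape:
            raise ValueError("spread shape must match values shape")
        if np.any(self.spread < 0):
            raise ValueError("spread must be nonnegative")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal R")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def time_average(self, skip_first: bool = True) -> np.ndarray:
        """Mean coefficient matrix over time.

        The entry at the first time index duplicates the first estimable step
        (there is no transition into t=0), so it is excluded by default.
        """
        start = 1 if (skip_first and self.n_timepoints > 1) else 0
        return self.values[:, :, start:].mean(axis=2)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with columns t, target, source, estimate, spread."""
        R, _, T = self.values.shape
        labels = self.labels or [f"node{k}" for k in range(R)]
        i, j, t = np.meshgrid(np.arange(R), np.arange(R), np.arange(T), indexing="ij")
        return pd.DataFrame(
            {
                "t": t.ravel(),
                "target": np.asarray(labels)[i.ravel()],
                "source": np.asarray(labels)[j.ravel()],
                "estimate": self.values.ravel(),
                "spread": self.spread.ravel(),
            }
        )
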