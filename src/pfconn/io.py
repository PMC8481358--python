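"""Readers, writers, ROI extraction, preprocessing and configuration loading.

File conventions:

* time series: delimited text (TSV/CSV), T rows by R labeled columns;
* coefficient trajectories: long-format TSV with columns
  ``t, target, source, estimate, spread``;
* ground truth / run manifests: JSON;
* 4-D volumes: NIfTI via nibabel, with ROIs given as voxel-index lists;
* filter configuration: TOML or YAML overriding ``FilterConfig`` defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import CoefficientTrajectory, TimeSeriesMatrix
from .filtering import FilterConfig

__all__ = [
    "RoiSpec",
    "read_series",
    "write_series",
    "read_trajectory",
    "write_trajectory",
    "write_ground_truth",
    "read_roi_specs",
    "extract_roi_series",
    "preprocess",
    "load_filter_config",
]


@dataclass
class RoiSpec:
    """A labeled region of interest as explicit voxel indices.

    ``voxel_indices`` is a list of (i, j, k) triples; ``slice_constraint``,
    if set, requires all voxels to lie on that k-slice (ROIs drawn on a
    single slice avoid slice-timing confounds).
    """

    label: str
    voxel_indices: list[tuple[int, int, int]]
    slice_constraint: int | None = None

    def __post_init__(self) -> None:
        if not self.voxel_indices:
            raise ValueError(f"ROI {self.label!r} has no voxels")
        self.voxel_indices = [tuple(int(v) for v in vox) for vox in self.voxel_indices]
        if any(len(v) != 3 for v in self.voxel_indices):
            raise ValueError("voxel indices must be (i, j, k) triples")
        if self.slice_constraint is not None and any(
            v[2] != self.slice_constraint for v in self.voxel_indices
        ):
            raise ValueError(
                f"ROI {self.label!r} has voxels off slice {self.slice_constraint}"
            )


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect is not None:
        raise ValueError("dialect must be 'tsv', 'csv' or None")
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_series(
    path: str | Path, dialect: str | None = None, dt: float | None = None
) -> TimeSeriesMatrix:
    """Read a T x R labeled table; rejects missing or non-numeric cells."""
    path = Path(path)
    sep = _delimiter_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column labels: {dupes}")
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric or missing value at row {row}, column {col!r}"
            )
        frame[col] = numeric
    return TimeSeriesMatrix.from_frame(frame, dt=dt)


def write_series(series: TimeSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    # %.17g preserves doubles exactly, so write -> read round-trips bit-wise
    series.to_frame().to_csv(
        path, sep=_delimiter_for(path, None), index=False, float_format="%.17g"
    )


def write_trajectory(trajectory: CoefficientTrajectory, path: str | Path) -> None:
    """Write long-format TSV (t, target, source, estimate, spread)."""
    trajectory.to_long_frame().to_csv(
        Path(path), sep="\t", index=False, float_format="%.17g"
    )


def read_trajectory(path: str | Path) -> CoefficientTrajectory:
    frame = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    labels = list(dict.fromkeys(frame["target"]))
    R, T = len(labels), int(frame["t"].max()) + 1
    idx = {lab: k for k, lab in enumerate(labels)}
    values = np.empty((R, R, T))
    spread = np.zeros((R, R, T))
    ii = frame["target"].map(idx).to_numpy()
    jj = frame["source"].map(idx).to_numpy()
    tt = frame["t"].to_numpy()
    values[ii, jj, tt] = frame["estimate"].to_numpy()
    spread[ii, jj, tt] = frame["spread"].to_numpy()
    return CoefficientTrajectory(values, spread, labels=labels)


def write_ground_truth(truth, spec, path: str | Path) -> None:
    """Companion JSON for a synthetic dataset: spec echo, sigma, trajectory."""
    spec_dict = asdict(spec)
    if spec_dict.get("stimulus") is not None:
        spec_dict["stimulus"] = {
            "on_off": np.asarray(spec.stimulus.on_off).tolist(),
            "period": spec.stimulus.period,
        }
    if spec_dict.get("coefficient_override") is not None:
        spec_dict["coefficient_override"] = np.asarray(
            spec.coefficient_override
        ).tolist()
    payload = {
        "spec": spec_dict,
        "noise_sigma": truth.noise_sigma.tolist(),
        "coefficients": truth.coefficients.values.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_roi_specs(path: str | Path) -> list[RoiSpec]:
    """ROI list from JSON: [{"label": ..., "voxels": [[i,j,k], ...]}, ...]."""
    entries = json.loads(Path(path).read_text())
    return [
        RoiSpec(
            label=e["label"],
            voxel_indices=[tuple(v) for v in e["voxels"]],
            slice_constraint=e.get("slice"),
        )
        for e in entries
    ]


def extract_roi_series(
    volume: str | Path | np.ndarray, rois: list[RoiSpec], dt: float | None = None
) -> TimeSeriesMatrix:
    """Average each ROI's voxel time series from a 4-D volume.

    ``volume`` is a NIfTI path or an (X, Y, Z, T) array; column order follows
    the ROI list.  If ``dt`` is not given and the volume is NIfTI, the
    repetition time is taken from the header when available.
    """
    if isinstance(volume, (str, Path)):
        img = nib.load(str(volume))
        data = np.asarray(img.get_fdata())
        if dt is None:
            zooms = img.header.get_zooms()
            if len(zooms) >= 4 and zooms[3] > 0:
                dt = float(zooms[3])
    else:
        data = np.asarray(volume, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    shape = data.shape[:3]
    columns = []
    for roi in rois:
        for vox in roi.voxel_indices:
            if not all(0 <= vox[d] < shape[d] for d in range(3)):
                raise IndexError(
                    f"ROI {roi.label!r} voxel {vox} outside volume {shape}"
                )
        vox_series = np.stack(
            [data[i, j, k, :] for (i, j, k) in roi.voxel_indices]
        )
        columns.append(vox_series.mean(axis=0))
    return TimeSeriesMatrix(
        np.column_stack(columns), [roi.label for roi in rois], dt=dt
    )


def preprocess(
    series: TimeSeriesMatrix, highpass_cutoff: float | None = None
) -> TimeSeriesMatrix:
    """Demean per node, normalize by one pooled factor, optionally detrend.

    Mirrors the standard fMRI pipeline tail: each node is demeaned, all
    nodes are divided by a single multiplicative factor (the pooled standard
    deviation), and slow drifts below ``highpass_cutoff`` (Hz; requires
    ``series.dt``) are removed by regressing out a discrete-cosine basis.
    """
    if series.n_timepoints < 4:
        raise ValueError("need at least 4 time points")
    x = series.values - series.values.mean(axis=0)
    pooled = x.std()
    if pooled == 0:
        raise ValueError("zero pooled variance; cannot normalize")
    x = x / pooled
    if highpass_cutoff is not None:
        if series.dt is None:
            raise ValueError("highpass filtering requires the sampling interval dt")
        T = x.shape[0]
        # cosine k has frequency k / (2 T dt); drop everything below cutoff
        k_max = int(np.floor(2.0 * T * series.dt * highpass_cutoff))
        if k_max >= 1:
            t = np.arange(T)
            basis = np.column_stack(
                [np.cos(np.pi * k * (t + 0.5) / T) for k in range(1, k_max + 1)]
            )
            coefs, *_ = np.linalg.lstsq(basis, x, rcond=None)
            x = x - basis @ coefs
    return TimeSeriesMatrix(x, series.labels, dt=series.dt)


def load_filter_config(path: str | Path, **overrides) -> FilterConfig:
    """FilterConfig from a TOML or YAML file, with keyword overrides."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        raise ValueError("config must be .toml, .yaml or .yml")
    data = {**(data or {}), **overrides}
    valid = set(FilterConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown filter-config keys: {sorted(unknown)}")
    return FilterConfig(**data)
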