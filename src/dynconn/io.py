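"""Delimited-text readers/writers and configuration for the pipeline.

All tables are comma-separated UTF-8 with a header row.  Subject time series
use columns ``time_s, roi1, roi2``; cohort manifests use
``subject_id, label, path``.  Every written artifact gets a JSON sidecar
recording the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import BivariateSeries
from .simulate import SimulatedSubject


def read_subject_timeseries(path, tr: float | None = None) -> BivariateSeries:
    """Read one subject's two-column time-series file.

    Expects a header with ``time_s`` plus two ROI columns.  ``tr`` is
    inferred from ``time_s`` when not given.  Non-numeric or missing cells
    are rejected with their row numbers (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    roi_cols = [c for c in df.columns if c != "time_s"]
    if len(roi_cols) != 2:
        raise ValueError(f"{path}: expected exactly 2 ROI columns, got {roi_cols}")
    body = df[["time_s"] + roi_cols].apply(pd.to_numeric, errors="coerce")
    bad = body.isna().any(axis=1)
    if bad.any():
        rows = (body.index[bad] + 1).tolist()
        raise ValueError(f"{path}: non-numeric or missing values at rows {rows}")
    if len(df) < 50:
        raise ValueError(f"{path}: fewer than 50 rows ({len(df)})")
    if tr is None:
        steps = np.diff(body["time_s"].to_numpy())
        if len(steps) == 0 or not np.allclose(steps, steps[0]):
            raise ValueError(f"{path}: time_s is not evenly sampled")
        tr = float(steps[0])
    return BivariateSeries(body[roi_cols].to_numpy(float), tr=tr,
                           labels=tuple(roi_cols))


def write_subject_timeseries(path, series: BivariateSeries,
                             truth: np.ndarray | None = None,
                             sidecar: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": series.time_s,
                       series.labels[0]: series.values[:, 0],
                       series.labels[1]: series.values[:, 1]})
    df.to_csv(path, index=False)
    meta = dict(sidecar or {})
    meta.setdefault("tr", series.tr)
    if truth is not None:
        meta["true_correlation"] = np.asarray(truth).tolist()
    write_sidecar(path, meta)


def write_subject(path, subject: SimulatedSubject) -> None:
    """Write a simulated subject plus a sidecar holding spec and truth."""
    spec = dataclasses.asdict(subject.spec)
    spec["correlation_mode"] = type(subject.spec.correlation).__name__
    write_subject_timeseries(path, subject.series,
                             truth=subject.true_correlation,
                             sidecar={"spec": spec})


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_sidecar(path, settings: dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        json.dump(settings, fh, indent=2, default=_jsonable)
    # trailing newline keeps the file diff-friendly
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "label", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def write_manifest(path, rows) -> None:
    pd.DataFrame(rows, columns=["subject_id", "label", "path"]).to_csv(
        path, index=False)


def write_table(path, table: pd.DataFrame, settings: dict | None = None) -> None:
    """Write a result table with its machine-readable settings sidecar."""
    table.to_csv(path, index=False)
    if settings is not None:
        write_sidecar(path, settings)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, loadable from YAML."""

    manifest: str = ""
    output_dir: str = "dynconn_out"
    tr: float = 2.0
    # DCC settings
    mean_order: tuple = (2, 2)
    n_restarts: int = 3
    # feature settings
    c: float = 0.001
    nperseg: int | None = None
    overlap: float = 0.5
    band: tuple = (0.01, 0.08)
    n_peak_bins: int = 8
    # sliding window
    window_seconds: float = 80.0
    window_overlap: float = 0.5
    # bootstrap
    B: int = 1000
    level: float = 0.95
    q: float = 0.05
    # CV
    k: int = 5
    repetitions: int = 30
    inner_cv: int = 5
    n_estimators: int = 500
    seed: int = 0
    run_inference: bool = True
    run_prediction: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mean_order", "band"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
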