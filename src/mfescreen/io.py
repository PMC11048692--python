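"""Subject file I/O and run configuration loading.

CSV matrix format: header row of channel names, one row per sample. The
sampling frequency comes from the caller (CLI flag) or from a JSON sidecar
next to the file (``subject.csv`` -> ``subject.json`` with at least
``{"fs": ...}``). EDF files are handled by :mod:`mfescreen.edf`.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import MFEConfig
from .errors import ConfigError, MontageError
from .preprocess import PreprocessConfig, RawRecording


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(".json")
    if side.exists():
        with open(side) as fh:
            meta = fh.read()
        try:
            return json.loads(meta)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed sidecar {side}: {exc}") from exc
    return {}


def read_subject_csv(
    path: str | os.PathLike,
    fs: float | None = None,
    subject_id: str | None = None,
    group_label: str | None = None,
) -> RawRecording:
    """Read a channels-in-columns CSV matrix into a montage-validated recording."""
    path = Path(path)
    meta = _sidecar(path)
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ConfigError(
            f"sampling frequency for {path.name} not given and no sidecar "
            f"{path.with_suffix('.json').name} found"
        )
    frame = pd.read_csv(path, header=0, dtype=str)
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise MontageError(f"{path.name}: empty CSV matrix")
    columns = list(frame.columns)
    data = np.empty((len(columns), frame.shape[0]))
    for ci, col in enumerate(columns):
        raw = frame[col].to_numpy()
        try:
            data[ci] = raw.astype(np.float64)
        except ValueError:
            for ri, cellval in enumerate(raw):
                try:
                    float(cellval)
                except (TypeError, ValueError):
                    raise ConfigError(
                        f"{path.name}: non-numeric value {cellval!r} at data row "
                        f"{ri + 1}, column {col!r}"
                    ) from None
            raise
    rec = RawRecording(
        samples=data,
        fs=float(fs),
        channel_names=columns,
        subject_id=subject_id or meta.get("subject_id", path.stem),
        group_label=group_label or meta.get("group_label"),
    )
    return rec.to_montage()


def write_subject_csv(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write a recording as a CSV matrix plus an ``fs`` sidecar JSON."""
    path = Path(path)
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.channel_names))
    frame.to_csv(path, index=False, float_format="%.6f")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"fs": rec.fs, "subject_id": rec.subject_id}, fh)


def read_subject(
    path: str | os.PathLike,
    fs: float | None = None,
    subject_id: str | None = None,
    group_label: str | None = None,
) -> RawRecording:
    """Read a subject recording from EDF or CSV, dispatching on the extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        from .edf import read_edf

        rec = read_edf(path, subject_id=subject_id)
        rec.group_label = group_label or rec.group_label
        return rec.to_montage()
    if suffix == ".csv":
        return read_subject_csv(path, fs=fs, subject_id=subject_id, group_label=group_label)
    raise ConfigError(f"unsupported subject file format {suffix!r} (use .edf or .csv)")


def load_run_config(path: str | os.PathLike | None) -> tuple[PreprocessConfig, MFEConfig]:
    """Load ``{"preprocess": {...}, "mfe": {...}}`` JSON; defaults when omitted.

    Unknown top-level or nested keys are rejected.
    """
    if path is None:
        return PreprocessConfig(), MFEConfig()
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a JSON object")
    unknown = set(raw) - {"preprocess", "mfe"}
    if unknown:
        raise ConfigError(f"unknown run config sections: {sorted(unknown)}")
    pre = PreprocessConfig.from_dict(raw.get("preprocess", {}))
    mfe = MFEConfig.from_dict(raw.get("mfe", {}))
    return pre, mfe
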