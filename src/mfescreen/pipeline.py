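"""Convenience composition: raw recording -> banded epoch stacks -> MFE tensor."""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Sequence

from .entropy import MFEConfig, MFETensor, subject_mfe
from .preprocess import (
    EpochSet,
    PreprocessConfig,
    RawRecording,
    bandpass_and_trim,
    extract_epochs,
    normalize_channels,
    resample_recording,
)


def config_fingerprint(pre_cfg: PreprocessConfig, mfe_cfg: MFEConfig) -> str:
    """Short stable hash of the full analysis configuration.

    Guards against mixing artifacts (MFE tensors, reference models, reports)
    produced under different parameters.
    """
    canonical = json.dumps(
        {"preprocess": pre_cfg.to_dict(), "mfe": mfe_cfg.to_dict()},
        sort_keys=True,
        separators=(",", ":"),
    )
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def preprocess_recording(
    rec: RawRecording,
    cfg: PreprocessConfig,
    epoch_starts: Sequence[int] | None = None,
) -> dict[str, EpochSet]:
    """Full preprocessing for every configured band.

    Fixed order: montage mapping -> resample -> epoch -> normalize ->
    band-pass filter -> transient trim. Returns one epoch stack per band,
    each with n_epochs - 1 epochs.
    """
    rec = rec.to_montage()
    rec = resample_recording(rec, cfg.fs_target)
    epochs = extract_epochs(rec, cfg, epoch_starts)
    normalized = normalize_channels(epochs, cfg)
    return {band: bandpass_and_trim(normalized, band, cfg) for band in cfg.bands}


def mfe_from_recording(
    rec: RawRecording,
    pre_cfg: PreprocessConfig | None = None,
    mfe_cfg: MFEConfig | None = None,
    epoch_starts: Sequence[int] | None = None,
) -> MFETensor:
    """Preprocess a recording and compute its MFE tensor."""
    pre_cfg = pre_cfg or PreprocessConfig()
    mfe_cfg = mfe_cfg or MFEConfig()
    banded = preprocess_recording(rec, pre_cfg, epoch_starts)
    tensor = subject_mfe(
        banded, mfe_cfg, fingerprint=config_fingerprint(pre_cfg, mfe_cfg)
    )
    tensor.group_label = rec.group_label
    return tensor
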