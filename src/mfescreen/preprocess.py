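"""Raw EEG to normalized, band-filtered, artifact-trimmed epoch stacks.

The pipeline order is fixed: resample -> epoch -> normalize -> filter -> trim.
Each step appends to the :class:`EpochSet` provenance log so a stack records
how it was produced; re-running with the same input and configuration is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import (
    ConfigError,
    DegenerateChannelError,
    InvalidRateError,
    MontageError,
    TooShortError,
)

#: The 19 scalp electrodes of the International 10-20 montage, in canonical order.
MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "F3", "C3", "P3", "O1",
    "Fp2", "F4", "C4", "P4", "O2",
    "F7", "T3", "T5", "F8", "T4", "T6",
    "FZ", "CZ", "PZ",
)

#: Modern 10-10 names mapped back to the classic labels used here.
CHANNEL_ALIASES: Mapping[str, str] = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

#: Canonical EEG frequency bands in Hz.
DEFAULT_BANDS: Mapping[str, tuple[float, float]] = {
    "all": (0.5, 30.0),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


def normalize_channel_name(name: str) -> str:
    """Map a channel label (case-insensitive, 10-10 aliases allowed) to the
    canonical montage spelling, or return the stripped input if unknown."""
    stripped = name.strip()
    lowered = stripped.upper()
    for canonical in MONTAGE_1020:
        if canonical.upper() == lowered:
            return canonical
    for alias, canonical in CHANNEL_ALIASES.items():
        if alias.upper() == lowered:
            return canonical
    return stripped


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing stage.

    Defaults follow the screening protocol: 200 Hz sampling, fifteen 3-second
    eyes-closed epochs, channel-wise normalization into the [-10, 10] frame,
    and an FIR band-pass whose order equals the per-epoch sample count.
    """

    fs_target: float = 200.0
    epoch_seconds: float = 3.0
    n_epochs: int = 15
    h_max: float = 10.0
    h_min: float = -10.0
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if self.h_max <= self.h_min:
            raise ConfigError(f"h_max ({self.h_max}) must exceed h_min ({self.h_min})")
        if self.fs_target <= 0:
            raise ConfigError("fs_target must be positive")
        if self.n_epochs < 1:
            raise ConfigError("n_epochs must be >= 1")
        spe = self.epoch_seconds * self.fs_target
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigError(
                f"epoch_seconds x fs_target = {spe} is not an integer sample count"
            )
        for name, (lo, hi) in self.bands.items():
            if not (0.0 < lo < hi):
                raise ConfigError(f"band {name!r}: invalid interval ({lo}, {hi})")
            if lo < 0.5 - 1e-12 or hi > 30.0 + 1e-12:
                raise ConfigError(f"band {name!r} must lie within [0.5, 30] Hz")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.fs_target))

    def to_dict(self) -> dict:
        return {
            "fs_target": self.fs_target,
            "epoch_seconds": self.epoch_seconds,
            "n_epochs": self.n_epochs,
            "h_max": self.h_max,
            "h_min": self.h_min,
            "bands": {k: [float(v[0]), float(v[1])] for k, v in self.bands.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessConfig":
        known = {"fs_target", "epoch_seconds", "n_epochs", "h_max", "h_min", "bands"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown preprocess config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "bands" in kwargs:
            kwargs["bands"] = {k: (float(v[0]), float(v[1])) for k, v in kwargs["bands"].items()}
        return cls(**kwargs)


@dataclass
class RawRecording:
    """A multichannel scalp EEG recording on the 19-channel 10-20 montage.

    ``samples`` is a channels x time float array in (arbitrary) microvolt-scale
    units; ``channel_names`` gives the row order.
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str] = MONTAGE_1020
    subject_id: str = "unknown"
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise MontageError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise InvalidRateError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise MontageError(f"recording {self.subject_id!r} contains non-finite samples")
        self.channel_names = [normalize_channel_name(c) for c in self.channel_names]
        if len(self.channel_names) != self.samples.shape[0]:
            raise MontageError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )

    def to_montage(self) -> "RawRecording":
        """Reorder channels into canonical montage order, dropping extras.

        Extra channels are ignored with a warning; missing montage channels
        raise :class:`MontageError`.
        """
        index = {name: i for i, name in enumerate(self.channel_names)}
        missing = [c for c in MONTAGE_1020 if c not in index]
        if missing:
            raise MontageError(
                f"recording {self.subject_id!r} is missing montage channels: {missing}"
            )
        extras = [c for c in self.channel_names if c not in MONTAGE_1020]
        if extras:
            warnings.warn(
                f"recording {self.subject_id!r}: ignoring non-montage channels {extras}",
                stacklevel=2,
            )
        rows = [index[c] for c in MONTAGE_1020]
        return RawRecording(
            samples=self.samples[rows],
            fs=self.fs,
            channel_names=list(MONTAGE_1020),
            subject_id=self.subject_id,
            group_label=self.group_label,
        )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """A stack of equal-length epochs: epochs x channels x samples."""

    data: np.ndarray
    fs: float
    subject_id: str = "unknown"
    band: str | None = None
    channel_names: Sequence[str] = MONTAGE_1020
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConfigError("epoch data must be epochs x channels x samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


def resample_recording(rec: RawRecording, fs_target: float) -> RawRecording:
    """Resample a recording to ``fs_target`` Hz with a polyphase anti-aliased
    resampler.

    A target rate at or below 60 Hz is rejected: it would violate the Nyquist
    requirement for the 13-30 Hz beta band.
    """
    if fs_target <= 60.0:
        raise InvalidRateError(
            f"fs_target = {fs_target} Hz violates Nyquist for the beta band (30 Hz); "
            "must exceed 60 Hz"
        )
    if rec.fs == fs_target:
        return rec
    ratio = Fraction(fs_target / rec.fs).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=1)
    return RawRecording(
        samples=out,
        fs=fs_target,
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
        group_label=rec.group_label,
    )


def extract_epochs(
    rec: RawRecording,
    cfg: PreprocessConfig,
    epoch_starts: Sequence[int] | None = None,
) -> EpochSet:
    """Cut ``cfg.n_epochs`` non-overlapping epochs from a recording.

    With ``epoch_starts`` omitted, the first ``n_epochs`` consecutive windows
    are used — a deterministic stand-in for manual clean-epoch selection.
    Explicit sample offsets reproduce a manual selection.
    """
    spe = cfg.samples_per_epoch
    if epoch_starts is None:
        needed = cfg.n_epochs * spe
        if rec.n_samples < needed:
            raise TooShortError(
                f"recording {rec.subject_id!r}: need {needed} samples for "
                f"{cfg.n_epochs} epochs of {spe}, have {rec.n_samples}"
            )
        starts = [i * spe for i in range(cfg.n_epochs)]
        prov = f"epoch: first {cfg.n_epochs} consecutive windows of {spe} samples"
    else:
        starts = sorted(int(s) for s in epoch_starts)
        if len(starts) != cfg.n_epochs:
            raise ConfigError(
                f"{len(starts)} epoch_starts given but n_epochs = {cfg.n_epochs}"
            )
        for a, b in zip(starts, starts[1:]):
            if b - a < spe:
                raise ConfigError(f"epoch starts {a} and {b} overlap (epoch is {spe} samples)")
        if starts[0] < 0 or starts[-1] + spe > rec.n_samples:
            raise TooShortError(
                f"epoch window [{starts[-1]}, {starts[-1] + spe}) exceeds recording "
                f"length {rec.n_samples}"
            )
        prov = f"epoch: {cfg.n_epochs} windows at explicit offsets"
    data = np.stack([rec.samples[:, s : s + spe] for s in starts], axis=0)
    return EpochSet(
        data=data,
        fs=rec.fs,
        subject_id=rec.subject_id,
        channel_names=list(rec.channel_names),
        provenance=[f"resampled/native at {rec.fs} Hz", prov],
    )


def normalize_channels(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Channel-wise affine normalization into the [h_min, h_max] frame.

    For channel i the frame is set by the medians over epochs of the per-epoch
    maxima (z_max,i) and minima (z_min,i); every sample of that channel maps as

        z_norm = (z - z_min,i) / (z_max,i - z_min,i) * (h_max - h_min) + h_min

    The medians are not global extrema, so individual samples may land outside
    the frame; they are deliberately not clipped (clipping would distort the
    entropy of the trace).
    """
    if epochs.n_epochs < 1:
        raise ConfigError("need at least one epoch to normalize")
    per_epoch_max = epochs.data.max(axis=2)  # epochs x channels
    per_epoch_min = epochs.data.min(axis=2)
    z_max = np.median(per_epoch_max, axis=0)  # channels
    z_min = np.median(per_epoch_min, axis=0)
    flat = np.nonzero(z_max <= z_min)[0]
    if flat.size:
        names = [epochs.channel_names[i] for i in flat]
        raise DegenerateChannelError(
            f"flat channel(s) {names}: median max equals median min, "
            "normalization undefined"
        )
    scale = (cfg.h_max - cfg.h_min) / (z_max - z_min)
    data = (epochs.data - z_min[None, :, None]) * scale[None, :, None] + cfg.h_min
    return EpochSet(
        data=data,
        fs=epochs.fs,
        subject_id=epochs.subject_id,
        band=epochs.band,
        channel_names=list(epochs.channel_names),
        provenance=epochs.provenance
        + [f"normalize: median-extrema frame -> [{cfg.h_min}, {cfg.h_max}]"],
    )


def design_bandpass(band_edges: tuple[float, float], order: int, fs: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR band-pass of the given order (taps = order + 1)."""
    lo, hi = band_edges
    return signal.firwin(order + 1, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def bandpass_and_trim(epochs: EpochSet, band: str, cfg: PreprocessConfig) -> EpochSet:
    """Band-pass filter an epoch stack and drop the filter-transient epoch.

    The FIR filter (order = samples per epoch) is applied causally, once, to
    the concatenated time series of each channel; the series is then
    re-epoched and the first epoch — which absorbs the start-up transient —
    is discarded. 15 input epochs therefore yield 14.
    """
    if band not in cfg.bands:
        raise ConfigError(f"unknown band {band!r}; configured bands: {sorted(cfg.bands)}")
    if epochs.n_epochs < 2:
        raise TooShortError("need at least 2 epochs (the first is dropped as transient)")
    spe = epochs.samples_per_epoch
    taps = design_bandpass(cfg.bands[band], order=spe, fs=epochs.fs)
    n_ep, n_ch, _ = epochs.data.shape
    concat = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_ep * spe)
    filtered = signal.lfilter(taps, 1.0, concat, axis=1)
    stacked = filtered.reshape(n_ch, n_ep, spe).transpose(1, 0, 2)
    trimmed = stacked[1:]
    return EpochSet(
        data=np.ascontiguousarray(trimmed),
        fs=epochs.fs,
        subject_id=epochs.subject_id,
        band=band,
        channel_names=list(epochs.channel_names),
        provenance=epochs.provenance
        + [
            f"bandpass: {band} {cfg.bands[band]} Hz, causal FIR order {spe} (Hamming)",
            "trim: dropped first (transient) epoch",
        ],
    )
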