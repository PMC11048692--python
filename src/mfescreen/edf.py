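"""Minimal EDF (European Data Format) reader/writer.

Covers plain continuous EDF with a uniform sampling rate across signals:
fixed 256-byte ASCII header, 256 bytes per signal of field blocks, then data
records of little-endian int16 samples scaled channel-wise between the
declared physical and digital ranges. EDF+ annotations channels are ignored
on read. This is intentionally small — none of the scientific EDF libraries
is available in the target environment — and supports exactly what the
screening pipeline needs.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import ConfigError, MontageError
from .preprocess import RawRecording

_HEADER = 256
_PER_SIGNAL = 256


def _ascii(field: bytes) -> str:
    return field.decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike, subject_id: str | None = None) -> RawRecording:
    """Read a continuous EDF file into a :class:`RawRecording`.

    Requires every retained signal to share one sampling rate; annotation
    channels (label starting with 'EDF Annotations') are dropped.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER:
        raise MontageError(f"{path.name}: truncated EDF header")
    try:
        n_records = int(_ascii(raw[236:244]))
        record_seconds = float(_ascii(raw[244:252]))
        n_signals = int(_ascii(raw[252:256]))
    except ValueError as exc:
        raise MontageError(f"{path.name}: malformed EDF header: {exc}") from exc
    sig_hdr_end = _HEADER + _PER_SIGNAL * n_signals
    if len(raw) < sig_hdr_end:
        raise MontageError(f"{path.name}: truncated EDF signal header")

    def sig_field(offset: int, width: int, idx: int) -> str:
        start = _HEADER + offset * n_signals + width * idx
        return _ascii(raw[start : start + width])

    labels = [sig_field(0, 16, i) for i in range(n_signals)]
    phys_min = [float(sig_field(16 + 80 + 8, 8, i)) for i in range(n_signals)]
    phys_max = [float(sig_field(16 + 80 + 8 + 8, 8, i)) for i in range(n_signals)]
    dig_min = [float(sig_field(16 + 80 + 8 + 8 + 8, 8, i)) for i in range(n_signals)]
    dig_max = [float(sig_field(16 + 80 + 8 + 8 + 8 + 8, 8, i)) for i in range(n_signals)]
    n_samp = [
        int(sig_field(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8, i)) for i in range(n_signals)
    ]

    keep = [i for i, lab in enumerate(labels) if not lab.startswith("EDF Annotations")]
    if not keep:
        raise MontageError(f"{path.name}: no data signals in EDF")
    rates = {n_samp[i] / record_seconds for i in keep}
    if len(rates) != 1:
        raise MontageError(
            f"{path.name}: mixed sampling rates {sorted(rates)} not supported"
        )
    fs = rates.pop()

    record_len = sum(n_samp)
    payload = np.frombuffer(raw, dtype="<i2", offset=sig_hdr_end)
    if payload.size < n_records * record_len:
        raise MontageError(f"{path.name}: EDF data shorter than header declares")
    payload = payload[: n_records * record_len].reshape(n_records, record_len)

    offsets = np.cumsum([0] + n_samp)
    channels = []
    names = []
    for i in keep:
        digital = payload[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        if dig_max[i] == dig_min[i]:
            raise MontageError(f"{path.name}: signal {labels[i]!r} has zero digital range")
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels.append(phys_min[i] + gain * (digital - dig_min[i]))
        names.append(labels[i].removeprefix("EEG ").split("-")[0])
    return RawRecording(
        samples=np.stack(channels),
        fs=fs,
        channel_names=names,
        subject_id=subject_id or _ascii(raw[8:88]).split(" ")[0] or path.stem,
    )


def _field(text: str, width: int) -> bytes:
    out = text.encode("ascii")
    if len(out) > width:
        raise ConfigError(f"EDF header field {text!r} exceeds {width} bytes")
    return out.ljust(width)


def write_edf(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write a recording as continuous EDF (one 1-second record per second).

    Samples are scaled channel-wise to the int16 digital range; amplitudes are
    therefore quantized to ~1/65000 of the channel peak-to-peak range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-second record
    n_ch, n_total = rec.samples.shape
    n_records = n_total // spr
    if n_records * spr != n_total:
        raise ConfigError("recording length must be a whole number of seconds for EDF")

    header = b"".join(
        [
            _field("0", 8),
            _field(rec.subject_id[:80], 80),
            _field("mfescreen synthetic", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HEADER + _PER_SIGNAL * n_ch), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )

    phys_min = rec.samples.min(axis=1)
    phys_max = rec.samples.max(axis=1)
    span = phys_max - phys_min
    span[span == 0] = 1.0
    # pad so 8-byte rounding of the declared range cannot clip real samples
    phys_min = phys_min - 0.01 * span
    phys_max = phys_max + 0.01 * span
    dmin, dmax = -32768.0, 32767.0

    def col(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    def num8(v: float) -> str:
        for p in range(7, 0, -1):
            s = f"{v:.{p}g}"
            if len(s) <= 8:
                return s
        raise ConfigError(f"cannot encode {v} in an 8-byte EDF field")

    # quantize the declared physical range to what the 8-byte field can hold,
    # so the scaling written is exactly the scaling read back
    phys_min = np.array([float(num8(v)) for v in phys_min])
    phys_max = np.array([float(num8(v)) for v in phys_max])
    phys_max = np.where(phys_max <= phys_min, phys_min + 1.0, phys_max)
    span = phys_max - phys_min

    sig_hdr = b"".join(
        [
            col([f"EEG {c}" for c in rec.channel_names], 16),
            col(["" for _ in range(n_ch)], 80),  # transducer
            col(["uV" for _ in range(n_ch)], 8),
            col([num8(v) for v in phys_min], 8),
            col([num8(v) for v in phys_max], 8),
            col([f"{dmin:.0f}" for _ in range(n_ch)], 8),
            col([f"{dmax:.0f}" for _ in range(n_ch)], 8),
            col(["" for _ in range(n_ch)], 80),  # prefiltering
            col([str(spr) for _ in range(n_ch)], 8),
            col(["" for _ in range(n_ch)], 32),
        ]
    )

    gain = (dmax - dmin) / span
    digital = np.round((rec.samples - phys_min[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    # interleave into records: record r holds spr samples of each channel in turn
    records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig_hdr + records.tobytes())
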