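"""Synthetic 19-channel EEG generator with band-wise controllable regularity.

Each channel is a sum over the four narrow EEG bands of

    amp_b * [ sqrt(lam_b) * sinusoid(f_b) + sqrt(1 - lam_b) * band-noise_b ]

plus 1/f^gamma broadband noise partially shared across channels. The
regularity parameter lam_b in [0, 1] is the fraction of band energy
contributed by a drift-free oscillator: lam -> 1 gives a nearly periodic
(low-entropy) band, lam -> 0 a stochastic band-limited (high-entropy) band.

The two frozen group presets emulate the entropy ordering reported for
eyes-closed resting EEG in Alzheimer's disease versus healthy controls: the
AD-like preset is *more* regular (higher lam, lower entropy) in alpha and
beta and *less* regular in delta and theta, and carries more slow-band
power. The presets are a stated world for testing the pipeline, not a
biophysical EEG model.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .errors import ConfigError
from .preprocess import MONTAGE_1020, RawRecording

#: Oscillator frequency per band, Hz. Deliberately near the *low edge* of each
#: band: a tone at the band center is not reliably more regular (in the fuzzy
#: entropy sense, at 200 Hz) than band-limited noise — the two entropy curves
#: cross near the theta center — whereas a low-edge tone is, at every scale
#: factor the screening uses, so the regularity dial acts monotonically.
BAND_FREQS: Mapping[str, float] = {"delta": 1.5, "theta": 4.5, "alpha": 8.5, "beta": 14.5}

#: Band edges used for the band-limited noise component, Hz.
NOISE_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Per-band oscillator amplitude and regularity for one group."""

    amplitude: Mapping[str, float]
    regularity: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in BAND_FREQS:
            if name not in self.amplitude or name not in self.regularity:
                raise ConfigError(f"group params missing band {name!r}")
        for name, lam in self.regularity.items():
            if not 0.0 <= lam <= 1.0:
                raise ConfigError(f"regularity for {name!r} must be in [0, 1], got {lam}")
        for name, amp in self.amplitude.items():
            if amp < 0:
                raise ConfigError(f"amplitude for {name!r} must be >= 0, got {amp}")


#: Frozen default presets (calibrated once by simulation, then fixed).
#: Slow-band (delta, theta) amplitudes are equal across groups so band
#: regularity — not relative broadband contamination — drives the entropy
#: contrast; the AD-like slow-band *relative* power excess comes from its
#: reduced alpha/beta amplitudes.
HS_LIKE = GroupParams(
    amplitude={"delta": 1.0, "theta": 1.0, "alpha": 1.5, "beta": 0.9},
    regularity={"delta": 0.75, "theta": 0.75, "alpha": 0.20, "beta": 0.20},
)
AD_LIKE = GroupParams(
    amplitude={"delta": 1.0, "theta": 1.0, "alpha": 0.7, "beta": 0.45},
    regularity={"delta": 0.20, "theta": 0.20, "alpha": 0.75, "beta": 0.75},
)

#: A deliberately less separable preset pair for stress testing.
HS_LIKE_HARD = GroupParams(
    amplitude=HS_LIKE.amplitude,
    regularity={"delta": 0.55, "theta": 0.55, "alpha": 0.40, "beta": 0.40},
)
AD_LIKE_HARD = GroupParams(
    amplitude=AD_LIKE.amplitude,
    regularity={"delta": 0.40, "theta": 0.40, "alpha": 0.55, "beta": 0.55},
)


@dataclass(frozen=True)
class SynthParams:
    """Full generator configuration: one preset per group plus shared knobs.

    broadband_amp : SD of the 1/f^gamma broadband component.
    gamma : spectral slope of the broadband noise.
    channel_corr : fraction of broadband variance shared across channels.
    amp_jitter : per-subject lognormal sigma on band amplitudes.
    lam_jitter : per-subject Gaussian sigma on band regularities.
    """

    hs: GroupParams = HS_LIKE
    ad: GroupParams = AD_LIKE
    broadband_amp: float = 0.6
    gamma: float = 1.0
    channel_corr: float = 0.3
    amp_jitter: float = 0.10
    lam_jitter: float = 0.05
    n_epochs: int = 15
    epoch_seconds: float = 3.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.channel_corr <= 1.0:
            raise ConfigError("channel_corr must be in [0, 1]")
        if self.fs <= 0 or self.n_epochs < 1 or self.epoch_seconds <= 0:
            raise ConfigError("fs, n_epochs and epoch_seconds must be positive")

    def preset(self, name: str = "default") -> "SynthParams":
        if name == "default":
            return replace(self, hs=HS_LIKE, ad=AD_LIKE)
        if name == "hard":
            return replace(self, hs=HS_LIKE_HARD, ad=AD_LIKE_HARD)
        raise ConfigError(f"unknown preset {name!r}")


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _pink_noise(rng, n: int, gamma: float, fs: float) -> np.ndarray:
    """Unit-SD 1/f^gamma noise via spectral shaping (DC removed)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-gamma / 2.0)
    out = np.fft.irfft(spec * shaping, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def subject_seed(master_seed: int, group: str, index: int) -> np.random.SeedSequence:
    """Counter-based per-subject seed: reproducible and order-independent."""
    group_code = {"HS": 1, "AD": 2}[group]
    return np.random.SeedSequence([int(master_seed), group_code, int(index)])


def generate_subject(
    group: Literal["HS", "AD"],
    params: SynthParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str | None = None,
) -> RawRecording:
    """Generate one synthetic 19-channel recording for a group.

    ``group`` selects the HS-like or AD-like preset within ``params``. The
    same (group, params, seed) always yields a bit-identical recording.
    """
    params = params or SynthParams()
    if group == "HS":
        gp = params.hs
    elif group == "AD":
        gp = params.ad
    else:
        raise ConfigError(f"unknown group {group!r}; expected 'HS' or 'AD'")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    n = int(round(params.n_epochs * params.epoch_seconds * params.fs))
    t = np.arange(n) / params.fs
    n_ch = len(MONTAGE_1020)

    # per-subject parameter jitter (biological variability across subjects)
    amps = {
        b: gp.amplitude[b] * float(np.exp(rng.normal(0.0, params.amp_jitter)))
        for b in BAND_FREQS
    }
    lams = {
        b: float(np.clip(gp.regularity[b] + rng.normal(0.0, params.lam_jitter), 0.02, 0.98))
        for b in BAND_FREQS
    }

    common_pink = _pink_noise(rng, n, params.gamma, params.fs)
    data = np.zeros((n_ch, n))
    for ch in range(n_ch):
        x = np.zeros(n)
        for band, f in BAND_FREQS.items():
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc = np.sqrt(2.0) * np.sin(2.0 * np.pi * f * t + phase)  # unit SD
            noise = _band_noise(rng, n, NOISE_BANDS[band], params.fs)
            lam = lams[band]
            x += amps[band] * (np.sqrt(lam) * osc + np.sqrt(1.0 - lam) * noise)
        own_pink = _pink_noise(rng, n, params.gamma, params.fs)
        rho = params.channel_corr
        x += params.broadband_amp * (
            np.sqrt(rho) * common_pink + np.sqrt(1.0 - rho) * own_pink
        )
        data[ch] = x
    return RawRecording(
        samples=data,
        fs=params.fs,
        channel_names=list(MONTAGE_1020),
        subject_id=subject_id or f"{group}-synth",
        group_label=group,
    )


@dataclass
class SynthCohort:
    """A generated labelled cohort plus its per-subject seed manifest."""

    recordings: list[RawRecording]
    params: SynthParams
    master_seed: int
    manifest: list[dict] = field(default_factory=list)


def generate_cohort(
    n_hs: int,
    n_ad: int,
    params: SynthParams | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    fmt: Literal["csv", "edf"] = "csv",
) -> SynthCohort:
    """Generate a labelled cohort; optionally write one file per subject plus
    a ``labels.csv`` manifest (columns subject_id, path, true_label) that the
    ``evaluate`` command consumes."""
    if n_hs < 1 or n_ad < 1:
        raise ConfigError("need at least one subject per group")
    params = params or SynthParams()
    recordings: list[RawRecording] = []
    manifest: list[dict] = []
    for group, count in (("HS", n_hs), ("AD", n_ad)):
        for i in range(count):
            sid = f"{group}{i + 1:03d}"
            rec = generate_subject(
                group, params, seed=subject_seed(seed, group, i), subject_id=sid
            )
            recordings.append(rec)
            manifest.append({"subject_id": sid, "path": "", "true_label": group})
    cohort = SynthCohort(
        recordings=recordings, params=params, master_seed=seed, manifest=manifest
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_subject_csv
        from .edf import write_edf

        for rec, row in zip(recordings, manifest):
            fname = f"{rec.subject_id}.{fmt}"
            path = out / fname
            if fmt == "csv":
                write_subject_csv(rec, path)
            elif fmt == "edf":
                write_edf(rec, path)
            else:
                raise ConfigError(f"unknown output format {fmt!r}")
            row["path"] = fname
        with open(out / "labels.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["subject_id", "path", "true_label"])
            writer.writeheader()
            writer.writerows(manifest)
        with open(out / "cohort.json", "w") as fh:
            json.dump({"seed": seed, "n_hs": n_hs, "n_ad": n_ad, "fs": params.fs}, fh)
    return cohort
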