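"""Fuzzy entropy, coarse-graining, and the per-subject MFE tensor.

Fuzzy entropy FuzzyEn(m, n, r) of a series is ln Phi_m - ln Phi_{m+1}, where
Phi_m is the mean over all template pairs i != j of the fuzzy membership
exp(-(d_ij / r)^n) and d_ij is the Chebyshev distance between the two
baseline-removed templates of length m (each template minus its own mean).
Because adding a point to a template cannot decrease the Chebyshev distance,
Phi_{m+1} <= Phi_m and the entropy is non-negative.

The multiscale extension computes the same statistic on coarse-grained
versions of the series. The default coarse-graining is an overlapping moving
average of window s (sum / s); the overlapping moving *sum* and the classic
non-overlapping average are selectable. The tolerance is fixed in absolute
units from the scale-1 series (r_abs = r x SD) and is *not* recomputed per
scale, following standard multiscale-entropy practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._fuzzen import _phi_pair
from .errors import ConfigError, IncompatibleConfigError
from .preprocess import EpochSet, MONTAGE_1020

COARSE_MODES = ("moving-average", "moving-sum", "nonoverlapping-average")


@dataclass(frozen=True)
class MFEConfig:
    """Parameters of the multiscale fuzzy entropy computation.

    m : embedding dimension (template length).
    r : tolerance as a fraction of the scale-1 epoch standard deviation.
    n : fuzzy membership exponent (2 = Gaussian-like membership).
    scales : scale factors to evaluate (default 1..20).
    coarse_mode : coarse-graining variant, see module docstring.
    """

    m: int = 2
    r: float = 0.20
    n: float = 2.0
    scales: tuple[int, ...] = tuple(range(1, 21))
    coarse_mode: str = "moving-average"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ConfigError("tolerance fraction r must be positive")
        if self.n <= 0:
            raise ConfigError("membership exponent n must be positive")
        if not self.scales or any(int(s) != s or s < 1 for s in self.scales):
            raise ConfigError("scales must be positive integers")
        if self.coarse_mode not in COARSE_MODES:
            raise ConfigError(
                f"coarse_mode {self.coarse_mode!r} not in {COARSE_MODES}"
            )

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "r": self.r,
            "n": self.n,
            "scales": list(self.scales),
            "coarse_mode": self.coarse_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MFEConfig":
        known = {"m", "r", "n", "scales", "coarse_mode"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown MFE config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "scales" in kwargs:
            kwargs["scales"] = tuple(int(s) for s in kwargs["scales"])
        return cls(**kwargs)


@dataclass
class MFETensor:
    """Per-subject entropy grid: band x channel x scale, averaged over epochs.

    Cells where every epoch saturated (membership mean underflowed to zero at
    dimension m+1) are NaN and are skipped by downstream scoring.
    """

    values: np.ndarray
    bands: tuple[str, ...]
    scales: tuple[int, ...]
    channel_names: tuple[str, ...] = MONTAGE_1020
    subject_id: str = "unknown"
    group_label: str | None = None
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.bands), len(self.channel_names), len(self.scales))
        if self.values.shape != expected:
            raise ConfigError(
                f"MFE tensor shape {self.values.shape} does not match "
                f"bands x channels x scales = {expected}"
            )


def coarse_grain(x: np.ndarray, s: int, mode: str = "moving-average") -> np.ndarray:
    """Coarse-grain a series at scale factor ``s``.

    Overlapping modes return length N - s + 1 (element j is the sum or mean of
    x[j .. j+s-1]); the non-overlapping classic mode returns length floor(N/s).
    Scale 1 is the identity for every mode.
    """
    x = np.asarray(x, dtype=np.float64)
    N = x.shape[0]
    if s < 1 or s > N:
        raise ConfigError(f"scale factor {s} out of range for series of length {N}")
    if mode not in COARSE_MODES:
        raise ConfigError(f"coarse mode {mode!r} not in {COARSE_MODES}")
    if s == 1:
        return x.copy()
    if mode == "nonoverlapping-average":
        n_win = N // s
        return x[: n_win * s].reshape(n_win, s).mean(axis=1)
    kernel_sum = np.convolve(x, np.ones(s), mode="valid")
    if mode == "moving-sum":
        return kernel_sum
    return kernel_sum / s


def fuzzy_entropy(x: np.ndarray, m: int = 2, r_abs: float = 0.2, n: float = 2.0) -> float:
    """Fuzzy entropy of a series with absolute tolerance ``r_abs``.

    Returns ``math.inf`` (a saturation flag) when the dimension-(m+1)
    membership mean underflows to zero.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.shape[0] < m + 2:
        raise ConfigError(
            f"series of length {x.shape[0]} too short for m = {m} (need >= {m + 2})"
        )
    if r_abs <= 0:
        raise ConfigError("absolute tolerance r_abs must be positive")
    phi_m, phi_m1 = _phi_pair(x, m, float(r_abs), float(n))
    if phi_m1 == 0.0:
        return math.inf
    value = math.log(phi_m) - math.log(phi_m1)
    # tiny negative values can arise from floating round-off only
    return max(value, 0.0) if value > -1e-12 else value


def mfe_profile(epoch: np.ndarray, cfg: MFEConfig) -> np.ndarray:
    """Multiscale fuzzy entropy profile of one epoch over ``cfg.scales``.

    The tolerance is r x SD of the raw (scale-1) epoch, held fixed across
    scales. A constant epoch has zero entropy at every scale.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    max_s = max(cfg.scales)
    if epoch.shape[0] < max_s + cfg.m + 2:
        raise ConfigError(
            f"epoch of length {epoch.shape[0]} too short for scale {max_s} "
            f"with m = {cfg.m}"
        )
    sd = float(np.std(epoch, ddof=1))
    if sd == 0.0:
        return np.zeros(len(cfg.scales))
    r_abs = cfg.r * sd
    out = np.empty(len(cfg.scales))
    for i, s in enumerate(cfg.scales):
        y = coarse_grain(epoch, int(s), cfg.coarse_mode)
        out[i] = fuzzy_entropy(y, cfg.m, r_abs, cfg.n)
    return out


def subject_mfe(
    banded_epochs: Mapping[str, EpochSet],
    cfg: MFEConfig,
    *,
    fingerprint: str = "",
) -> MFETensor:
    """Per-subject MFE tensor: mean profile over epochs for every band/channel.

    Saturated (infinite) per-epoch values are excluded from the mean; a cell
    where every epoch saturates becomes NaN and is flagged for downstream
    skipping.
    """
    if not banded_epochs:
        raise ConfigError("no bands supplied")
    bands = tuple(banded_epochs)
    first = banded_epochs[bands[0]]
    n_sat = 0
    for b, es in banded_epochs.items():
        if es.n_epochs != first.n_epochs or es.n_channels != first.n_channels:
            raise IncompatibleConfigError(
                f"band {b!r} epoch stack shape differs from band {bands[0]!r}"
            )
    values = np.empty((len(bands), first.n_channels, len(cfg.scales)))
    for bi, b in enumerate(bands):
        stack = banded_epochs[b].data
        for ci in range(first.n_channels):
            profiles = np.stack(
                [mfe_profile(stack[ei, ci], cfg) for ei in range(stack.shape[0])]
            )
            finite = np.isfinite(profiles)
            n_sat += int(profiles.size - finite.sum())
            with np.errstate(invalid="ignore"):
                sums = np.where(finite, profiles, 0.0).sum(axis=0)
                counts = finite.sum(axis=0)
                values[bi, ci] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if n_sat:
        import logging

        logging.getLogger(__name__).info(
            "subject %s: %d saturated epoch entropy values excluded from averaging",
            first.subject_id,
            n_sat,
        )
    return MFETensor(
        values=values,
        bands=bands,
        scales=tuple(int(s) for s in cfg.scales),
        channel_names=tuple(first.channel_names),
        subject_id=first.subject_id,
        group_label=getattr(first, "group_label", None),
        config_fingerprint=fingerprint,
    )
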