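"""Reference model: per-cell group statistics, intervals, and penalty factors.

For every (band, channel, scale) cell, labelled cohorts define two reference
intervals on the entropy axis:

    mean  m_g = (1/N) sum MFE_i            (per group g in {HS, AD})
    uncertainty  u_g = 1.96 * s_g / sqrt(N)   (95% CI half-width, sample SD)
    interval  [beta_g, alpha_g] = [m_g - u_g, m_g + u_g]

The orientation of the standardized scale in a cell is *direct* when
m_HS > m_AD (higher entropy means healthier there) and *inverse* otherwise.
Cells with large uncertainty or overlapping intervals are down-weighted by a
penalty factor

    Pf = 1 + ln(u + ol + 1),   u = (u_HS + u_AD) / 2

which is 1 exactly when both the mean uncertainty and the overlap vanish.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entropy import MFETensor
from .errors import (
    ConfigError,
    IncompatibleConfigError,
    InsufficientCohortError,
    SchemaError,
)

SCHEMA_VERSION = "1"


def group_stats(values: Sequence[float]) -> tuple[float, float]:
    """Group mean and mean uncertainty (95% CI half-width) of MFE values.

    u = 1.96 * sample SD / sqrt(N); requires at least two finite values.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise InsufficientCohortError(
            f"need at least 2 values for group statistics, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InsufficientCohortError("group values must all be finite")
    mean = float(arr.mean())
    u = 1.96 * float(arr.std(ddof=1)) / math.sqrt(arr.size)
    return mean, u


def interval_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Overlap length of two closed intervals (lo, hi) on the entropy axis."""
    (lo_a, hi_a), (lo_b, hi_b) = a, b
    if hi_a < lo_a or hi_b < lo_b:
        raise ConfigError("interval bounds out of order")
    return max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))


def penalty_factor(u_hs: float, u_ad: float, ol: float) -> float:
    """Penalty factor Pf = 1 + ln(u + ol + 1) with u the mean uncertainty.

    Pf >= 1, equal to 1 only in the ideal zero-uncertainty, zero-overlap case,
    and strictly increasing in both the uncertainty and the overlap.
    """
    if u_hs < 0 or u_ad < 0 or ol < 0:
        raise ConfigError("uncertainties and overlap must be non-negative")
    u = (u_hs + u_ad) / 2.0
    return 1.0 + math.log(u + ol + 1.0)


@dataclass(frozen=True, eq=False)
class ReferenceCell:
    """Reference statistics of one (band, channel, scale) cell."""

    band: str
    channel: str
    scale: int
    m_hs: float
    u_hs: float
    m_ad: float
    u_ad: float
    orientation: str  # "direct" (m_hs > m_ad) or "inverse"
    ol: float
    pf: float
    valid: bool = True

    def __eq__(self, other: object) -> bool:
        # NaN-aware equality so invalid cells round-trip losslessly
        if not isinstance(other, ReferenceCell):
            return NotImplemented

        def same(a: float, b: float) -> bool:
            return a == b or (isinstance(a, float) and isinstance(b, float)
                              and math.isnan(a) and math.isnan(b))

        return (
            (self.band, self.channel, self.scale) == (other.band, other.channel, other.scale)
            and self.orientation == other.orientation
            and self.valid == other.valid
            and all(
                same(getattr(self, f), getattr(other, f))
                for f in ("m_hs", "u_hs", "m_ad", "u_ad", "ol", "pf")
            )
        )

    def __hash__(self) -> int:
        return hash((self.band, self.channel, self.scale))

    @property
    def alpha_hs(self) -> float:
        return self.m_hs + self.u_hs

    @property
    def beta_hs(self) -> float:
        return self.m_hs - self.u_hs

    @property
    def alpha_ad(self) -> float:
        return self.m_ad + self.u_ad

    @property
    def beta_ad(self) -> float:
        return self.m_ad - self.u_ad

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "channel": self.channel,
            "scale": self.scale,
            "m_hs": self.m_hs,
            "u_hs": self.u_hs,
            "m_ad": self.m_ad,
            "u_ad": self.u_ad,
            "alpha_hs": self.alpha_hs,
            "beta_hs": self.beta_hs,
            "alpha_ad": self.alpha_ad,
            "beta_ad": self.beta_ad,
            "orientation": self.orientation,
            "ol": self.ol,
            "pf": self.pf,
            "valid": self.valid,
        }


def make_cell(
    band: str,
    channel: str,
    scale: int,
    hs_values: Sequence[float],
    ad_values: Sequence[float],
) -> ReferenceCell:
    """Build one reference cell from per-group MFE samples.

    A cell is invalid when either group lacks two finite values or the group
    means coincide exactly (orientation undefined).
    """
    hs = np.asarray(hs_values, dtype=np.float64)
    ad = np.asarray(ad_values, dtype=np.float64)
    hs = hs[np.isfinite(hs)]
    ad = ad[np.isfinite(ad)]
    if hs.size < 2 or ad.size < 2:
        return ReferenceCell(band, channel, scale, math.nan, math.nan, math.nan,
                             math.nan, "direct", 0.0, 1.0, valid=False)
    m_hs, u_hs = group_stats(hs)
    m_ad, u_ad = group_stats(ad)
    if m_hs == m_ad:
        return ReferenceCell(band, channel, scale, m_hs, u_hs, m_ad, u_ad,
                             "direct", 0.0, 1.0, valid=False)
    orientation = "direct" if m_hs > m_ad else "inverse"
    ol = interval_overlap((m_hs - u_hs, m_hs + u_hs), (m_ad - u_ad, m_ad + u_ad))
    pf = penalty_factor(u_hs, u_ad, ol)
    return ReferenceCell(band, channel, scale, m_hs, u_hs, m_ad, u_ad,
                         orientation, ol, pf, valid=True)


@dataclass
class ReferenceModel:
    """Complete reference grid plus cohort metadata."""

    cells: dict[tuple[str, str, int], ReferenceCell]
    bands: tuple[str, ...]
    channel_names: tuple[str, ...]
    scales: tuple[int, ...]
    n_hs: int
    n_ad: int
    hs_ids: tuple[str, ...] = ()
    ad_ids: tuple[str, ...] = ()
    config_fingerprint: str = ""
    version: str = SCHEMA_VERSION

    def cell(self, band: str, channel: str, scale: int) -> ReferenceCell:
        return self.cells[(band, channel, scale)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceModel):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.bands == other.bands
            and self.channel_names == other.channel_names
            and self.scales == other.scales
            and self.n_hs == other.n_hs
            and self.n_ad == other.n_ad
            and self.hs_ids == other.hs_ids
            and self.ad_ids == other.ad_ids
            and self.config_fingerprint == other.config_fingerprint
            and self.version == other.version
        )


def build_reference(
    hs: Sequence[MFETensor], ad: Sequence[MFETensor]
) -> ReferenceModel:
    """Build the reference model from labelled cohorts of MFE tensors.

    All tensors must share band/channel/scale axes and configuration
    fingerprint; both cohorts need at least two subjects.
    """
    if len(hs) < 2 or len(ad) < 2:
        raise InsufficientCohortError(
            f"need >= 2 subjects per group, got {len(hs)} HS and {len(ad)} AD"
        )
    ref = hs[0]
    for t in list(hs) + list(ad):
        if (t.bands, t.channel_names, t.scales) != (ref.bands, ref.channel_names, ref.scales):
            raise IncompatibleConfigError(
                f"tensor {t.subject_id!r} axes differ from {ref.subject_id!r}"
            )
        if t.config_fingerprint != ref.config_fingerprint:
            raise IncompatibleConfigError(
                f"tensor {t.subject_id!r} fingerprint {t.config_fingerprint!r} "
                f"differs from {ref.config_fingerprint!r}"
            )
    hs_stack = np.stack([t.values for t in hs])  # subjects x band x ch x scale
    ad_stack = np.stack([t.values for t in ad])
    cells: dict[tuple[str, str, int], ReferenceCell] = {}
    for bi, band in enumerate(ref.bands):
        for ci, channel in enumerate(ref.channel_names):
            for si, scale in enumerate(ref.scales):
                cells[(band, channel, scale)] = make_cell(
                    band, channel, int(scale),
                    hs_stack[:, bi, ci, si], ad_stack[:, bi, ci, si],
                )
    return ReferenceModel(
        cells=cells,
        bands=ref.bands,
        channel_names=ref.channel_names,
        scales=tuple(int(s) for s in ref.scales),
        n_hs=len(hs),
        n_ad=len(ad),
        hs_ids=tuple(t.subject_id for t in hs),
        ad_ids=tuple(t.subject_id for t in ad),
        config_fingerprint=ref.config_fingerprint,
    )


def save_reference(model: ReferenceModel, path: str | os.PathLike) -> None:
    """Serialize a reference model to JSON (schema version 1)."""
    payload = {
        "version": model.version,
        "config_fingerprint": model.config_fingerprint,
        "bands": list(model.bands),
        "channels": list(model.channel_names),
        "scales": list(model.scales),
        "cohort": {
            "n_hs": model.n_hs,
            "n_ad": model.n_ad,
            "hs_ids": list(model.hs_ids),
            "ad_ids": list(model.ad_ids),
        },
        "cells": [model.cells[k].to_dict() for k in sorted(model.cells)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True)


_CELL_KEYS = {
    "band", "channel", "scale", "m_hs", "u_hs", "m_ad", "u_ad",
    "alpha_hs", "beta_hs", "alpha_ad", "beta_ad", "orientation", "ol", "pf", "valid",
}


def load_reference(path: str | os.PathLike) -> ReferenceModel:
    """Load and validate a reference model; refuses unknown schema versions."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read reference model {path!r}: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError("reference model must be a JSON object")
    version = payload.get("version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported reference schema version {version!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    required = {"bands", "channels", "scales", "cohort", "cells", "config_fingerprint"}
    missing = required - set(payload)
    if missing:
        raise SchemaError(f"reference model missing keys: {sorted(missing)}")
    cells: dict[tuple[str, str, int], ReferenceCell] = {}
    for raw in payload["cells"]:
        if set(raw) != _CELL_KEYS:
            raise SchemaError(
                f"malformed reference cell keys: {sorted(set(raw) ^ _CELL_KEYS)}"
            )
        cell = ReferenceCell(
            band=raw["band"], channel=raw["channel"], scale=int(raw["scale"]),
            m_hs=raw["m_hs"], u_hs=raw["u_hs"], m_ad=raw["m_ad"], u_ad=raw["u_ad"],
            orientation=raw["orientation"], ol=raw["ol"], pf=raw["pf"],
            valid=raw["valid"],
        )
        cells[(cell.band, cell.channel, cell.scale)] = cell
    bands = tuple(payload["bands"])
    channels = tuple(payload["channels"])
    scales = tuple(int(s) for s in payload["scales"])
    expected = {(b, c, s) for b in bands for c in channels for s in scales}
    if set(cells) != expected:
        raise SchemaError("reference model cell grid is incomplete")
    cohort = payload["cohort"]
    return ReferenceModel(
        cells=cells,
        bands=bands,
        channel_names=channels,
        scales=scales,
        n_hs=int(cohort["n_hs"]),
        n_ad=int(cohort["n_ad"]),
        hs_ids=tuple(cohort.get("hs_ids", ())),
        ad_ids=tuple(cohort.get("ad_ids", ())),
        config_fingerprint=payload["config_fingerprint"],
        version=version,
    )
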