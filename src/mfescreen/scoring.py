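"""Standardized-scale scoring of a subject under test (SUT).

Each cell of the subject's MFE tensor is compared with the cell's two
reference intervals and mapped onto a standardized scale running from -3 to
+3: the AD interval occupies [-3, -1] (its mean at -2), the HS interval
[+1, +3] (its mean at +2), and the gap between the facing edges is the
intermediate zone [-1, +1]. For a *direct* cell (m_HS > m_AD) the scale
ascends with entropy; for an *inverse* cell it descends. The affine map of
the zone the value falls in gives phi0 (clamped to [-3, +3]); the final
weight is phi = phi0 / Pf, so poorly separated or uncertain cells contribute
less.

Per-subject aggregation yields two percentage indices: I_AD and I_HS, the
shares of total |phi| mass pointing to the AD-like and healthy-like
condition. In the default "zone" mode the numerators are restricted to cells
whose value actually falls in the AD/HS interval, so intermediate-zone cells
dilute both indices and the two do not generally sum to 100%. The literal
"sign" mode splits the numerators by the sign of phi instead (the two then
sum to 100% whenever no phi is exactly zero).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .entropy import MFETensor
from .errors import ConfigError, IncompatibleConfigError
from .reference import ReferenceCell, ReferenceModel

Zone = Literal["HS", "AD", "intermediate", "skipped"]
IndexMode = Literal["zone", "sign"]


@dataclass(frozen=True)
class PhiRecord:
    """Score of one (band, channel, scale) cell for a subject under test."""

    band: str
    channel: str
    scale: int
    x_sut: float
    zone: str
    phi0: float
    phi: float


@dataclass
class PhiTensor:
    """All per-cell scores of one subject."""

    records: list[PhiRecord]
    subject_id: str = "unknown"

    def __iter__(self):
        return iter(self.records)

    @property
    def n_skipped(self) -> int:
        return sum(1 for r in self.records if r.zone == "skipped")

    @property
    def n_used(self) -> int:
        return len(self.records) - self.n_skipped


@dataclass
class SubjectReport:
    """Final screening indices and predicted label for one subject."""

    subject_id: str
    i_ad: float
    i_hs: float
    predicted: str  # "AD", "HS" or "indeterminate"
    n_cells_used: int
    n_cells_skipped: int
    index_mode: str
    per_band: dict[str, dict[str, float]] = field(default_factory=dict)
    per_channel_phi: dict[str, float] = field(default_factory=dict)
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "i_ad": self.i_ad,
            "i_hs": self.i_hs,
            "predicted": self.predicted,
            "n_cells_used": self.n_cells_used,
            "n_cells_skipped": self.n_cells_skipped,
            "index_mode": self.index_mode,
            "per_band": self.per_band,
            "per_channel_phi": self.per_channel_phi,
            "config_fingerprint": self.config_fingerprint,
        }


def assign_zone(x: float, cell: ReferenceCell) -> Zone:
    """Locate an entropy value relative to a cell's two reference intervals.

    Inside exactly one interval -> that group's zone. Inside both
    (overlapping intervals) -> the group whose mean is nearer; an exact tie is
    intermediate. In the gap between the facing edges -> intermediate. Beyond
    the outermost extremes -> the adjacent group's zone (phi0 is clamped
    later).
    """
    if not cell.valid or not math.isfinite(x):
        return "skipped"
    in_hs = cell.beta_hs <= x <= cell.alpha_hs
    in_ad = cell.beta_ad <= x <= cell.alpha_ad
    if in_hs and in_ad:
        d_hs = abs(x - cell.m_hs)
        d_ad = abs(x - cell.m_ad)
        if d_hs < d_ad:
            return "HS"
        if d_ad < d_hs:
            return "AD"
        return "intermediate"
    if in_hs:
        return "HS"
    if in_ad:
        return "AD"
    # outside both: either the inter-interval gap, or beyond an outer extreme
    if cell.orientation == "direct":
        if x > cell.alpha_hs:
            return "HS"
        if x < cell.beta_ad:
            return "AD"
    else:
        if x < cell.beta_hs:
            return "HS"
        if x > cell.alpha_ad:
            return "AD"
    return "intermediate"


def _affine(x: float, x0: float, x1: float, e0: float, e1: float) -> float:
    """Map x by the affine function sending x0 -> e0 and x1 -> e1."""
    if x1 == x0:
        # degenerate interval: only the single point can be in this zone;
        # intermediate degenerate gap maps to the scale midpoint
        return (e0 + e1) / 2.0
    return (x - x0) / (x1 - x0) * (e1 - e0) + e0


def phi0_score(x: float, cell: ReferenceCell, zone: Zone | None = None) -> float:
    """Standardized-scale score phi0 of an entropy value in a cell.

    Applies the zone's affine map (group means -> +/-2, facing interval edges
    -> +/-1, outer extremes -> +/-3, direction set by the cell orientation)
    and clamps the result to [-3, +3].
    """
    if zone is None:
        zone = assign_zone(x, cell)
    if zone == "skipped":
        raise ConfigError("cannot score a skipped cell")
    direct = cell.orientation == "direct"
    if zone == "HS":
        if direct:
            phi0 = _affine(x, cell.beta_hs, cell.alpha_hs, 1.0, 3.0)
        else:
            phi0 = _affine(x, cell.beta_hs, cell.alpha_hs, 3.0, 1.0)
    elif zone == "AD":
        if direct:
            phi0 = _affine(x, cell.beta_ad, cell.alpha_ad, -3.0, -1.0)
        else:
            phi0 = _affine(x, cell.beta_ad, cell.alpha_ad, -1.0, -3.0)
    else:  # intermediate
        if direct:
            phi0 = _affine(x, cell.alpha_ad, cell.beta_hs, -1.0, 1.0)
        else:
            phi0 = _affine(x, cell.alpha_hs, cell.beta_ad, 1.0, -1.0)
    return float(np.clip(phi0, -3.0, 3.0))


def phi_score(phi0: float, cell: ReferenceCell) -> float:
    """Penalty-weighted score phi = phi0 / Pf."""
    if cell.pf < 1.0:
        raise ConfigError(f"penalty factor {cell.pf} < 1")
    return phi0 / cell.pf


def score_cells(tensor: MFETensor, model: ReferenceModel) -> PhiTensor:
    """Score every cell of a subject's MFE tensor against the reference."""
    if tensor.config_fingerprint and model.config_fingerprint and (
        tensor.config_fingerprint != model.config_fingerprint
    ):
        raise IncompatibleConfigError(
            f"subject tensor fingerprint {tensor.config_fingerprint!r} does not "
            f"match reference model {model.config_fingerprint!r}"
        )
    if (tensor.bands, tensor.channel_names, tensor.scales) != (
        model.bands, model.channel_names, model.scales
    ):
        raise IncompatibleConfigError("tensor axes do not match reference model grid")
    records = []
    for bi, band in enumerate(tensor.bands):
        for ci, channel in enumerate(tensor.channel_names):
            for si, scale in enumerate(tensor.scales):
                x = float(tensor.values[bi, ci, si])
                cell = model.cell(band, channel, scale)
                zone = assign_zone(x, cell)
                if zone == "skipped":
                    records.append(PhiRecord(band, channel, scale, x, zone, 0.0, 0.0))
                    continue
                phi0 = phi0_score(x, cell, zone)
                records.append(
                    PhiRecord(band, channel, scale, x, zone, phi0, phi_score(phi0, cell))
                )
    return PhiTensor(records=records, subject_id=tensor.subject_id)


def compute_indices(
    phis: PhiTensor | Iterable[PhiRecord], mode: IndexMode = "zone"
) -> tuple[float, float]:
    """Aggregate per-cell phi values into (I_AD, I_HS) percentage indices.

    The denominator is the total |phi| over all non-skipped cells. In "zone"
    mode the numerators are the |phi| mass of AD-zone and HS-zone cells;
    intermediate cells count only in the denominator. In "sign" mode the
    numerators split by the sign of phi.
    """
    records = [r for r in phis if r.zone != "skipped"]
    if not records:
        raise ConfigError("all cells skipped; indices are undefined")
    denom = sum(abs(r.phi) for r in records)
    if denom == 0.0:
        return 0.0, 0.0
    if mode == "zone":
        num_ad = sum(abs(r.phi) for r in records if r.zone == "AD")
        num_hs = sum(abs(r.phi) for r in records if r.zone == "HS")
    elif mode == "sign":
        num_ad = sum(-r.phi for r in records if r.phi < 0)
        num_hs = sum(r.phi for r in records if r.phi > 0)
    else:
        raise ConfigError(f"unknown index mode {mode!r}")
    return 100.0 * num_ad / denom, 100.0 * num_hs / denom


def classify(i_ad: float, i_hs: float) -> str:
    """Predicted label by the greater-index rule; an exact tie is indeterminate."""
    if i_ad > i_hs:
        return "AD"
    if i_hs > i_ad:
        return "HS"
    return "indeterminate"


def score_subject(
    tensor: MFETensor, model: ReferenceModel, index_mode: IndexMode = "zone"
) -> tuple[PhiTensor, SubjectReport]:
    """Full scoring of one subject: per-cell phi values plus the final report."""
    phis = score_cells(tensor, model)
    i_ad, i_hs = compute_indices(phis, index_mode)
    per_band: dict[str, dict[str, float]] = {}
    for band in tensor.bands:
        band_records = [r for r in phis if r.band == band and r.zone != "skipped"]
        if band_records:
            b_ad, b_hs = compute_indices(band_records, index_mode)
            per_band[band] = {"i_ad": b_ad, "i_hs": b_hs}
    per_channel: dict[str, float] = {}
    for channel in tensor.channel_names:
        vals = [r.phi for r in phis if r.channel == channel and r.zone != "skipped"]
        if vals:
            per_channel[channel] = float(np.mean(vals))
    report = SubjectReport(
        subject_id=tensor.subject_id,
        i_ad=i_ad,
        i_hs=i_hs,
        predicted=classify(i_ad, i_hs),
        n_cells_used=phis.n_used,
        n_cells_skipped=phis.n_skipped,
        index_mode=index_mode,
        per_band=per_band,
        per_channel_phi=per_channel,
        config_fingerprint=tensor.config_fingerprint,
    )
    return phis, report


def save_report(report: SubjectReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def save_phis_csv(phis: PhiTensor, path: str | os.PathLike) -> None:
    """Long-format CSV of per-cell scores: band, channel, scale, x_sut, zone, phi0, phi."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "band": r.band, "channel": r.channel, "scale": r.scale,
                "x_sut": r.x_sut, "zone": r.zone, "phi0": r.phi0, "phi": r.phi,
            }
            for r in phis
        ]
    )
    frame.to_csv(path, index=False)
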