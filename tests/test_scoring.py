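"""Standardized-scale scoring: zones, phi0/phi, indices, labels."""

import numpy as np
import pytest

import mfescreen as m
from mfescreen import MFETensor
from mfescreen.errors import ConfigError
from mfescreen.scoring import PhiRecord, PhiTensor

from conftest import build_cell


class TestAssignZone:
    def test_mean_is_inside_own_interval(self):
        cell = build_cell(2.0, 0.2, 1.0, 0.2)
        assert m.assign_zone(2.0, cell) == "HS"
        assert m.assign_zone(1.0, cell) == "AD"

    def test_gap_midpoint_is_intermediate(self):
        cell = build_cell(2.0, 0.2, 1.0, 0.2)  # HS [1.8, 2.2], AD [0.8, 1.2]
        assert m.assign_zone(1.5, cell) == "intermediate"

    def test_overlap_resolved_by_nearest_mean(self):
        # HS [1.0, 2.0] (mean 1.5), AD [1.5, 2.5] (mean 2.0): inverse cell
        cell = build_cell(1.5, 0.5, 2.0, 0.5)
        assert m.assign_zone(1.9, cell) == "AD"
        assert m.assign_zone(1.6, cell) == "HS"
        assert m.assign_zone(1.75, cell) == "intermediate"  # exact tie

    def test_beyond_outer_extremes_keeps_adjacent_group(self):
        direct = build_cell(2.0, 0.2, 1.0, 0.2)
        assert m.assign_zone(2.5, direct) == "HS"
        assert m.assign_zone(0.5, direct) == "AD"
        inverse = build_cell(1.0, 0.2, 2.0, 0.2)
        assert m.assign_zone(0.5, inverse) == "HS"
        assert m.assign_zone(2.5, inverse) == "AD"

    def test_invalid_cell_skipped(self):
        from dataclasses import replace

        cell = build_cell(2.0, 0.2, 1.0, 0.2)
        invalid = replace(cell, valid=False)
        assert m.assign_zone(2.0, invalid) == "skipped"
        assert m.assign_zone(float("nan"), cell) == "skipped"


class TestPhi0:
    @pytest.mark.parametrize("orientation_cell", [
        build_cell(2.0, 0.2, 1.0, 0.2),   # direct
        build_cell(1.0, 0.2, 2.0, 0.2),   # inverse
    ])
    def test_group_means_map_to_plus_minus_two(self, orientation_cell):
        cell = orientation_cell
        assert m.phi0_score(cell.m_hs, cell) == pytest.approx(2.0)
        assert m.phi0_score(cell.m_ad, cell) == pytest.approx(-2.0)

    def test_interval_edge_images_direct(self):
        cell = build_cell(2.0, 0.2, 1.0, 0.2)
        assert m.phi0_score(cell.beta_hs, cell) == pytest.approx(1.0)
        assert m.phi0_score(cell.alpha_hs, cell) == pytest.approx(3.0)
        assert m.phi0_score(cell.alpha_ad, cell) == pytest.approx(-1.0)
        assert m.phi0_score(cell.beta_ad, cell) == pytest.approx(-3.0)

    def test_interval_edge_images_inverse(self):
        cell = build_cell(1.0, 0.2, 2.0, 0.2)
        assert m.phi0_score(cell.alpha_hs, cell) == pytest.approx(1.0)
        assert m.phi0_score(cell.beta_hs, cell) == pytest.approx(3.0)
        assert m.phi0_score(cell.beta_ad, cell) == pytest.approx(-1.0)
        assert m.phi0_score(cell.alpha_ad, cell) == pytest.approx(-3.0)

    def test_extrapolation_clamped(self):
        cell = build_cell(2.0, 0.2, 1.0, 0.2)  # alpha_HS = 2.2
        assert m.phi0_score(2.8, cell) == 3.0
        assert m.phi0_score(0.1, cell) == -3.0

    def test_degenerate_interval_maps_mean(self):
        cell = build_cell(2.0, 0.0, 1.0, 0.2)
        assert m.phi0_score(2.0, cell) == pytest.approx(2.0)

    @pytest.mark.parametrize("m_hs, m_ad", [(2.0, 1.0), (1.0, 2.0)])
    def test_continuity_and_monotonicity(self, m_hs, m_ad):
        cell = build_cell(m_hs, 0.2, m_ad, 0.3)
        xs = np.linspace(0.4, 2.6, 2201)
        phi0 = np.array([m.phi0_score(x, cell) for x in xs])
        assert np.all(np.abs(phi0) <= 3.0)
        # continuity: no jump exceeds the local affine slope bound
        assert np.max(np.abs(np.diff(phi0))) < 0.06
        direction = 1.0 if m_hs > m_ad else -1.0
        assert np.all(direction * np.diff(phi0) >= -1e-12)


class TestPhiAndIndices:
    def test_phi_unchanged_at_unit_penalty(self):
        cell = build_cell(2.0, 0.0, 1.0, 0.0)
        assert cell.pf == 1.0
        assert m.phi_score(2.4, cell) == 2.4

    def test_phi_divides_by_penalty(self):
        cell = build_cell(2.0, 0.3, 1.6, 0.3)
        assert cell.pf > 1.0
        assert m.phi_score(3.0, cell) == pytest.approx(3.0 / cell.pf)
        assert np.sign(m.phi_score(-1.5, cell)) == -1.0

    @staticmethod
    def _records():
        return [
            PhiRecord("alpha", "C3", 1, 2.0, "HS", 2.0, 2.0),
            PhiRecord("alpha", "C3", 2, 1.0, "AD", -1.0, -1.0),
            PhiRecord("alpha", "C3", 3, 1.5, "intermediate", 0.5, 0.5),
        ]

    def test_zone_mode_hand_example(self):
        i_ad, i_hs = m.compute_indices(self._records(), mode="zone")
        assert i_hs == pytest.approx(100 * 2.0 / 3.5)
        assert i_ad == pytest.approx(100 * 1.0 / 3.5)
        assert i_ad + i_hs < 100.0

    def test_sign_mode_hand_example(self):
        i_ad, i_hs = m.compute_indices(self._records(), mode="sign")
        assert i_hs == pytest.approx(100 * 2.5 / 3.5)
        assert i_ad == pytest.approx(100 * 1.0 / 3.5)
        assert i_ad + i_hs == pytest.approx(100.0)

    def test_all_hs_zone(self):
        records = [PhiRecord("alpha", "C3", s, 2.0, "HS", 2.0, 1.5) for s in range(5)]
        assert m.compute_indices(records) == (0.0, 100.0)

    def test_scale_invariance(self):
        base = self._records()
        scaled = [
            PhiRecord(r.band, r.channel, r.scale, r.x_sut, r.zone, r.phi0, 3.7 * r.phi)
            for r in base
        ]
        assert m.compute_indices(scaled) == pytest.approx(m.compute_indices(base))

    def test_all_skipped_raises(self):
        records = [PhiRecord("alpha", "C3", 1, np.nan, "skipped", 0.0, 0.0)]
        with pytest.raises(ConfigError):
            m.compute_indices(records)


class TestClassify:
    @pytest.mark.parametrize(
        "i_ad, i_hs, expected",
        [(86.5, 10.0, "AD"), (40.0, 55.0, "HS"), (50.0, 50.0, "indeterminate")],
    )
    def test_greater_index_rule(self, i_ad, i_hs, expected):
        assert m.classify(i_ad, i_hs) == expected


class TestScoreSubject:
    def _world(self, rng):
        def tensor(sid, base, fingerprint="fp"):
            return MFETensor(
                values=base + rng.normal(0, 0.02, size=(2, 2, 3)),
                bands=("alpha", "theta"), scales=(1, 2, 3),
                channel_names=("C3", "P4"), subject_id=sid,
                config_fingerprint=fingerprint,
            )

        hs = [tensor(f"h{i}", 2.0) for i in range(8)]
        ad = [tensor(f"a{i}", 1.0) for i in range(8)]
        return m.build_reference(hs, ad)

    def test_subject_at_hs_means_scores_pure_hs(self, rng):
        model = self._world(rng)
        means = np.array(
            [[[model.cell(b, c, s).m_hs for s in model.scales]
              for c in model.channel_names] for b in model.bands]
        )
        tensor = MFETensor(
            values=means, bands=model.bands, scales=model.scales,
            channel_names=model.channel_names, subject_id="sut",
            config_fingerprint="fp",
        )
        phis, report = m.score_subject(tensor, model)
        assert report.i_hs == pytest.approx(100.0)
        assert report.i_ad == 0.0
        assert report.predicted == "HS"
        assert all(r.zone == "HS" and r.phi > 0 for r in phis)

    def test_phi_magnitude_bounded_by_phi0(self, e2e_world):
        model = e2e_world["model"]
        tensor = e2e_world["held_out"]["AD"][0]
        phis, _ = m.score_subject(tensor, model)
        for r in phis:
            if r.zone != "skipped":
                assert abs(r.phi0) <= 3.0 + 1e-12
                assert abs(r.phi) <= abs(r.phi0) + 1e-12
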