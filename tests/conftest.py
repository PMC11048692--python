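import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mfescreen as m
from mfescreen import MFEConfig, PreprocessConfig
from mfescreen.reference import ReferenceCell, interval_overlap, penalty_factor
from mfescreen.synthetic import subject_seed

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240324)


def build_cell(m_hs, u_hs, m_ad, u_ad, band="alpha", channel="P4", scale=1):
    """Reference cell from explicit group statistics (test helper)."""
    orientation = "direct" if m_hs > m_ad else "inverse"
    ol = interval_overlap((m_hs - u_hs, m_hs + u_hs), (m_ad - u_ad, m_ad + u_ad))
    pf = penalty_factor(u_hs, u_ad, ol)
    return ReferenceCell(band, channel, scale, m_hs, u_hs, m_ad, u_ad,
                         orientation, ol, pf)


@pytest.fixture
def cell_factory():
    return build_cell


# ---------------------------------------------------------------------------
# Scaled-down end-to-end world, shared across test modules.
#
# Full-default MFE (15 epochs x 20 scales x 5 bands x 19 channels) for 120+
# subjects costs hours on one CPU, so the end-to-end experiment runs the whole
# pipeline at a reduced but otherwise identical configuration: 5 recorded
# epochs (4 after transient removal), scale factors 1..5, all five bands, all
# 19 channels, 12+12 reference subjects and 10+10 held-out subjects drawn
# from the frozen default presets.
# ---------------------------------------------------------------------------

E2E_SEED = 2024
E2E_PRE = PreprocessConfig(n_epochs=5)
E2E_MFE = MFEConfig(scales=(1, 2, 3, 4, 5))


def _cohort_tensors(group, n, offset=0):
    tensors = []
    for i in range(n):
        rec = m.generate_subject(
            group, seed=subject_seed(E2E_SEED, group, i + offset),
            subject_id=f"{group}{i + offset:03d}",
        )
        tensors.append(m.mfe_from_recording(rec, E2E_PRE, E2E_MFE))
    return tensors


@pytest.fixture(scope="session")
def e2e_world():
    """Reference model from synthetic cohorts plus scored held-out subjects."""
    hs_ref = _cohort_tensors("HS", 12)
    ad_ref = _cohort_tensors("AD", 12)
    model = m.build_reference(hs_ref, ad_ref)
    held_out = {"HS": _cohort_tensors("HS", 10, offset=100),
                "AD": _cohort_tensors("AD", 10, offset=100)}
    reports = {
        g: [m.score_subject(t, model)[1] for t in tensors]
        for g, tensors in held_out.items()
    }
    return {
        "pre": E2E_PRE,
        "mfe": E2E_MFE,
        "hs_ref": hs_ref,
        "ad_ref": ad_ref,
        "model": model,
        "held_out": held_out,
        "reports": reports,
    }
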