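"""Shared fixtures: synthetic reference, healthy panel, and default cohort.

Expensive simulation fixtures are session-scoped and built once; all seeds
are fixed so the whole suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mefi
from mefi.fsd import compute_profile, reference_profile
from mefi.models import extract_features
from mefi.peaks import call_peaks
from mefi.simulate import SimConfig, simulate_cohort

HC_PANEL_SIZE = 30
PANEL_SEED_BASE = 100


@pytest.fixture(scope="session")
def ref():
    return mefi.synthetic_reference()


@pytest.fixture(scope="session")
def annotations():
    return mefi.default_annotations()


@pytest.fixture(scope="session")
def gc_track(ref):
    return mefi.gc_fraction_track(ref)


@pytest.fixture(scope="session")
def hc_panel(ref, gc_track):
    """Healthy-control reference panel of 30 profiles (as in capture data)."""
    cfg = SimConfig(seed=1)
    return [
        compute_profile(
            mefi.simulate_sample(
                cfg, "HC", sample_id=f"panel{i}", ref=ref, seed=PANEL_SEED_BASE + i
            ),
            gc_track,
        )
        for i in range(HC_PANEL_SIZE)
    ]


@pytest.fixture(scope="session")
def ref_profile_z(hc_panel):
    return reference_profile(hc_panel)


@pytest.fixture(scope="session")
def ref_peaks(ref_profile_z):
    return call_peaks(ref_profile_z)


@pytest.fixture(scope="session")
def default_cohort(ref, gc_track, ref_profile_z, ref_peaks):
    """100 MT / 100 HC cohort under the default study conditions, with the
    extracted 1,029-feature matrix and labels."""
    cfg = SimConfig(seed=7)
    samples, truth = simulate_cohort(cfg, {"MT": 100, "HC": 100}, ref=ref)
    rows = {
        fs.sample_id: extract_features(fs, ref, gc_track, ref_profile_z, ref_peaks)
        for fs in samples
    }
    features = pd.DataFrame(rows).T
    truth = truth.set_index("sample_id").loc[features.index]
    return features, truth


@pytest.fixture
def toy_ref():
    """20-bp circular toy genome with all four bases."""
    return mefi.MtReference("ACGTACGTACGTACGTACGT", name="toy")
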