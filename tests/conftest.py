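"""Shared fixtures.

The full-scale tag-recovery runs (two 2000-tag scenes through the whole
detection pipeline) are the most expensive part of the suite, so they are
computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import memquant as mq


@pytest.fixture(scope="session")
def tag_recovery_results():
    """Full pipeline on 2000-tag scenes for both planted distance laws.

    Returns {law: (planted_within100, recovered_histogram)} where the planted
    array holds the exact analytic distances of the planted sub-100-nm tags.
    """
    results = {}
    for law in [(50.0, 17.0), (35.0, 15.0)]:
        scene = mq.gen_tag_scene(
            2000, distance_law=law, touching_pair_fraction=0.05, seed=42
        )
        _table, hist = mq.run_tag_pipeline(
            scene.confidence,
            scene.membrane,
            scene.awi_top_picks,
            scene.awi_bottom_picks,
        )
        d = scene.truth["distance_nm"].to_numpy()
        results[law] = (d[d < 100.0], hist)
    return results


@pytest.fixture(scope="session")
def small_noiseless_tag_scene():
    """A noiseless scene with touching pairs, for exact-detection checks."""
    return mq.gen_tag_scene(
        300,
        distance_law=(50.0, 17.0),
        touching_pair_fraction=0.2,
        noise_sd=0.0,
        footprint_xy_nm=450.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def prem_scene():
    return mq.gen_prem_scene(20, seed=5)


@pytest.fixture
def flat_surfaces():
    """Flat AWI planes at z=0 and z=150 nm over a 1000x1000 nm footprint."""
    g = np.linspace(0.0, 1000.0, 4)
    gx, gy = np.meshgrid(g, g)

    def picks(z):
        return mq.PointSet3D(
            np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
        )

    return mq.SurfacePair.from_picks(picks(150.0), picks(0.0))
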