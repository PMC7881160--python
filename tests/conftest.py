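import numpy as np
import pytest

import ldquant as lq
from ldquant.orientation import default_lookup_table


@pytest.fixture(scope="session")
def coarse_table():
    """5-degree lookup grid (fast; used where grid resolution is not under test)."""
    return default_lookup_table(5.0)


@pytest.fixture(scope="session")
def fine_table():
    """Full 1-degree default lookup grid."""
    return default_lookup_table(1.0)


def make_ring_samples(dist, modality, seed, size=256, radius=60.0, photons=1e4,
                      object_id=None):
    """Render a vesicle ring pair and run the full extraction chain."""
    scene = lq.SceneSpec(
        distribution=dist,
        modality=modality,
        image_size=(size, size),
        center=(size / 2.0, size / 2.0),
        radius=radius,
        photons_per_pixel=photons,
        seed=seed,
    )
    res = lq.render(scene)
    return lq.analyze_ring_pair(
        res.pair,
        geometry=dist.geometry,
        radius_range=(radius - 20, radius + 20),
        min_intensity=photons / 100.0,
        object_id=object_id or f"obj{seed}",
    )


@pytest.fixture(scope="session")
def ring_samples_90_10():
    """1P + 2P θ-samples extracted from rendered rings at truth (90°, 10°)."""
    dist = lq.TiltDistribution.single(90.0, 10.0)
    s1 = make_ring_samples(dist, "1p", seed=11)
    s2 = make_ring_samples(dist, "2p", seed=12)
    return s1, s2
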