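import numpy as np
import pytest

import oratlas as oa


@pytest.fixture(scope="session")
def default_spec():
    return oa.PhantomSpec.default()


@pytest.fixture(scope="session")
def clean_spec(default_spec):
    """Noise-free phantom: exact geometric assertions hold."""
    return default_spec.with_(jitter_sd=0.0)


@pytest.fixture(scope="session")
def bundle_left(default_spec):
    return oa.make_phantom_bundle(default_spec, "left")


@pytest.fixture(scope="session")
def bundle_left_clean(clean_spec):
    return oa.make_phantom_bundle(clean_spec, "left")


@pytest.fixture(scope="session")
def template_labels(default_spec):
    """Label volume built directly from the two-sided template bundle."""
    division_map = {}
    for side in ("left", "right"):
        b = oa.make_phantom_bundle(default_spec, side)
        for division in ("ORu", "ORl"):
            division_map[(side, division)] = b.select(division=division)
    return oa.build_label_volume(division_map, default_spec.grid)


@pytest.fixture(scope="session")
def template_tdi(default_spec):
    bundles = [oa.make_phantom_bundle(default_spec, s) for s in ("left", "right")]
    merged = oa.merge_groups(bundles)
    return oa.compute_tdi(merged, default_spec.grid)


@pytest.fixture
def tiny_grid():
    return oa.VolumeGrid.from_extent((0.0, 0.0, 0.0), (19.0, 19.0, 19.0), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
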