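import numpy as np
import pytest

from camquant import synthetic as syn


@pytest.fixture(scope="session")
def small_tree():
    """Deterministic mid-sized tree (several segments, one-plus junction)."""
    params = syn.TreeParams(
        n_roots=3, branch_probability=0.1, diameter_range=(4.0, 12.0),
        deep_fraction=0.0,
    )
    return syn.generate_vessel_tree((192, 192), params, seed=14)


@pytest.fixture(scope="session")
def small_sample():
    params = syn.TreeParams(
        n_roots=3, branch_probability=0.1, diameter_range=(3.0, 14.0),
        deep_fraction=0.3,
    )
    return syn.make_sample((128, 128), params, seed=3)


def straight_segment_tree(p0, p1, radius, canvas=(160, 160)):
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    seg = syn.Segment(
        points=np.stack([p0, p1]),
        radii=np.array([radius, radius], dtype=float),
    )
    tree = syn.VesselTree(tuple(canvas), [seg])
    tree.validate()
    return tree
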