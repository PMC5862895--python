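import pytest

import cardioflow as cf


@pytest.fixture(scope="session")
def small_tree():
    """A 4-generation tree (8 terminals, 15 airways)."""
    return cf.generate_airway_tree(n_generations=4, seed=11)


@pytest.fixture(scope="session")
def single_bifurcation_tree():
    segs = {
        0: cf.AirwaySegment(0, None, [1, 2], [0, 0, 0], [0, 0, 5.0], 0.5, 0),
        1: cf.AirwaySegment(1, 0, [], [0, 0, 5.0], [2, 0, 8.0], 0.4, 1),
        2: cf.AirwaySegment(2, 0, [], [0, 0, 5.0], [-2, 0, 8.0], 0.3, 1),
    }
    return cf.AirwayTree(segs)


@pytest.fixture(scope="session")
def single_cylinder_geometry():
    """One sealed cylinder (open at the trachea end only): radius 0.5 mm, length 10 mm."""
    seg = cf.AirwaySegment(0, None, [], [0, 0, 0], [0, 0, 10.0], 0.5, 0)
    return cf.simplify_geometry(cf.AirwayTree({0: seg}))
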