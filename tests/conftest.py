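"""Shared fixtures: session-scoped synthetic skulls so the expensive
generation and gape runs happen once."""

import numpy as np
import pytest

from sabrebite.synthetic import SkullParams, make_skull_pair


@pytest.fixture(scope="session")
def skull():
    """Default synthetic skull (planted: 90 deg bone-contact gape, 0.17
    canine arc-centre ratio)."""
    return make_skull_pair(SkullParams(target_tets=3000))


@pytest.fixture(scope="session")
def skull_33():
    """Skull planted with the 0.33 arc-centre ratio."""
    return make_skull_pair(SkullParams(target_tets=2000, canine_arc_ratio=0.33))


@pytest.fixture(scope="session")
def gape_result(skull):
    from sabrebite.gape import find_max_gape

    return find_max_gape(skull, cartilage_mm=1.0, backoff_deg=2.0)
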