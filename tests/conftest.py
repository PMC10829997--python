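import numpy as np
import pytest

from helpers import render_bursts

from meavocab import make_geometry, make_templates


@pytest.fixture(scope="session")
def geometry():
    return make_geometry()


@pytest.fixture(scope="session")
def templates3(geometry):
    return make_templates(3, geometry, seed=2)


@pytest.fixture(scope="session")
def templates9(geometry):
    return make_templates(9, geometry, seed=1)


@pytest.fixture(scope="session")
def template_bursts(templates3, geometry):
    """Labelled rendered bursts: 20 realizations of each of 3 templates."""
    rng = np.random.default_rng(42)
    bursts, labels = [], []
    for t in templates3:
        bursts.extend(render_bursts(t, geometry, rng, 20))
        labels.extend([t.template_id] * 20)
    for i, b in enumerate(bursts):
        b.burst_id = i
    return bursts, np.asarray(labels)
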