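import numpy as np
import pytest

import tilemark as tm


@pytest.fixture(scope="session")
def small_zero_study():
    """Scaled-down study, zero probe noise: every call is exact."""
    design = tm.StudyDesign().scaled(400, 2).with_sigma(0.0)
    return tm.simulate_study(design, seed=5)


@pytest.fixture(scope="session")
def default_noisy_study():
    """The default study conditions (2000 promoters, 4x500 kb regions,
    sigma=0.3, focal amplitude 2.0)."""
    return tm.simulate_study(tm.StudyDesign(), seed=11)


@pytest.fixture()
def tiny_layout():
    """Four promoter tiles and one 100 kb long region."""
    return tm.build_layout(4, 1, 100_000)


def flat_track(layout, value=0.0, cell="cellA", mark="H3K4me3"):
    return tm.ProbeTrack(cell, mark, np.full(layout.n_probes, value), layout)
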