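import logging

import numpy as np
import pytest

from foldpath import (
    FixtureSpec,
    FoldingConfig,
    make_fixture,
    run_folding,
)

logging.getLogger("foldpath").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def hairpin():
    """20-residue helix-hairpin native structure."""
    return make_fixture(FixtureSpec(kind="helix_hairpin", n=20))


@pytest.fixture(scope="session")
def helix10():
    return make_fixture(FixtureSpec(kind="ideal_helix", n=10))


@pytest.fixture(scope="session")
def hairpin_traj(hairpin):
    """Converged folding run of the hairpin from an extended start (defaults)."""
    traj = run_folding(hairpin, FoldingConfig())
    assert traj.converged
    return traj


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
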