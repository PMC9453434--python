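import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

import metacov as mc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atlas():
    return mc.default_atlas()


@pytest.fixture
def dyads_with_bridge():
    """Two positive dyads (1-2, 3-4, weight 1) plus a negative 2-3 bridge."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    w[1, 2] = w[2, 1] = -0.5
    return mc.SignedNetwork(["n1", "n2", "n3", "n4"], w)


@pytest.fixture
def two_cliques():
    """Two disconnected 4-cliques of unit weight."""
    w = np.zeros((8, 8))
    w[:4, :4] = 1.0
    w[4:, 4:] = 1.0
    np.fill_diagonal(w, 0.0)
    return mc.SignedNetwork([f"n{i}" for i in range(8)], w)


@pytest.fixture
def small_suvr_table(atlas):
    """Deterministic 6-subject cohort with two groups and both sexes."""
    rng = np.random.default_rng(42)
    values = 1.5 + 0.1 * rng.standard_normal((6, atlas.n_rois))
    return mc.SuvrTable(
        subject_ids=[f"S{i}" for i in range(6)],
        roi_names=list(atlas.names),
        values=values,
        group=np.array(["CN-to-CN"] * 4 + ["AD"] * 2, dtype=object),
        sex=np.array(["women", "men"] * 3, dtype=object),
    )
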