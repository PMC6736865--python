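import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from melcore.containers import Alignment, TraitMatrix
from melcore import synthdata


@pytest.fixture
def two_group_matrix() -> TraitMatrix:
    """The hand-computable two-species, one-trait collection."""
    return TraitMatrix(
        ["a1", "a2", "a3", "b1", "b2", "b3"],
        ["A", "A", "A", "B", "B", "B"],
        np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]]),
        ["trait"],
    )


@pytest.fixture
def small_alignment() -> Alignment:
    """Five sequences, two haplotypes differing at 2 of 10 clean sites."""
    s = "ACGTACGTAC"
    s2 = "ACGTACGTGG"  # differs at sites 8, 9
    return Alignment(["x1", "x2", "x3", "x4", "x5"], [s, s, s, s2, s2], "toy")


@pytest.fixture
def small_collection():
    """A compact synthetic collection (4 species, 60 accessions) with truth."""
    cfg = synthdata.TraitSimConfig(
        n_species=4,
        accessions_per_species=(30, 15, 10, 5),
        n_traits=5,
        seed=11,
    )
    return synthdata.simulate_collection(seed=11, trait_cfg=cfg)
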