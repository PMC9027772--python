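"""Shared fixtures: the published plot table and small synthetic objects."""

import numpy as np
import pytest
from skbio import TreeNode

from halosoil import CommunitySimSpec, OtuTable, gen_community

# Published survey of ten coastal plots: EC (μS/cm), printed salinity (g/kg)
# for the plots the calibrated conversion reproduces exactly, and the
# printed classification.
PLOT_EC = {1: 491, 2: 2807, 3: 334, 4: 429, 5: 290,
           6: 684, 7: 4374, 8: 244, 9: 2483, 10: 753}
PLOT_SALINITY_2DP = {1: 1.24, 3: 0.84, 5: 0.73, 10: 1.91}
PLOT_GROUPS = {"Non": [3, 5, 8], "Mild": [1, 4, 6, 10], "Severe": [2, 7, 9]}


@pytest.fixture(scope="session")
def toy_table():
    counts = np.array([[6, 2, 0], [2, 2, 0], [0, 0, 5]])
    return OtuTable(counts, ["s1", "s2", "s3"], ["A", "B", "C"],
                    taxonomy={"A": "Bacteria;P1;C1;O1",
                              "B": "Bacteria;P1;C1;O2",
                              "C": "Archaea;P2;C2;O3"})


@pytest.fixture(scope="session")
def caterpillar_tree():
    return TreeNode.read(["((A:1,B:2):0.5,C:1);"])


@pytest.fixture(scope="session")
def small_community():
    """A small gradient community for cross-checks (6 samples/class, 80 OTUs)."""
    spec = CommunitySimSpec(n_samples=6, n_otus=80, seed=11)
    return gen_community(spec)
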