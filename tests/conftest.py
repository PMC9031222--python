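import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitorearr import GeneLabel, GeneOrder, registry
from mitorearr.gene_order import TRNA_GENES

# stand-in gene names for small abstract orders (property tests)
SMALL_NAMES = list(TRNA_GENES[:10])


def perm_order(names, strands=None) -> GeneOrder:
    """Build a linearized order over arbitrary vocabulary names."""
    if strands is None:
        strands = ["+"] * len(names)
    return GeneOrder(tuple((GeneLabel(nm), s) for nm, s in zip(names, strands)),
                     topology="linearized")


@pytest.fixture(scope="session")
def reg():
    return registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220406)
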