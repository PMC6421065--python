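import numpy as np
import pytest

from divclock import clocksim, seqsim, treesim
from divclock.trees import rng_from


@pytest.fixture(scope="session")
def gtr():
    return seqsim.GTRParams.nuclear_rrna()


@pytest.fixture(scope="session")
def bd25_tree():
    """One 25-tip birth-death chronogram at the study's generating conditions."""
    r = treesim.expected_net_diversification(25, 2, 5)
    return treesim.simulate_chronogram(treesim.BDParams(r, 0.5), 25, 5.0, 20_240_101)


@pytest.fixture(scope="session")
def strict_clock_dataset(gtr, bd25_tree):
    """Chronogram + strict-clock phylogram + 5 kb alignment (session-cached)."""
    rates = clocksim.draw_branch_rates(bd25_tree, clocksim.StrictClockParams(), 7)
    phylo = clocksim.apply_rates(bd25_tree, rates)
    aln = seqsim.simulate_alignment(phylo, gtr, 5000, 8)
    return bd25_tree, phylo, aln


def make_rng(*path):
    return rng_from(987_654_321, *path)
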