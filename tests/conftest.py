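import dendropy
import pytest

from structsignal import Alignment, SimulationConfig, StructuredAlignment
from structsignal import simulate_structured_alignment, simulate_tree


@pytest.fixture
def toy_structured() -> StructuredAlignment:
    """Two taxa, forced pairing {0-7, 1-6}, middle columns unpaired."""
    aln = Alignment(["x", "y"], ["ACGUACGU", "ACGTACGT"])
    return StructuredAlignment(aln, "((....))")


@pytest.fixture
def balanced8() -> dendropy.Tree:
    """Balanced ultrametric 8-taxon tree with sizeable internal branches."""
    nwk = (
        "(((a:0.3,b:0.3):0.3,(c:0.3,d:0.3):0.3):0.3,"
        "((e:0.3,f:0.3):0.3,(g:0.3,h:0.3):0.3):0.3);"
    )
    return dendropy.Tree.get(data=nwk, schema="newick")


@pytest.fixture
def small_synthetic():
    """Seeded 8-taxon structured alignment with stems, loops and RAAs."""
    tree = simulate_tree(8, seed=11)
    config = SimulationConfig(
        n_taxa=8, n_stem_pairs=15, n_loop_columns=40, n_raa_blocks=2,
        raa_base_length=12, seed=11,
    )
    saln, truth = simulate_structured_alignment(tree, config, seed=11)
    return saln, truth, tree
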