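import pytest

from hetlink.heteronet import assemble_network
from hetlink.similarity import (
    NODE_LNC,
    NODE_PROT,
    AssociationSets,
    build_alignment_graph,
    build_jaccard_graph,
)
from hetlink.synthetic_data import PlantedNetworkSpec, generate_planted_network


@pytest.fixture(scope="session")
def small_planted():
    """Desk-scale planted fixture: 12 lncRNAs x 8 proteins, 2 blocks."""
    spec = PlantedNetworkSpec(
        n_lnc=12, n_prot=8, k_blocks=2, p_within=0.7, p_between=0.05, sim_noise=0.05, seed=11
    )
    return generate_planted_network(spec)


@pytest.fixture(scope="session")
def small_network(small_planted):
    """Heterogeneous network with interaction + both similarity edge kinds."""
    assoc = AssociationSets.from_interactions(small_planted.interactions)
    lnc_j = build_jaccard_graph(assoc, NODE_LNC, threshold=0.5)
    prot_j = build_jaccard_graph(assoc, NODE_PROT, threshold=0.0)
    return assemble_network(
        small_planted.positive_pairs, lnc_j, prot_j,
        extra_lnc=small_planted.lncRNAs, extra_prot=small_planted.proteins,
    )


@pytest.fixture(scope="session")
def alignment_network(small_planted):
    """Same interactions but alignment-provenance similarity edges (KBNet)."""
    lnc_b = build_alignment_graph(small_planted.lnc_hits, NODE_LNC, 1e-3)
    prot_b = build_alignment_graph(small_planted.prot_hits, NODE_PROT, 1e-2)
    return assemble_network(
        small_planted.positive_pairs, lnc_b, prot_b,
        extra_lnc=small_planted.lncRNAs, extra_prot=small_planted.proteins,
    )
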