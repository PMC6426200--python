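import pytest

from mitopop import (
    default_phylotree,
    make_table1_fixture,
    synthetic_hvri_reference,
)
from mitopop.model import Motif, Variant, VariantKind


@pytest.fixture(scope="session")
def segment():
    return synthetic_hvri_reference()


@pytest.fixture(scope="session")
def tree():
    return default_phylotree()


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


def motif_from_bits(bits, positions):
    """Binary vector -> motif of 'T' substitutions at the given positions."""
    return Motif(
        Variant(positions[i], 0, VariantKind.SUBSTITUTION, "T")
        for i, b in enumerate(bits)
        if b
    )


def network_bits(net, positions):
    """Node set of a network as binary vectors over the given positions."""
    out = set()
    for _, attrs in net.graph.nodes(data=True):
        states = attrs["motif"].site_states()
        out.add(tuple(1 if (p, 0) in states else 0 for p in positions))
    return out
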