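import numpy as np
import pytest

from granulome.model import BlockTable, Placement, SyntenyBlockRecord


def rec(bid, colour, **genomes):
    """Shorthand record builder: name=(scaffold, start, end, strand, genes)."""
    placements = {g: Placement(v[0], v[1], v[2], v[3]) for g, v in genomes.items()}
    genes = {g: v[4] for g, v in genomes.items()}
    return SyntenyBlockRecord(bid, colour, placements, genes)


def table(records, names):
    return BlockTable(list(records), tuple(names))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_threeway():
    """Three genomes, four blocks; block b3 is inverted in genome c."""
    names = ("p", "a", "c")
    recs = [
        rec("b1", 1, p=("s1", 1, 100, "+", 90), a=("x1", 1, 100, "+", 95), c=("y1", 1, 100, "+", 92)),
        rec("b2", 1, p=("s1", 121, 220, "+", 85), a=("x1", 121, 220, "+", 88), c=("y1", 121, 220, "+", 90)),
        rec("b3", 1, p=("s1", 241, 260, "+", 18), a=("x1", 241, 260, "+", 17), c=("y1", 241, 260, "-", 16)),
        rec("b4", 2, p=("s2", 1, 150, "+", 140), a=("x2", 1, 150, "+", 135), c=("y2", 1, 150, "+", 138)),
    ]
    return table(recs, names)
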