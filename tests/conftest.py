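import pytest

import biogeofit as bg


@pytest.fixture
def cherry_ab():
    """Two-terminal clade (X, Y) with X in A and Y in B."""
    return bg.read_dataset("(X,Y);", "taxon\tareas\nX\tA\nY\tB\n")


@pytest.fixture
def h_ab():
    return bg.AreaCladogram.from_newick("(A,B);")


@pytest.fixture
def turner_example():
    """Seven-taxon two-slice data-set mirroring the time-slicing protocol.

    ((A,(B,C)),(D,(E,(F,G)))) with D confined to an older interval than
    the other six terminals.
    """
    newick = "((A,(B,C)),(D,(E,(F,G))));"
    assign = "taxon\tareas\n" + "\n".join(
        f"{t}\t{a}" for t, a in [("A", "X"), ("B", "Y"), ("C", "X"),
                                 ("D", "Z"), ("E", "Y"), ("F", "Z"),
                                 ("G", "Z")])
    strat = "taxon\tfirst\tlast\n" + "\n".join(
        f"{t}\tKim\tKim" if t == "D" else f"{t}\tTth\tTth"
        for t in "ABCDEFG")
    return bg.read_dataset(newick, assign, strat)
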