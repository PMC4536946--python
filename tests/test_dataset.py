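import pytest

import biogeofit as bg
from biogeofit.dataset import DatasetError
from biogeofit.trees import to_newick


def test_read_minimal_dataset():
    ds = bg.read_dataset("((A,B),C);", "taxon\tareas\nA\tEU\nB\tEU\nC\tNA\n")
    assert ds.n_taxa == 3
    assert ds.area_universe == ("EU", "NA")
    assert ds.assignment.areas_of("A") == {"EU"}


@pytest.mark.parametrize("assignment,message", [
    ("taxon\tareas\nA\tEU\nB\tEU\n", "lacks area assignment"),
    ("taxon\tareas\nA\tEU\nB\tEU\nC\tNA\nD\tNA\n", "unknown taxa"),
    ("taxon\tareas\nA\t\nB\tEU\nC\tNA\n", "empty area set"),
])
def test_read_rejects_inconsistent_assignments(assignment, message):
    with pytest.raises(DatasetError, match=message):
        bg.read_dataset("((A,B),C);", assignment)


def test_read_rejects_duplicate_leaves():
    with pytest.raises(DatasetError, match="duplicate leaf"):
        bg.read_dataset("((A,A),C);", "taxon\tareas\nA\tEU\nC\tNA\n")


def test_polytomy_rejected_unless_resolved():
    trich = "(M,Ng,Nl);"
    assign = "taxon\tareas\nM\tNA\nNg\tNA\nNl\tSA\n"
    with pytest.raises(DatasetError, match="polytomy"):
        bg.read_dataset(trich, assign)
    ds = bg.read_dataset(trich, assign, polytomy_policy="listed-resolution",
                         polytomy_resolutions={"M": "(M,(Ng,Nl));"})
    assert to_newick(ds.clades[0]) == "(M,(Ng,Nl));"


def test_listed_resolution_must_cover_the_polytomy():
    tree = bg.read_dataset("(M,(Ng,Nl));",
                           "taxon\tareas\nM\tNA\nNg\tNA\nNl\tSA\n").clades[0]
    # already binary: identity under any policy
    assert bg.resolve_polytomy(tree, "error") is tree
    from biogeofit.trees import parse_newick
    poly = parse_newick("(W,X,Y,Z);")
    with pytest.raises(DatasetError, match="polytomy"):
        bg.resolve_polytomy(poly, "error")
    with pytest.raises(DatasetError, match="inconsistent|unknown leaf"):
        bg.resolve_polytomy(poly, "listed-resolution",
                            {"W": "(W,(X,Q));"})


def test_resolve_polytomy_preserves_leaf_set():
    from biogeofit.trees import parse_newick
    poly = parse_newick("((W,X,Y,Z),V);")
    out = bg.resolve_polytomy(poly, "listed-resolution",
                              {"W": "((W,X),(Y,Z));"})
    assert sorted(out.leaf_labels()) == ["V", "W", "X", "Y", "Z"]
    assert out.is_binary()


def test_roundtrip_read_write_read():
    newick = "((A,B),(C,D));\n(E,F);\n"
    assign = ("taxon\tareas\nA\tEU\nB\tEA;EU\nC\tNA\nD\tNA\n"
              "E\tEA\nF\tEA\n")
    strat = ("taxon\tfirst\tlast\nA\tKim\tTth\nB\tKim\tKim\nC\tBer\tApt\n"
             "D\tApt\tApt\nE\tKim\tTth\nF\tTth\tTth\n")
    ds = bg.read_dataset(newick, assign, strat)
    ds2 = bg.read_dataset(*bg.write_dataset(ds))
    assert [to_newick(c) for c in ds2.clades] == [to_newick(c)
                                                 for c in ds.clades]
    assert ds2.assignment.mapping == ds.assignment.mapping
    assert ds2.strat == ds.strat


def test_singleton_area_pruning_removes_unique_area_taxon():
    # one 'African' terminal in an otherwise two-area data-set
    ds = bg.read_dataset(
        "((Aram,(P1,P2)),(P3,P4));",
        "taxon\tareas\nAram\tAF\nP1\tEU\nP2\tEU\nP3\tNA\nP4\tNA\n")
    pruned, log = bg.prune_singleton_areas(ds)
    assert "Aram" not in pruned.taxa
    assert pruned.n_taxa == 4
    assert "AF" not in pruned.area_universe
    assert any("Aram" in entry for entry in log)


def test_pruning_is_identity_when_every_area_recurs():
    ds = bg.read_dataset(
        "((A,B),(C,D));", "taxon\tareas\nA\tEU\nB\tEU\nC\tNA\nD\tNA\n")
    pruned, log = bg.prune_singleton_areas(ds, min_taxa=3)
    assert pruned.taxa == ds.taxa
    assert len(log) == 0


def test_pruning_reaches_fixpoint_in_one_batch():
    """A terminal is pruned only when every one of its areas is its own
    exclusive singleton, so one batch removal can never create a *new*
    singleton: the iterated rule converges after a single pass, removing
    all singleton-area terminals together."""
    ds = bg.read_dataset(
        "(((W,X),Y),(Z,V));",
        "taxon\tareas\nW\tP\nX\tR\nY\tQ\nZ\tQ\nV\tQ\n")
    pruned, log = bg.prune_singleton_areas(ds)
    assert sorted(pruned.taxa) == ["V", "Y", "Z"]
    assert not any("pass 2" in e and "pruned" in e for e in log)
    counts = pruned.assignment.area_counts(pruned.taxa)
    assert all(c >= 2 for c in counts.values())
    assert pruned.area_universe == ("Q",)
    # idempotence: a second application changes nothing
    again, log2 = bg.prune_singleton_areas(pruned)
    assert again.taxa == pruned.taxa and len(log2) == 0


def test_pruning_below_minimum_errors():
    ds = bg.read_dataset("(A,B);", "taxon\tareas\nA\tEU\nB\tNA\n")
    with pytest.raises(DatasetError, match="too small"):
        bg.prune_singleton_areas(ds)


def test_treefitter_nexus_reader():
    text = """
    #NEXUS
    begin trees;
        tree one = ((T_1,T_2),T_3);
        tree two = (T_4,T_5);
    end;
    begin distribution;
        areas EA EU NA;
        matrix
            T_1 1 0 0
            T_2 0 1 0
            T_3 0 1 1
            T_4 1 0 0
            T_5 0 0 1
        ;
    end;
    """
    ds = bg.read_treefitter_nexus(text)
    assert len(ds.clades) == 2
    assert ds.n_taxa == 5
    assert ds.area_universe == ("EA", "EU", "NA")
    assert ds.assignment.areas_of("T_3") == {"EU", "NA"}
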