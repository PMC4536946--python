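from collections import Counter

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import biogeofit as bg


def _ds(newick, assignment):
    table = "taxon\tareas\n" + "\n".join(f"{t}\t{a}"
                                         for t, a in assignment.items())
    return bg.read_dataset(newick, table)


@pytest.fixture
def six_taxon_ds():
    return _ds("((a,b),(c,(d,e)));\n(f,g);",
               {"a": "A", "b": "B", "c": "C", "d": "A", "e": "B",
                "f": "C", "g": "A"})


def test_two_terminal_permutation_reaches_both_orders(cherry_ab):
    seen = set()
    for seed in range(40):
        rng = np.random.default_rng(seed)
        perm = bg.permute_terminals(cherry_ab, rng)
        seen.add(tuple(sorted((t, min(a)) for t, a in
                              perm.assignment.mapping.items())))
    assert len(seen) == 2  # identity and swap both reachable


def test_pterm_preserves_area_set_multiset(six_taxon_ds):
    original = Counter(six_taxon_ds.assignment.mapping.values())
    rng = np.random.default_rng(7)
    for _ in range(1000):
        perm = bg.permute_terminals(six_taxon_ds, rng)
        assert Counter(perm.assignment.mapping.values()) == original
        assert perm.area_universe == six_taxon_ds.area_universe
        assert [c.canonical() for c in perm.clades] == \
            [c.canonical() for c in six_taxon_ds.clades]


def test_pterm_is_deterministic_under_a_seed(six_taxon_ds):
    a = bg.permute_terminals(six_taxon_ds, np.random.default_rng(3))
    b = bg.permute_terminals(six_taxon_ds, np.random.default_rng(3))
    assert a.assignment.mapping == b.assignment.mapping


def test_ptree_preserves_leaves_and_assignments(six_taxon_ds):
    rng = np.random.default_rng(11)
    for _ in range(200):
        perm = bg.permute_topology(six_taxon_ds, rng)
        assert perm.assignment.mapping == six_taxon_ds.assignment.mapping
        for before, after in zip(six_taxon_ds.clades, perm.clades):
            assert sorted(after.leaf_labels()) == sorted(before.leaf_labels())


def test_ptree_two_leaf_clade_is_fixed(cherry_ab):
    perm = bg.permute_topology(cherry_ab, np.random.default_rng(0))
    assert perm.clades[0].canonical() == cherry_ab.clades[0].canonical()


def test_ptree_uniform_over_three_leaf_topologies():
    ds = _ds("(a,(b,c));", {"a": "A", "b": "B", "c": "A"})
    rng = np.random.default_rng(5)
    counts = Counter(bg.permute_topology(ds, rng).clades[0].canonical()
                     for _ in range(10_000))
    assert len(counts) == 3
    assert scipy.stats.chisquare(list(counts.values())).pvalue > 1e-4


def test_reports_are_identical_under_a_fixed_seed(six_taxon_ds):
    config = bg.PermutationConfig(n_replicates=50, seed=42)
    r1 = bg.cost_significance(six_taxon_ds, bg.SC, config)
    r2 = bg.cost_significance(six_taxon_ds, bg.SC, config)
    assert r1 == r2
    e1 = bg.event_significance(six_taxon_ds, bg.SC, config)
    e2 = bg.event_significance(six_taxon_ds, bg.SC, config)
    assert e1 == e2


def test_perfectly_congruent_data_reach_p_zero():
    """Two large clades endemic to the two areas cost 0 as observed, while
    a permuted replicate reattains 0 only by restoring block purity - so
    the raw proportion reports exactly 0 (the add-one variant cannot)."""
    tips_a = ",".join(f"a{i}" for i in range(10))
    tips_b = ",".join(f"b{i}" for i in range(10))
    newick = f"({tips_a.replace(',', ',(') + ')' * 9});\n" \
             f"({tips_b.replace(',', ',(') + ')' * 9});\n"
    assign = "taxon\tareas\n" + "\n".join(
        [f"a{i}\tA" for i in range(10)] + [f"b{i}\tB" for i in range(10)])
    ds = bg.read_dataset(newick, assign)
    H = bg.AreaCladogram.from_newick("(A,B);")
    config = bg.PermutationConfig(n_replicates=200, seed=1)
    report = bg.cost_significance(ds, bg.SC, config, cladograms=[H])
    assert report.tests[0].observed_cost == 0
    assert report.tests[0].cost_p == 0.0
    corrected = bg.cost_significance(
        ds, bg.SC, bg.PermutationConfig(n_replicates=200, seed=1,
                                        add_one=True), cladograms=[H])
    assert 0 < corrected.tests[0].cost_p <= 1 / 200


def test_event_tails_overlap_at_equality(six_taxon_ds):
    config = bg.PermutationConfig(n_replicates=100, seed=9)
    report = bg.event_significance(six_taxon_ds, bg.SC, config)
    for t in report.tests:
        for name, tail in t.events.items():
            assert 0 <= tail.gtr_p <= 1 and 0 <= tail.ltr_p <= 1
            lo, hi = tail.observed
            if lo == hi:
                # >= and <= tails both include ties, so they overlap
                assert tail.gtr_p + tail.ltr_p >= 1


def test_sympatry_saturated_clades_flag_sympatry():
    """Clades each endemic to a different area: observed sympatry is
    maximal, permuted terminals break the clustering, so the sympatry gtr
    tail collapses toward 0 and dispersal sits in the low tail."""
    ds = _ds("((a,b),(c,d));\n((e,f),(g,h));\n((i,j),(k,l));",
             {t: a for t, a in zip("abcdefghijkl",
                                   "AAAA" "BBBB" "CCCC")})
    config = bg.PermutationConfig(n_replicates=400, seed=3)
    report = bg.event_significance(ds, bg.SC, config, max_cladograms=1)
    assert report.observed_event_ranges["sympatry"] == (9, 9)
    assert report.event_gtr_p("sympatry") < 0.01


def test_fixed_hypothesis_p_values_are_calibrated():
    """Against an a-priori area cladogram the PTP p-value is exchangeable:
    over null data-sets the rejection rate stays near alpha."""
    from biogeofit.trees import random_topology
    rng = np.random.default_rng(17)
    areas = ["A", "B", "C", "D"]
    rejections = 0
    n_datasets = 120
    for s in range(n_datasets):
        tree = random_topology([f"t{i}" for i in range(12)], rng)
        mapping = {t: frozenset([areas[int(rng.integers(4))]])
                   for t in tree.leaf_labels()}
        ds = bg.BiogeoDataset((tree,),
                              bg.AreaAssignment(mapping, tuple(areas)))
        H = bg.AreaCladogram(random_topology(areas, rng))
        report = bg.cost_significance(
            ds, bg.SC, bg.PermutationConfig(n_replicates=100, seed=1000 + s),
            cladograms=[H])
        if report.tests[0].cost_p < 0.05:
            rejections += 1
    assert 0.0 <= rejections / n_datasets <= 0.12


def test_too_few_replicates_warns():
    ds = _ds("((a,b),c);\n(d,(e,f));",
             {"a": "A", "b": "B", "c": "C", "d": "A", "e": "B", "f": "C"})
    config = bg.PermutationConfig(n_replicates=5, seed=0)
    report = bg.cost_significance(ds, bg.SC, config)
    assert any("cannot resolve" in w for w in report.warnings)
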