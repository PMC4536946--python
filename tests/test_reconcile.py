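import random

import pytest
from hypothesis import given, settings, strategies as st

import biogeofit as bg
from biogeofit.dataset import DatasetError
from oracle_utils import oracle_fit, random_instance


def _ds(newick, assignment, universe=None):
    table = "taxon\tareas\n" + "\n".join(f"{t}\t{a}"
                                         for t, a in assignment.items())
    return bg.read_dataset(newick, table, area_universe=universe)


def test_cost_regime_presets():
    assert bg.SC == bg.EventCosts(0, 0, 1, 2)
    assert bg.MC == bg.EventCosts(-1, 0, 0, 0)
    assert bg.EventCosts.from_name("sc") is bg.SC
    with pytest.raises(ValueError):
        bg.EventCosts.from_name("XX")


def test_forced_vicariance(cherry_ab, h_ab):
    res = bg.fit(cherry_ab, h_ab, bg.SC)
    assert res.min_cost == 0
    assert res.n_optimal == 1
    assert res.event_ranges == ((1, 1), (0, 0), (0, 0), (0, 0))


def test_duplication_only_cherry(h_ab):
    ds = _ds("(X,Y);", {"X": "A", "Y": "A"}, universe=["A", "B"])
    res = bg.fit(ds, h_ab, bg.SC)
    assert res.min_cost == 0
    assert res.event_ranges == ((0, 0), (1, 1), (0, 0), (0, 0))
    assert bg.fit(ds, h_ab, bg.MC).min_cost == 0


def test_duplication_beats_dispersal_on_three_leaf_clade(h_ab):
    """(X,(Y,Z)) with X,Y in A and Z in B: the duplication-at-root history
    (one extinction) beats vicariance-at-root plus dispersal (cost 2)."""
    ds = _ds("(X,(Y,Z));", {"X": "A", "Y": "A", "Z": "B"})
    res = bg.fit(ds, h_ab, bg.SC)
    assert res.min_cost == 1
    assert res.event_ranges == ((1, 1), (1, 1), (1, 1), (0, 0))


def test_universe_mismatch_is_an_error(cherry_ab):
    H = bg.AreaCladogram.from_newick("((A,B),C);")
    with pytest.raises(DatasetError, match="universe"):
        bg.fit(cherry_ab, H, bg.SC)


def test_singleton_clades_fit_with_zero_events(h_ab):
    ds = bg.read_dataset("(X);\n(Y);", "taxon\tareas\nX\tA\nY\tB\n")
    res = bg.fit(ds, h_ab, bg.SC)
    assert res.min_cost == 0
    assert res.event_ranges == ((0, 0),) * 4
    assert res.warnings


@pytest.mark.parametrize("policy,expected_cost", [
    ("cheapest-single", 0.0),   # optimizer picks the congruent area
    ("all-dispersal", 2.0),     # the extra listed area costs one dispersal
    ("all-free", 0.0),
])
def test_widespread_terminal_policies(h_ab, policy, expected_cost):
    ds = _ds("(X,Y);", {"X": "A;B", "Y": "B"})
    res = bg.fit(ds, h_ab, bg.SC, widespread_policy=policy)
    assert res.min_cost == expected_cost


def test_enumerate_optimal_single_history(cherry_ab, h_ab):
    recs, truncated = bg.enumerate_optimal(cherry_ab, h_ab, bg.SC)
    assert not truncated
    assert len(recs) == 1
    assert recs[0].counts == (1, 0, 0, 0)
    assert recs[0].total_cost == 0


def test_enumerate_optimal_duplication_at_leaf(h_ab):
    """Root association at the H-root or at the wrong leaf is costlier, so
    the duplication sits at leaf A and the optimum is unique."""
    ds = _ds("(X,Y);", {"X": "A", "Y": "A"}, universe=["A", "B"])
    recs, _ = bg.enumerate_optimal(ds, h_ab, bg.SC)
    assert len(recs) == 1
    assert recs[0].counts == (0, 1, 0, 0)
    root_entry = [e for e in recs[0].embedding if e[0][1] == ("X", "Y")]
    assert root_entry[0][1] == ("A",)  # the duplication sits at leaf A


def test_enumerate_optimal_mirror_pair():
    """(W,(X,(Y,Z))) with W,X in A, Y in B, Z in C on H=((A,B),C) has
    exactly two mirror-optimal embeddings with identical event counts
    (verified by exhaustive enumeration)."""
    ds = _ds("(W,(X,(Y,Z)));", {"W": "A", "X": "A", "Y": "B", "Z": "C"})
    H = bg.AreaCladogram.from_newick("((A,B),C);")
    res = bg.fit(ds, H, bg.SC)
    recs, truncated = bg.enumerate_optimal(ds, H, bg.SC)
    assert not truncated
    assert res.n_optimal == len(recs) == 2
    assert res.min_cost == 3
    assert recs[0].counts == recs[1].counts == (1, 1, 1, 1)
    assert recs[0].embedding != recs[1].embedding


def test_enumerate_cap_truncates_but_flags():
    ds = _ds("((W,X),(Y,Z));", {"W": "A", "X": "A", "Y": "A", "Z": "A"},
             universe=["A", "B"])
    H = bg.AreaCladogram.from_newick("(A,B);")
    full, full_trunc = bg.enumerate_optimal(ds, H, bg.MC, cap=1000)
    assert not full_trunc and len(full) > 1  # every embedding ties under MC
    capped, truncated = bg.enumerate_optimal(ds, H, bg.MC, cap=1)
    assert len(capped) == 1 and truncated


def test_enumeration_agrees_with_fit_counts():
    rnd = random.Random(5)
    for _ in range(25):
        ds, H, costs = random_instance(rnd)
        res = bg.fit(ds, H, costs)
        recs, truncated = bg.enumerate_optimal(ds, H, costs, cap=5000)
        assert not truncated
        assert len(recs) == res.n_optimal
        for rec in recs:
            assert abs(rec.total_cost - res.min_cost) < 1e-9
            for k in range(4):
                assert res.event_ranges[k][0] <= rec.counts[k] \
                    <= res.event_ranges[k][1]


def test_dp_matches_brute_force_on_random_instances():
    """DP minimum cost, optimum count and event ranges all agree with
    exhaustive enumeration over every embedding (150 random instances,
    <=5 leaves per clade, <=3 areas, random integer costs)."""
    rnd = random.Random(11)
    for _ in range(150):
        ds, H, costs = random_instance(rnd)
        res = bg.fit(ds, H, costs)
        cost, count, lo, hi = oracle_fit(ds, H, costs)
        assert abs(res.min_cost - cost) < 1e-9
        assert res.n_optimal == count
        assert tuple(r[0] for r in res.event_ranges) == lo
        assert tuple(r[1] for r in res.event_ranges) == hi


@given(st.integers(0, 10_000), st.sampled_from(range(4)),
       st.integers(1, 3))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_raising_one_event_cost_never_lowers_min_cost(seed, which, bump):
    rnd = random.Random(seed)
    ds, H, costs = random_instance(rnd)
    base = bg.fit(ds, H, costs).min_cost
    kwargs = dict(vicariance=costs.vicariance, sympatry=costs.sympatry,
                  extinction=costs.extinction, dispersal=costs.dispersal)
    key = ["vicariance", "sympatry", "extinction", "dispersal"][which]
    kwargs[key] = kwargs[key] + bump
    assert bg.fit(ds, H, bg.EventCosts(**kwargs)).min_cost >= base - 1e-9


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_divergences_classified_exactly_once(seed):
    """For single-area data-sets every internal vertex carries exactly one
    of vicariance/sympatry/dispersal, so their counts sum to
    (terminals - clades) in every optimal reconciliation."""
    rnd = random.Random(seed)
    ds, H, costs = random_instance(rnd)
    res = bg.fit(ds, H, costs)
    n_div = ds.n_taxa - len(ds.clades)
    lo = sum(res.event_ranges[k][0] for k in (0, 1, 3))
    hi = sum(res.event_ranges[k][1] for k in (0, 1, 3))
    recs, truncated = bg.enumerate_optimal(ds, H, costs, cap=5000)
    assert lo <= n_div <= hi
    for rec in recs:
        assert rec.counts[0] + rec.counts[1] + rec.counts[3] == n_div


def test_mc_cost_bounded_by_internal_vertices():
    rnd = random.Random(23)
    for _ in range(40):
        ds, H, _ = random_instance(rnd)
        res = bg.fit(ds, H, bg.MC)
        n_internal = ds.n_taxa - len(ds.clades)
        assert -n_internal - 1e-9 <= res.min_cost <= 1e-9
        # MC minimum equals minus the maximum achievable vicariance count
        assert abs(res.min_cost + res.range_of("vicariance")[1]) < 1e-9
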