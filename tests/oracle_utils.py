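"""Independent brute-force oracle for the reconciliation model.

Deliberately implemented without the package's dynamic programme or its
bitmask indexing: embeddings are enumerated exhaustively as full mappings
from taxon vertices to area-cladogram vertices, events are classified by
explicit parent-pointer walks, and optima are found by scanning.  Only
usable for tiny instances; that is the point.
"""

import itertools
import random

from biogeofit import AreaAssignment, BiogeoDataset
from biogeofit.trees import Node


def walk_down(anc, node):
    """Number of edges from ``anc`` down to ``node``; None if not below."""
    steps = 0
    v = node
    while v is not None:
        if v is anc:
            return steps
        v = v.parent
        steps += 1
    return None


def classify(h, x1, x2, costs):
    """(cost, event vector) of the divergence at m(u)=h with children at
    x1, x2; None if the placement is impossible."""
    d1, d2 = walk_down(h, x1), walk_down(h, x2)
    if d1 is not None and d2 is not None:
        if h.children:
            left, right = h.children
            a1l, a1r = walk_down(left, x1), walk_down(right, x1)
            a2l, a2r = walk_down(left, x2), walk_down(right, x2)
            if a1l is not None and a2r is not None:
                ext = a1l + a2r
                return (costs.vicariance + costs.extinction * ext,
                        (1, 0, ext, 0))
            if a1r is not None and a2l is not None:
                ext = a1r + a2l
                return (costs.vicariance + costs.extinction * ext,
                        (1, 0, ext, 0))
        ext = d1 + d2
        return costs.sympatry + costs.extinction * ext, (0, 1, ext, 0)
    if (d1 is None) != (d2 is None):
        ext = d1 if d1 is not None else d2
        return costs.dispersal + costs.extinction * ext, (0, 0, ext, 1)
    return None


def oracle_fit(ds, H, costs):
    """(min cost, n optimal embeddings, event minima, event maxima)."""
    hnodes = list(H.root.postorder())
    leaf_by_area = {v.label: v for v in hnodes if not v.children}
    per_clade = []
    for clade in ds.clades:
        vertices = list(clade.postorder())
        choices = []
        for v in vertices:
            if v.is_leaf:
                choices.append([leaf_by_area[a] for a in
                                sorted(ds.assignment.areas_of(v.label))])
            else:
                choices.append(hnodes)
        best = float("inf")
        count = 0
        evmin = evmax = None
        for combo in itertools.product(*choices):
            placed = dict(zip((id(v) for v in vertices), combo))
            cost, events, feasible = 0.0, [0, 0, 0, 0], True
            for v in vertices:
                if v.is_leaf:
                    continue
                res = classify(placed[id(v)], placed[id(v.children[0])],
                               placed[id(v.children[1])], costs)
                if res is None:
                    feasible = False
                    break
                cost += res[0]
                for k in range(4):
                    events[k] += res[1][k]
            if not feasible:
                continue
            if cost < best - 1e-9:
                best, count = cost, 1
                evmin, evmax = list(events), list(events)
            elif abs(cost - best) <= 1e-9:
                count += 1
                evmin = [min(a, b) for a, b in zip(evmin, events)]
                evmax = [max(a, b) for a, b in zip(evmax, events)]
        per_clade.append((best, count, evmin, evmax))
    total_cost = sum(t[0] for t in per_clade)
    total_count = 1
    for t in per_clade:
        total_count *= t[1]
    lo = tuple(sum(t[2][k] for t in per_clade) for k in range(4))
    hi = tuple(sum(t[3][k] for t in per_clade) for k in range(4))
    return total_cost, total_count, lo, hi


def random_join_tree(labels, rnd: random.Random) -> Node:
    """Random rooted binary tree by iterative pairwise joining."""
    nodes = [Node(lab) for lab in labels]
    while len(nodes) > 1:
        i, j = rnd.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(Node(None, [a, b]))
    return nodes[0]


def random_instance(rnd: random.Random):
    """A random tiny data-set, area cladogram and integer cost regime."""
    n_areas = rnd.randint(2, 3)
    areas = ["A", "B", "C"][:n_areas]
    n_clades = rnd.randint(1, 2)
    names = iter("abcdefghij")
    clades = []
    for ci in range(n_clades):
        size = rnd.randint(1, 5) if n_clades > 1 else rnd.randint(2, 5)
        clades.append(random_join_tree([next(names) for _ in range(size)],
                                       rnd))
    mapping = {}
    for clade in clades:
        for leaf in clade.leaf_labels():
            mapping[leaf] = frozenset([rnd.choice(areas)])
    ds = BiogeoDataset(tuple(clades), AreaAssignment(mapping, tuple(areas)))
    from biogeofit import AreaCladogram, EventCosts
    H = AreaCladogram(random_join_tree(areas, rnd))
    costs = EventCosts(rnd.choice([0, 0, 1, 2]), rnd.choice([0, 0, 1]),
                       rnd.choice([0, 1, 1, 2]), rnd.choice([0, 1, 2, 3]))
    return ds, H, costs
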