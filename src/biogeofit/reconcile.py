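"""Minimum-cost reconciliation of taxon cladograms with an area cladogram.

The model is the classical event-based "tree fitting" of historical
biogeography.  Every vertex ``u`` of a taxon cladogram is associated with a
vertex ``m(u)`` of the area cladogram ``H``.  At an internal taxon vertex
``u`` with children ``u1, u2`` and association ``h = m(u)`` the divergence
is classified by where the children's associations fall:

* **vicariance** (codivergence, cost ``v``): ``m(u1)`` and ``m(u2)`` lie in
  the subtrees of the two *distinct* children of ``h`` — the taxon
  divergence tracks the area divergence;
* **sympatry** (duplication, cost ``s``): both children stay within the
  subtree of ``h`` without forming the vicariant split;
* **dispersal** (switch, cost ``d``): exactly one child jumps to a vertex
  outside the subtree of ``h`` while the other stays within.

In every case, each area-cladogram edge traversed *downward* between an
event's prescribed starting vertex (the two children of ``h`` for
vicariance, ``h`` itself for the staying lineages of sympatry and
dispersal) and the child's realized association contributes one
**extinction** (sorting) event of cost ``e``.  A single-area terminal must
be associated with its area's leaf in ``H``; multi-area (widespread)
terminals follow a selectable policy.  In multi-clade data-sets each
clade's root may be associated with any vertex of ``H`` at no cost and the
clade costs sum.

The minimisation is a dynamic programme over (taxon vertex x area vertex);
negative event costs (e.g. the maximum-codivergence regime) are safe
because event counts are bounded by tree size.  Alongside the minimum cost
the DP propagates the number of distinct optimal embeddings and exact
per-event (min, max) ranges over the optimal set via min-plus/max-plus
sweeps, without materialising embeddings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

from .dataset import BiogeoDataset, DatasetError
from .trees import Node, parse_newick, to_newick

__all__ = [
    "EventCosts",
    "SC",
    "MC",
    "COST_REGIMES",
    "AreaCladogram",
    "Reconciliation",
    "FitResult",
    "fit",
    "enumerate_optimal",
    "WIDESPREAD_POLICIES",
]

_EPS = 1e-9
_INF = float("inf")

#: event vector index order used throughout: (vic, sym, ext, dis)
VIC, SYM, EXT, DIS = 0, 1, 2, 3
EVENT_NAMES = ("vicariance", "sympatry", "extinction", "dispersal")

WIDESPREAD_POLICIES = ("cheapest-single", "all-dispersal", "all-free")


@dataclass(frozen=True)
class EventCosts:
    """Per-event costs of the four biogeographic event types."""

    vicariance: float
    sympatry: float
    extinction: float
    dispersal: float

    def __post_init__(self):
        for name in EVENT_NAMES:
            val = getattr(self, name)
            if val != val or val in (_INF, -_INF):
                raise ValueError(f"{name} cost must be finite")

    def total(self, counts: tuple[int, int, int, int]) -> float:
        return (self.vicariance * counts[VIC] + self.sympatry * counts[SYM]
                + self.extinction * counts[EXT] + self.dispersal * counts[DIS])

    @classmethod
    def from_name(cls, name: str) -> "EventCosts":
        try:
            return COST_REGIMES[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown cost regime {name!r}; known: "
                f"{sorted(COST_REGIMES)}") from None


#: Standard costs: vicariance and sympatry free, extinction 1, dispersal 2.
SC = EventCosts(vicariance=0.0, sympatry=0.0, extinction=1.0, dispersal=2.0)
#: Maximum codivergence: vicariance rewarded at -1, everything else free.
MC = EventCosts(vicariance=-1.0, sympatry=0.0, extinction=0.0, dispersal=0.0)

COST_REGIMES = {"SC": SC, "MC": MC}


class AreaCladogram:
    """A rooted binary tree whose leaves are distinct area codes."""

    def __init__(self, root: Node):
        if not root.is_binary():
            raise ValueError("area cladogram must be binary")
        labels = root.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("area cladogram leaves must be distinct areas")
        self.root = root
        self._index: Optional[_HIndex] = None

    @classmethod
    def from_newick(cls, text: str) -> "AreaCladogram":
        return cls(parse_newick(text))

    @property
    def areas(self) -> frozenset[str]:
        return frozenset(self.root.leaf_labels())

    @property
    def newick(self) -> str:
        return to_newick(self.root)

    def canonical(self) -> str:
        return self.root.canonical()

    def index(self) -> "_HIndex":
        if self._index is None:
            self._index = _HIndex(self.root)
        return self._index

    def __eq__(self, other):
        return (isinstance(other, AreaCladogram)
                and self.canonical() == other.canonical())

    def __hash__(self):
        return hash(self.canonical())

    def __repr__(self):
        return f"AreaCladogram({self.newick!r})"


class _HIndex:
    """Array view of an area cladogram for the reconciliation DP.

    Vertices are numbered in postorder.  ``mask[i]`` is the bitmask of the
    subtree of vertex ``i`` (used for O(1) descendant tests), ``depth[i]``
    the edge distance from the root.
    """

    __slots__ = ("nodes", "n", "left", "right", "parent", "depth",
                 "mask", "leaf_of", "postorder", "root_id", "leaf_sets")

    def __init__(self, root: Node):
        self.nodes: list[Node] = list(root.postorder())
        self.n = len(self.nodes)
        ids = {id(v): i for i, v in enumerate(self.nodes)}
        self.left = [-1] * self.n
        self.right = [-1] * self.n
        self.parent = [-1] * self.n
        self.mask = [0] * self.n
        self.leaf_of: dict[str, int] = {}
        self.leaf_sets: list[tuple[str, ...]] = [()] * self.n
        for i, v in enumerate(self.nodes):
            if v.is_leaf:
                self.mask[i] = 1 << i
                self.leaf_of[v.label] = i
                self.leaf_sets[i] = (v.label,)
            else:
                li, ri = ids[id(v.children[0])], ids[id(v.children[1])]
                self.left[i], self.right[i] = li, ri
                self.parent[li] = self.parent[ri] = i
                self.mask[i] = self.mask[li] | self.mask[ri] | (1 << i)
                self.leaf_sets[i] = tuple(sorted(
                    self.leaf_sets[li] + self.leaf_sets[ri]))
        self.root_id = self.n - 1
        self.depth = [0] * self.n
        for i in range(self.n - 2, -1, -1):
            self.depth[i] = self.depth[self.parent[i]] + 1
        self.postorder = list(range(self.n))

    def in_subtree(self, h: int, x: int) -> bool:
        return bool(self.mask[h] & (1 << x))

    def dist_down(self, h: int, x: int) -> int:
        return self.depth[x] - self.depth[h]

    def mrca(self, leaf_ids: Iterable[int]) -> int:
        target = 0
        for i in leaf_ids:
            target |= 1 << i
        for h in range(self.n):
            if self.mask[h] & target == target:
                return h
        raise ValueError("mrca not found")  # unreachable on a rooted tree


@dataclass(frozen=True)
class Reconciliation:
    """One optimal embedding: taxon subtree -> area-cladogram vertex.

    ``embedding`` maps (clade index, sorted taxon-subtree leaf tuple) to the
    sorted leaf tuple of the associated area-cladogram vertex.
    """

    embedding: tuple
    counts: tuple[int, int, int, int]
    total_cost: float

    def count(self, event: str) -> int:
        return self.counts[EVENT_NAMES.index(event)]


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting a data-set to one fixed area cladogram."""

    area_cladogram: AreaCladogram
    min_cost: float
    n_optimal: int
    event_ranges: tuple[tuple[int, int], ...]  # (min, max) per event
    costs: EventCosts
    widespread_policy: str
    warnings: tuple[str, ...] = ()

    def range_of(self, event: str) -> tuple[int, int]:
        return self.event_ranges[EVENT_NAMES.index(event)]

    def report_row(self) -> str:
        """Tab-separated row: newick, cost, n optimal, per-event min-max."""
        cols = [self.area_cladogram.newick, f"{self.min_cost:g}",
                str(self.n_optimal)]
        for lo, hi in self.event_ranges:
            cols.append(str(lo) if lo == hi else f"{lo}-{hi}")
        return "\t".join(cols)


# ---------------------------------------------------------------------------
# Leaf association sets under the widespread policies
# ---------------------------------------------------------------------------

def _leaf_positions(areas: frozenset[str], H: _HIndex, policy: str,
                    ) -> list[tuple[int, float, tuple[int, int, int, int]]]:
    """Allowed H-vertices for a terminal: (vertex, extra cost, extra events).

    Extra costs are expressed in *event units*: the caller scales dispersal
    units by the dispersal cost.
    """
    leaf_ids = sorted(H.leaf_of[a] for a in areas)
    if len(leaf_ids) == 1 or policy == "cheapest-single":
        return [(i, 0.0, (0, 0, 0, 0)) for i in leaf_ids]
    if policy == "all-dispersal":
        extra = len(leaf_ids) - 1
        return [(i, float(extra), (0, 0, 0, extra)) for i in leaf_ids]
    if policy == "all-free":
        # the widespread range is treated as (part of) an ancestral
        # composite area: any vertex on the paths from the MRCA of the
        # listed areas down to those leaves, at no cost
        mrca = H.mrca(leaf_ids)
        allowed = set()
        for i in leaf_ids:
            v = i
            while True:
                allowed.add(v)
                if v == mrca:
                    break
                v = H.parent[v]
        return [(i, 0.0, (0, 0, 0, 0)) for i in sorted(allowed)]
    raise ValueError(f"unknown widespread policy {policy!r}")


# ---------------------------------------------------------------------------
# Cost-only DP (fast path, used heavily by the permutation tests)
# ---------------------------------------------------------------------------

def _clade_min_cost(postorder: list[Node],
                    leaf_areas: dict[str, frozenset[str]],
                    H: _HIndex, costs: EventCosts, policy: str) -> float:
    v, s, e, d = (costs.vicariance, costs.sympatry,
                  costs.extinction, costs.dispersal)
    n = H.n
    left, right = H.left, H.right
    table: dict[int, list[float]] = {}
    for u in postorder:
        if u.is_leaf:
            row = [_INF] * n
            for h, extra_d, _ in _leaf_positions(leaf_areas[u.label], H,
                                                 policy):
                row[h] = min(row[h], extra_d * d)
            table[id(u)] = row
            continue
        c1 = table.pop(id(u.children[0]))
        c2 = table.pop(id(u.children[1]))
        in1, sub1 = _in_sub_cost(c1, H, e)
        in2, sub2 = _in_sub_cost(c2, H, e)
        out1 = _out_cost(c1, sub1, H)
        out2 = _out_cost(c2, sub2, H)
        row = [_INF] * n
        for h in range(n):
            l, r = left[h], right[h]
            if l < 0:  # leaf of H
                best = s + c1[h] + c2[h]
                cand = d + c1[h] + out2[h]
                if cand < best:
                    best = cand
                cand = d + out1[h] + c2[h]
                if cand < best:
                    best = cand
            else:
                best = v + min(in1[l] + in2[r], in1[r] + in2[l])
                strict1 = e + min(in1[l], in1[r])
                strict2 = e + min(in2[l], in2[r])
                cand = s + min(
                    c1[h] + c2[h],
                    c1[h] + strict2,
                    strict1 + c2[h],
                    2 * e + in1[l] + in2[l],
                    2 * e + in1[r] + in2[r],
                )
                if cand < best:
                    best = cand
                cand = d + min(in1[h] + out2[h], out1[h] + in2[h])
                if cand < best:
                    best = cand
            row[h] = best
        table[id(u)] = row
    root_row = table[id(postorder[-1])]
    return min(root_row)


def _in_sub_cost(c: list[float], H: _HIndex, e: float):
    n = H.n
    in_ = [0.0] * n
    sub = [0.0] * n
    for h in range(n):
        l = H.left[h]
        if l < 0:
            in_[h] = c[h]
            sub[h] = c[h]
        else:
            r = H.right[h]
            in_[h] = min(c[h], e + min(in_[l], in_[r]))
            sub[h] = min(c[h], sub[l], sub[r])
    return in_, sub


def _out_cost(c: list[float], sub: list[float], H: _HIndex):
    out = [_INF] * H.n
    for h in range(H.n - 1, -1, -1):
        l = H.left[h]
        if l >= 0:
            r = H.right[h]
            base = min(out[h], c[h])
            out[l] = min(base, sub[r])
            out[r] = min(base, sub[l])
    return out


# ---------------------------------------------------------------------------
# Full DP: (cost, count of optimal embeddings, per-event min/max ranges)
# ---------------------------------------------------------------------------

_ZEROV = (0, 0, 0, 0)
_INFVAL = (_INF, 0, _ZEROV, _ZEROV)


def _vadd(a, b):
    if a[0] == _INF or b[0] == _INF:
        return _INFVAL
    return (a[0] + b[0], a[1] * b[1],
            tuple(x + y for x, y in zip(a[2], b[2])),
            tuple(x + y for x, y in zip(a[3], b[3])))


def _vshift(a, dcost, devents):
    if a[0] == _INF:
        return _INFVAL
    return (a[0] + dcost, a[1],
            tuple(x + y for x, y in zip(a[2], devents)),
            tuple(x + y for x, y in zip(a[3], devents)))


def _vbest(values):
    best = _INFVAL
    for val in values:
        if val[0] == _INF:
            continue
        if best[0] == _INF or val[0] < best[0] - _EPS:
            best = val
        elif abs(val[0] - best[0]) <= _EPS:
            best = (best[0], best[1] + val[1],
                    tuple(min(x, y) for x, y in zip(best[2], val[2])),
                    tuple(max(x, y) for x, y in zip(best[3], val[3])))
    return best


def _event_value(dcost, devents):
    return (dcost, 1, devents, devents)


def _clade_full(postorder: list[Node],
                leaf_areas: dict[str, frozenset[str]],
                H: _HIndex, costs: EventCosts, policy: str,
                keep_tables: bool = False):
    v, s, e, d = (costs.vicariance, costs.sympatry,
                  costs.extinction, costs.dispersal)
    n = H.n
    vic1 = (1, 0, 0, 0)
    sym1 = (0, 1, 0, 0)
    ext1 = (0, 0, 1, 0)
    dis1 = (0, 0, 0, 1)
    tables: dict[int, list] = {}
    for u in postorder:
        if u.is_leaf:
            row = [_INFVAL] * n
            for h, extra_d, ev in _leaf_positions(leaf_areas[u.label], H,
                                                  policy):
                row[h] = _vbest([row[h], _event_value(extra_d * d, ev)])
            tables[id(u)] = row
            continue
        c1 = tables[id(u.children[0])]
        c2 = tables[id(u.children[1])]
        in1 = _in_sub_full(c1, H, e, ext1)
        in2 = _in_sub_full(c2, H, e, ext1)
        sub1 = _sub_full(c1, H)
        sub2 = _sub_full(c2, H)
        out1 = _out_full(c1, sub1, H)
        out2 = _out_full(c2, sub2, H)
        row = [_INFVAL] * n
        for h in range(n):
            l, r = H.left[h], H.right[h]
            opts = []
            if l < 0:
                opts.append(_vshift(_vadd(c1[h], c2[h]), s, sym1))
                opts.append(_vshift(_vadd(c1[h], out2[h]), d, dis1))
                opts.append(_vshift(_vadd(out1[h], c2[h]), d, dis1))
            else:
                opts.append(_vshift(_vadd(in1[l], in2[r]), v, vic1))
                opts.append(_vshift(_vadd(in1[r], in2[l]), v, vic1))
                strict1 = _vbest([_vshift(in1[l], e, ext1),
                                  _vshift(in1[r], e, ext1)])
                strict2 = _vbest([_vshift(in2[l], e, ext1),
                                  _vshift(in2[r], e, ext1)])
                opts.append(_vshift(_vadd(c1[h], c2[h]), s, sym1))
                opts.append(_vshift(_vadd(c1[h], strict2), s, sym1))
                opts.append(_vshift(_vadd(strict1, c2[h]), s, sym1))
                opts.append(_vshift(_vadd(_vshift(in1[l], e, ext1),
                                          _vshift(in2[l], e, ext1)), s, sym1))
                opts.append(_vshift(_vadd(_vshift(in1[r], e, ext1),
                                          _vshift(in2[r], e, ext1)), s, sym1))
                opts.append(_vshift(_vadd(in1[h], out2[h]), d, dis1))
                opts.append(_vshift(_vadd(out1[h], in2[h]), d, dis1))
            row[h] = _vbest(opts)
        if not keep_tables:
            tables.pop(id(u.children[0]))
            tables.pop(id(u.children[1]))
        tables[id(u)] = row
    root_row = tables[id(postorder[-1])]
    clade_value = _vbest(root_row)
    return (clade_value, tables) if keep_tables else (clade_value, None)


def _in_sub_full(c, H, e, ext1):
    in_ = [_INFVAL] * H.n
    for h in range(H.n):
        l = H.left[h]
        if l < 0:
            in_[h] = c[h]
        else:
            r = H.right[h]
            in_[h] = _vbest([c[h], _vshift(in_[l], e, ext1),
                             _vshift(in_[r], e, ext1)])
    return in_


def _sub_full(c, H):
    sub = [_INFVAL] * H.n
    for h in range(H.n):
        l = H.left[h]
        if l < 0:
            sub[h] = c[h]
        else:
            sub[h] = _vbest([c[h], sub[H.left[h]], sub[H.right[h]]])
    return sub


def _out_full(c, sub, H):
    out = [_INFVAL] * H.n
    for h in range(H.n - 1, -1, -1):
        l = H.left[h]
        if l >= 0:
            r = H.right[h]
            base = _vbest([out[h], c[h]])
            out[l] = _vbest([base, sub[r]])
            out[r] = _vbest([base, sub[l]])
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _check_universe(ds: BiogeoDataset, H: AreaCladogram) -> None:
    if H.areas != frozenset(ds.area_universe):
        raise DatasetError(
            f"area cladogram leaves {sorted(H.areas)} do not match the "
            f"data-set universe {sorted(ds.area_universe)}")


def fit(ds: BiogeoDataset, H: AreaCladogram, costs: EventCosts,
        widespread_policy: str = "cheapest-single") -> FitResult:
    """Fit a data-set to one fixed area cladogram.

    Returns the global minimum total cost over all embeddings permitted by
    the event model, the number of distinct optimal embeddings and exact
    per-event (min, max) count ranges over that optimal set.
    """
    _check_universe(ds, H)
    if widespread_policy not in WIDESPREAD_POLICIES:
        raise ValueError(f"unknown widespread policy {widespread_policy!r}")
    hidx = H.index()
    leaf_areas = ds.assignment.mapping
    warnings = []
    if all(len(c.leaves()) < 2 for c in ds.clades):
        warnings.append("no clade has two or more terminals; "
                        "no events to score")
    total = (0.0, 1, _ZEROV, _ZEROV)
    for clade in ds.clades:
        post = list(clade.postorder())
        value, _ = _clade_full(post, leaf_areas, hidx, costs,
                               widespread_policy)
        if value[0] == _INF:
            raise DatasetError("no feasible embedding for clade "
                               f"{to_newick(clade)}")
        total = _vadd(total, value)
    ranges = tuple((lo, hi) for lo, hi in zip(total[2], total[3]))
    return FitResult(H, total[0], total[1], ranges, costs,
                     widespread_policy, tuple(warnings))


def fit_cost(ds: BiogeoDataset, H: AreaCladogram, costs: EventCosts,
             widespread_policy: str = "cheapest-single") -> float:
    """Minimum reconciliation cost only (fast path for permutation nulls)."""
    _check_universe(ds, H)
    hidx = H.index()
    leaf_areas = ds.assignment.mapping
    out = 0.0
    for clade in ds.clades:
        cost = _clade_min_cost(list(clade.postorder()), leaf_areas, hidx,
                               costs, widespread_policy)
        if cost == _INF:
            raise DatasetError("no feasible embedding for clade "
                               f"{to_newick(clade)}")
        out += cost
    return out


def _classify(H: _HIndex, h: int, x1: int, x2: int,
              costs: EventCosts):
    """Event type and cost for child associations (x1, x2) under m(u)=h.

    Returns (cost, event vector) or None if the pair is not permitted.
    """
    ins1 = H.in_subtree(h, x1)
    ins2 = H.in_subtree(h, x2)
    if ins1 and ins2:
        l, r = H.left[h], H.right[h]
        if l >= 0:
            in_l1, in_r1 = H.in_subtree(l, x1), H.in_subtree(r, x1)
            in_l2, in_r2 = H.in_subtree(l, x2), H.in_subtree(r, x2)
            if (in_l1 and in_r2) or (in_r1 and in_l2):
                ext = H.dist_down(h, x1) - 1 + H.dist_down(h, x2) - 1
                return (costs.vicariance + costs.extinction * ext,
                        (1, 0, ext, 0))
        ext = H.dist_down(h, x1) + H.dist_down(h, x2)
        return (costs.sympatry + costs.extinction * ext, (0, 1, ext, 0))
    if ins1 != ins2:
        ext = H.dist_down(h, x1) if ins1 else H.dist_down(h, x2)
        return (costs.dispersal + costs.extinction * ext, (0, 0, ext, 1))
    return None


def enumerate_optimal(ds: BiogeoDataset, H: AreaCladogram, costs: EventCosts,
                      widespread_policy: str = "cheapest-single",
                      cap: int = 1000,
                      ) -> tuple[list[Reconciliation], bool]:
    """All optimal embeddings (up to ``cap``), in canonical order.

    Returns ``(reconciliations, truncated)``.  Event ranges remain exact in
    :func:`fit` even when the list is truncated here.
    """
    _check_universe(ds, H)
    hidx = H.index()
    leaf_areas = ds.assignment.mapping

    per_clade: list[list[tuple[tuple, tuple]]] = []
    for ci, clade in enumerate(ds.clades):
        post = list(clade.postorder())
        value, tables = _clade_full(post, leaf_areas, hidx, costs,
                                    widespread_policy, keep_tables=True)
        if value[0] == _INF:
            raise DatasetError("no feasible embedding")
        target = value[0]
        items: list[tuple[tuple, tuple]] = []  # (embedding entries, events)

        leaf_keys = {id(u): tuple(sorted(u.leaf_labels())) for u in post}

        def expand(u: Node, h: int, budget: float):
            """Yield (entries, events) for subtree u with m(u)=h at cost=budget."""
            key = ((ci, leaf_keys[id(u)]), hidx.leaf_sets[h])
            if u.is_leaf:
                for pos, extra_d, ev in _leaf_positions(
                        leaf_areas[u.label], hidx, widespread_policy):
                    if pos == h and abs(extra_d * costs.dispersal
                                        - budget) <= _EPS:
                        yield ((key,), ev)
                return
            c1 = tables[id(u.children[0])]
            c2 = tables[id(u.children[1])]
            for x1 in range(hidx.n):
                if c1[x1][0] == _INF:
                    continue
                for x2 in range(hidx.n):
                    if c2[x2][0] == _INF:
                        continue
                    cls = _classify(hidx, h, x1, x2, costs)
                    if cls is None:
                        continue
                    ev_cost, ev = cls
                    rest = budget - ev_cost
                    if abs(c1[x1][0] + c2[x2][0] - rest) > _EPS:
                        continue
                    for e1, v1 in expand(u.children[0], x1, c1[x1][0]):
                        for e2, v2 in expand(u.children[1], x2, c2[x2][0]):
                            yield ((key,) + e1 + e2,
                                   tuple(a + b + c for a, b, c
                                         in zip(ev, v1, v2)))

        root = post[-1]
        root_row = tables[id(root)]
        for h in range(hidx.n):
            if abs(root_row[h][0] - target) <= _EPS:
                for entries, ev in expand(root, h, target):
                    items.append((entries, ev))
                    if len(items) > cap:
                        break
        items.sort()
        per_clade.append(items)

    combos = []
    truncated = False
    for chosen in itertools.product(*per_clade):
        entries = tuple(e for item in chosen for e in item[0])
        events = tuple(sum(item[1][k] for item in chosen) for k in range(4))
        combos.append(Reconciliation(entries, events, costs.total(events)))
        if len(combos) >= cap:
            truncated = True
            break
    combos.sort(key=lambda r: r.embedding)
    return combos, truncated
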