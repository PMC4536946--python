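"""Simulation of biogeographic data-sets with known event history.

The generator draws a random area cladogram ``H`` and grows each clade by
repeated leaf-splitting on ``H``.  Every lineage occupies a vertex of
``H``; each split draws one of the three divergence event types:

* **vicariance** (permitted only at an internal vertex): the daughters
  descend into the two children of the current vertex;
* **sympatry**: both daughters retain the current vertex;
* **dispersal**: one daughter jumps to a uniformly chosen other vertex.

After each split, each daughter sitting at an internal vertex may take one
step down a uniformly chosen edge with probability
``per_branch_extinction_prob`` (an early local extinction).  After growth,
every lineage still at an internal vertex descends to a uniformly chosen
leaf of its subtree, each skipped edge recorded as a true extinction, so
terminals end with a single realized area.  The generating cladogram, the
per-event true counts and the realized assignments are returned as ground
truth for recovery experiments.

Growth stops at exactly the requested number of terminals; there is no
birth-death timing because only topology and assignments matter to the
downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import AreaAssignment, BiogeoDataset
from .reconcile import AreaCladogram
from .trees import Node, random_topology

__all__ = ["SimParams", "SimTruth", "simulate"]


@dataclass(frozen=True)
class SimParams:
    """Conditions of one simulated data-set."""

    n_areas: int = 4
    n_taxa: int = 16
    n_clades: int = 1
    p_vic: float = 0.34
    p_sym: float = 0.33
    p_dis: float = 0.33
    per_branch_extinction_prob: float = 0.05
    seed: int = 0
    #: where each clade's founding lineage sits on H: "leaf" (a sweepstakes
    #: coloniser of one extant area, the default), "root" (a vicariant
    #: radiation from the ancestral composite area) or "uniform"
    root_placement: str = "leaf"

    def __post_init__(self):
        if self.n_areas < 3:
            raise ValueError("n_areas must be >= 3")
        if self.n_clades < 1 or self.n_taxa < self.n_clades:
            raise ValueError("need n_taxa >= n_clades >= 1")
        probs = (self.p_vic, self.p_sym, self.p_dis)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError("p_vic + p_sym + p_dis must equal 1")
        if self.root_placement not in ("leaf", "root", "uniform"):
            raise ValueError(
                f"unknown root placement {self.root_placement!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated data-set."""

    area_cladogram: AreaCladogram
    event_counts: tuple[tuple[int, int, int, int], ...]  # per clade
    assignments: dict[str, str]                          # taxon -> area

    @property
    def total_counts(self) -> tuple[int, int, int, int]:
        return tuple(sum(c[k] for c in self.event_counts) for k in range(4))


class _StuckClade(Exception):
    pass


def _grow_clade(prefix: str, n_leaves: int, H, params: SimParams,
                rng: np.random.Generator):
    """One clade's topology, lineage positions and true event counts."""
    n_h = H.n
    if params.root_placement == "root":
        start = H.root_id
    elif params.root_placement == "uniform":
        start = int(rng.integers(n_h))
    else:
        leaf_ids = sorted(H.leaf_of.values())
        start = leaf_ids[int(rng.integers(len(leaf_ids)))]
    root = Node(None)
    positions: dict[int, int] = {id(root): start}
    tips = [root]
    counts = [0, 0, 0, 0]  # vic, sym, ext, dis

    def maybe_step_down(node: Node) -> None:
        pos = positions[id(node)]
        if H.left[pos] >= 0 and rng.random() < params.per_branch_extinction_prob:
            child = H.left[pos] if rng.random() < 0.5 else H.right[pos]
            positions[id(node)] = child
            counts[2] += 1

    while len(tips) < n_leaves:
        splittable = []
        for t in tips:
            pos = positions[id(t)]
            p_vic = params.p_vic if H.left[pos] >= 0 else 0.0
            p_dis = params.p_dis if n_h > 1 else 0.0
            tot = p_vic + params.p_sym + p_dis
            if tot > 0:
                splittable.append((t, p_vic, params.p_sym, p_dis, tot))
        if not splittable:
            raise _StuckClade
        t, p_vic, p_sym, p_dis, tot = \
            splittable[int(rng.integers(len(splittable)))]
        u = rng.random() * tot
        pos = positions[id(t)]
        c1, c2 = Node(None), Node(None)
        if u < p_vic:
            positions[id(c1)] = H.left[pos]
            positions[id(c2)] = H.right[pos]
            counts[0] += 1
        elif u < p_vic + p_sym:
            positions[id(c1)] = pos
            positions[id(c2)] = pos
            counts[1] += 1
        else:
            other = int(rng.integers(n_h - 1))
            if other >= pos:
                other += 1
            stay_first = rng.random() < 0.5
            positions[id(c1)] = pos if stay_first else other
            positions[id(c2)] = other if stay_first else pos
            counts[3] += 1
        t.children = [c1, c2]
        c1.parent = c2.parent = t
        tips.remove(t)
        tips.extend([c1, c2])
        maybe_step_down(c1)
        maybe_step_down(c2)

    # final descent: every lineage settles in one extant area
    assignments: dict[str, str] = {}
    for i, t in enumerate(tips, start=1):
        t.label = f"{prefix}t{i}"
        pos = positions[id(t)]
        while H.left[pos] >= 0:
            pos = H.left[pos] if rng.random() < 0.5 else H.right[pos]
            counts[2] += 1
        assignments[t.label] = H.nodes[pos].label
    return root, assignments, tuple(counts)


def simulate(params: SimParams,
             area_cladogram: Optional[AreaCladogram] = None,
             max_retries: int = 100,
             ) -> tuple[BiogeoDataset, SimTruth]:
    """Draw one data-set and its ground truth.

    ``area_cladogram`` fixes the generating hypothesis (its leaves define
    the area universe); by default a uniform random topology on areas
    ``A1..An`` is drawn.  Degenerate parameter choices that cannot realize
    the requested number of terminals (e.g. ``p_vic=1`` from a leaf
    placement) raise after ``max_retries`` restarts of the stuck clade.
    """
    rng = np.random.default_rng(params.seed)
    if area_cladogram is None:
        areas = [f"A{i+1}" for i in range(params.n_areas)]
        area_cladogram = AreaCladogram(random_topology(areas, rng))
    elif len(area_cladogram.areas) != params.n_areas:
        raise ValueError("area_cladogram size disagrees with n_areas")
    H = area_cladogram.index()

    base, extra = divmod(params.n_taxa, params.n_clades)
    sizes = [base + (1 if i < extra else 0) for i in range(params.n_clades)]

    clades: list[Node] = []
    per_clade_counts = []
    assignments: dict[str, str] = {}
    for ci, size in enumerate(sizes, start=1):
        prefix = f"c{ci}_" if params.n_clades > 1 else ""
        for attempt in range(max_retries + 1):
            try:
                tree, assign, counts = _grow_clade(prefix, size, H, params,
                                                   rng)
                break
            except _StuckClade:
                if attempt == max_retries:
                    raise ValueError(
                        "simulation parameters cannot realize "
                        f"{size} terminals (clade {ci} stuck after "
                        f"{max_retries} retries)")
        clades.append(tree)
        per_clade_counts.append(counts)
        assignments.update(assign)

    universe = tuple(sorted(area_cladogram.areas))
    mapping = {t: frozenset([a]) for t, a in assignments.items()}
    ds = BiogeoDataset(tuple(clades), AreaAssignment(mapping, universe))
    ds.validate()
    truth = SimTruth(area_cladogram, tuple(per_clade_counts), assignments)
    return ds, truth
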