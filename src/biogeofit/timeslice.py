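"""Time-slicing of biogeographic data-sets.

Biogeographic patterns change through time in a reticulate way, so a
single data-set can superimpose temporally distinct signals.  A time slice
restricts the analysis to a closed stage interval:

1. terminals whose stratigraphic range does not intersect the slice are
   dropped (degree-2 vertices suppressed);
2. every surviving internal vertex is dated with a minimum-age constraint
   computed on the FULL tree — the oldest first-appearance stage among all
   of its descendants, dropped or not — because a divergence must be at
   least as old as the oldest lineage it subtends;
3. internal vertices dated strictly before the slice are dissolved: their
   child subtrees become separate clades, removing the out-of-slice
   divergence without deleting terminals (the method fits multiple clades
   simultaneously, so no information is lost);
4. singleton-area pruning is re-applied to the sliced data-set.

Every drop and dissolve is logged.  A slice that retains fewer than three
terminals or fewer than three represented areas is not analysable and
raises.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import (BiogeoDataset, DatasetError, PruningLog,
                      prune_singleton_areas)
from .trees import Node

__all__ = ["TimeSliceSpec", "PAPER_SLICES", "date_nodes", "slice_dataset"]


@dataclass(frozen=True)
class TimeSliceSpec:
    """A named closed stage interval ``[first_stage, last_stage]``."""

    name: str
    first_stage: str
    last_stage: str


#: The time slices analysed for the pterosaur data-set.
PAPER_SLICES: tuple[TimeSliceSpec, ...] = (
    TimeSliceSpec("Late Triassic-Late Jurassic", "Car", "Tth"),
    TimeSliceSpec("Middle and Late Jurassic", "Aal", "Tth"),
    TimeSliceSpec("Late Jurassic", "Oxf", "Tth"),
    TimeSliceSpec("Late Jurassic-Early Cretaceous", "Oxf", "Alb"),
    TimeSliceSpec("Early Cretaceous", "Ber", "Alb"),
    TimeSliceSpec("Cretaceous", "Ber", "Maa"),
)


def date_nodes(ds: BiogeoDataset) -> dict[int, int]:
    """Minimum-age ordinals for every vertex, keyed by ``id(vertex)``.

    A vertex's age is the smallest first-appearance ordinal (i.e. the
    oldest stage) among all terminals it subtends; ages can only get
    younger tipward.  Requires a first stage for every terminal.
    """
    if ds.strat is None:
        raise DatasetError("dataset has no stratigraphic ranges")
    missing = [t for t in ds.taxa if t not in ds.strat]
    if missing:
        raise DatasetError(f"taxa lack stratigraphic data: {sorted(missing)}")
    scale = ds.stage_scale
    ages: dict[int, int] = {}
    for clade in ds.clades:
        for v in clade.postorder():
            if v.is_leaf:
                ages[id(v)] = scale.ordinal(ds.strat[v.label][0])
            else:
                ages[id(v)] = min(ages[id(c)] for c in v.children)
    return ages


def _restrict(clade: Node, keep: set[str]) -> Node | None:
    """Restrict to surviving leaves, preserving original node identity.

    Unlike :func:`biogeofit.trees.filter_leaves` this keeps the original
    ``Node`` objects for retained branching vertices, so full-tree node
    ages remain addressable by ``id``.
    """
    if clade.is_leaf:
        return clade if clade.label in keep else None
    kept = [_restrict(c, keep) for c in clade.children]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    clade.children = kept
    for c in kept:
        c.parent = clade
    return clade


def slice_dataset(ds: BiogeoDataset, spec: TimeSliceSpec,
                  min_taxa: int = 3, min_areas: int = 3,
                  ) -> tuple[BiogeoDataset, PruningLog]:
    """Derive the time-sliced data-set for ``spec`` (see module docstring)."""
    scale = ds.stage_scale
    first_ord = scale.ordinal(spec.first_stage)
    last_ord = scale.ordinal(spec.last_stage)
    if first_ord > last_ord:
        raise DatasetError(f"slice {spec.name!r} interval reversed")
    ages = date_nodes(ds)
    log = PruningLog()

    keep: set[str] = set()
    for t in ds.taxa:
        t_first, t_last = ds.strat[t]
        if scale.intersects(t_first, t_last, spec.first_stage,
                            spec.last_stage):
            keep.add(t)
        else:
            log.record(f"dropped {t} (range [{t_first}, {t_last}] outside "
                       f"slice [{spec.first_stage}, {spec.last_stage}])")

    new_clades: list[Node] = []
    for clade in ds.clades:
        work = _restrict(_copy_with_ages(clade, ages), keep)
        if work is None:
            continue
        new_clades.extend(_dissolve(work, ages, first_ord, scale, log))

    if not new_clades:
        raise DatasetError(f"slice {spec.name!r} not analysable: "
                           "no terminals survive")

    sliced = ds.restrict_to(keep)
    sliced = BiogeoDataset(tuple(new_clades), sliced.assignment,
                           sliced.strat, scale)
    sliced.validate()
    sliced, prune_log = prune_singleton_areas(sliced, min_taxa=min_taxa)
    for entry in prune_log:
        log.record(entry)
    if sliced.n_taxa < min_taxa or len(sliced.represented_areas()) < min_areas:
        raise DatasetError(
            f"slice {spec.name!r} not analysable: {sliced.n_taxa} terminals "
            f"over {len(sliced.represented_areas())} areas (need >="
            f"{min_taxa} terminals and >={min_areas} areas)")
    return sliced, log


def _copy_with_ages(clade: Node, ages: dict[int, int]) -> Node:
    """Deep-copy a clade, aliasing the copies' ages to the originals'."""
    def rec(v: Node) -> Node:
        new = Node(v.label, [rec(c) for c in v.children])
        ages[id(new)] = ages[id(v)]
        return new
    return rec(clade)


def _dissolve(root: Node, ages: dict[int, int], first_ord: int,
              scale, log: PruningLog) -> list[Node]:
    """Split off subtrees below internal vertices older than the slice.

    A vertex dated exactly at the slice's first stage is retained; only
    strictly older divergences dissolve.
    """
    if root.is_leaf or ages[id(root)] >= first_ord:
        return [root]
    stage = scale.codes[ages[id(root)]]
    log.record("dissolved divergence over "
               f"{{{', '.join(sorted(root.leaf_labels()))}}} "
               f"(dated {stage}, before slice start)")
    out: list[Node] = []
    for child in root.children:
        child.parent = None
        out.extend(_dissolve(child, ages, first_ord, scale, log))
    return out
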