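"""Biogeographic data-sets: domain types, validation, I/O and pruning.

A data-set couples one or more rooted binary taxon cladograms with a
mapping from each terminal taxon to a non-empty set of geographic areas,
optionally annotated with per-taxon stratigraphic ranges (first/last stage
codes) for time-slicing.

File formats
------------
* Trees: standard Newick, one or more trees (names quoted when containing
  spaces).  Parsing is delegated to dendropy.
* Assignments: tab-separated text with a header row ``taxon<TAB>areas``
  where ``areas`` is a semicolon-separated list of area codes.
* Stratigraphic ranges: tab-separated ``taxon<TAB>first<TAB>last``.
* A reader for a NEXUS-like "Treefitter dialect" (TREES block plus a
  DISTRIBUTION matrix of taxon x area 0/1) is provided for supplementary
  data files distributed in that shape.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import dendropy

from .stages import StageScale, MESOZOIC_STAGES
from .trees import Node, filter_leaves, to_newick

__all__ = [
    "AreaAssignment",
    "BiogeoDataset",
    "PruningLog",
    "read_dataset",
    "write_dataset",
    "read_treefitter_nexus",
    "resolve_polytomy",
    "prune_singleton_areas",
    "PTEROSAUR_AREAS",
]

#: The five-area preset used for the pterosaur analyses.
PTEROSAUR_AREAS: tuple[str, ...] = ("EA", "CA", "EU", "NA", "SA")


class DatasetError(ValueError):
    """Raised for structurally invalid biogeographic data-sets."""


@dataclass(frozen=True)
class AreaAssignment:
    """Mapping taxon name -> non-empty frozenset of area codes."""

    mapping: dict[str, frozenset[str]]
    area_universe: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.area_universe)) != len(self.area_universe):
            raise DatasetError("area universe contains duplicates")
        if not self.area_universe:
            raise DatasetError("area universe is empty")
        universe = set(self.area_universe)
        for taxon, areas in self.mapping.items():
            if not areas:
                raise DatasetError(f"taxon {taxon} has an empty area set")
            extra = set(areas) - universe
            if extra:
                raise DatasetError(
                    f"taxon {taxon} assigned to unknown area(s) "
                    f"{sorted(extra)}")

    def areas_of(self, taxon: str) -> frozenset[str]:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise DatasetError(f"taxon {taxon} lacks area assignment") from None

    def area_counts(self, taxa: Iterable[str]) -> dict[str, int]:
        """Number of listed terminals assigning each area (0 for unused)."""
        counts = {a: 0 for a in self.area_universe}
        for t in taxa:
            for a in self.areas_of(t):
                counts[a] += 1
        return counts


@dataclass
class PruningLog:
    """Human-auditable record of taxon removals."""

    entries: list[str] = field(default_factory=list)

    def record(self, message: str) -> None:
        self.entries.append(message)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class BiogeoDataset:
    """One or more taxon clades plus area assignments over a fixed universe.

    ``strat`` optionally maps each taxon to a closed stage interval
    ``(first, last)`` on ``stage_scale``.
    """

    clades: tuple[Node, ...]
    assignment: AreaAssignment
    strat: Optional[dict[str, tuple[str, str]]] = None
    stage_scale: StageScale = field(default_factory=StageScale)

    # -- derived -----------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        out: list[str] = []
        for clade in self.clades:
            out.extend(clade.leaf_labels())
        return out

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def area_universe(self) -> tuple[str, ...]:
        return self.assignment.area_universe

    def represented_areas(self) -> set[str]:
        out: set[str] = set()
        for t in self.taxa:
            out |= self.assignment.areas_of(t)
        return out

    def validate(self, allow_polytomy: bool = False) -> "BiogeoDataset":
        if not self.clades:
            raise DatasetError("dataset has no clades")
        seen: set[str] = set()
        for clade in self.clades:
            if not allow_polytomy and clade.max_out_degree() > 2:
                raise DatasetError(
                    "polytomy present; supply a resolution policy "
                    "(see resolve_polytomy)")
            for name in clade.leaf_labels():
                if name in seen:
                    raise DatasetError(f"duplicate leaf name {name}")
                seen.add(name)
                self.assignment.areas_of(name)  # raises if missing
        unknown = set(self.assignment.mapping) - seen
        if unknown:
            raise DatasetError(
                f"assignment names unknown taxa: {sorted(unknown)}")
        if self.strat is not None:
            missing = seen - set(self.strat)
            if missing:
                raise DatasetError(
                    "taxa lack stratigraphic ranges: "
                    f"{sorted(missing)}")
            for taxon, (first, last) in self.strat.items():
                if not self.stage_scale.older_or_equal(first, last):
                    raise DatasetError(
                        f"taxon {taxon} range [{first}, {last}] reversed")
        return self

    def restrict_to(self, taxa: set[str],
                    drop_unused_areas: bool = False) -> "BiogeoDataset":
        """Keep only the named terminals (suppressing unary vertices)."""
        clades = []
        for clade in self.clades:
            kept = filter_leaves(clade, lambda name: name in taxa)
            if kept is not None:
                clades.append(kept)
        mapping = {t: self.assignment.mapping[t]
                   for t in self.assignment.mapping if t in taxa}
        universe = self.assignment.area_universe
        if drop_unused_areas:
            used = set().union(*mapping.values()) if mapping else set()
            universe = tuple(a for a in universe if a in used)
        strat = None
        if self.strat is not None:
            strat = {t: r for t, r in self.strat.items() if t in taxa}
        return BiogeoDataset(tuple(clades),
                             AreaAssignment(mapping, universe),
                             strat, self.stage_scale)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_trees(newick_text: str) -> list[Node]:
    try:
        tree_list = dendropy.TreeList.get(data=newick_text, schema="newick",
                                          preserve_underscores=True)
    except Exception as err:
        if "Duplicate taxon" in str(err) or "Multiple occurrences" in str(err):
            raise DatasetError(f"duplicate leaf names in newick input: {err}")
        raise DatasetError(f"cannot parse newick input: {err}") from err
    if not len(tree_list):
        raise DatasetError("no trees found in newick input")
    out = []
    for tree in tree_list:
        from .trees import suppress_unary
        root = suppress_unary(_from_dendropy(tree.seed_node))
        out.append(root)
    return out


def _from_dendropy(dnode) -> Node:
    children = dnode.child_nodes()
    if not children:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        if label is None:
            raise DatasetError("unlabelled leaf in newick input")
        return Node(str(label))
    return Node(None, [_from_dendropy(c) for c in children])


def _parse_table(text: str, n_cols: int, what: str) -> list[list[str]]:
    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DatasetError(f"empty {what} table")
    for ln in lines[1:]:  # header row skipped
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < n_cols:
            raise DatasetError(f"malformed {what} row: {ln!r}")
        rows.append([f.strip() for f in fields[:n_cols]])
    return rows


def read_dataset(newick_text: str,
                 assignment_table: str,
                 strat_table: Optional[str] = None,
                 area_universe: Optional[Iterable[str]] = None,
                 stage_scale: Optional[StageScale] = None,
                 polytomy_policy: str = "error",
                 polytomy_resolutions: Optional[dict[str, str]] = None,
                 ) -> BiogeoDataset:
    """Assemble and validate a :class:`BiogeoDataset` from text inputs.

    ``assignment_table`` rows are ``taxon<TAB>areas`` with semicolon-separated
    area codes.  The area universe defaults to the distinct assigned codes in
    first-appearance order.  Polytomies raise unless
    ``polytomy_policy='listed-resolution'`` and a resolution newick string is
    supplied per affected clade (keyed by any leaf name in the polytomy).
    """
    clades = _parse_trees(newick_text)

    mapping: dict[str, frozenset[str]] = {}
    order: list[str] = []
    for taxon, areas_field in _parse_table(assignment_table, 2, "assignment"):
        areas = [a.strip() for a in areas_field.split(";") if a.strip()]
        if not areas:
            raise DatasetError(f"taxon {taxon} has an empty area set")
        if taxon in mapping:
            raise DatasetError(f"duplicate assignment row for taxon {taxon}")
        mapping[taxon] = frozenset(areas)
        for a in areas:
            if a not in order:
                order.append(a)
    universe = tuple(area_universe) if area_universe is not None else tuple(order)
    assignment = AreaAssignment(mapping, universe)

    strat = None
    scale = stage_scale or StageScale(MESOZOIC_STAGES)
    if strat_table is not None:
        strat = {}
        for taxon, first, last in _parse_table(strat_table, 3, "strat"):
            scale.ordinal(first), scale.ordinal(last)
            strat[taxon] = (first, last)

    if polytomy_policy != "error":
        resolved = []
        for clade in clades:
            if clade.max_out_degree() > 2:
                resolved.append(resolve_polytomy(
                    clade, policy=polytomy_policy,
                    resolutions=polytomy_resolutions))
            else:
                resolved.append(clade)
        clades = resolved

    ds = BiogeoDataset(tuple(clades), assignment, strat, scale)
    return ds.validate()


def write_dataset(ds: BiogeoDataset) -> tuple[str, str, Optional[str]]:
    """Serialize to (newick text, assignment table, strat table)."""
    newick = "\n".join(to_newick(c) for c in ds.clades) + "\n"
    lines = ["taxon\tareas"]
    for t in ds.taxa:
        lines.append(f"{t}\t{';'.join(sorted(ds.assignment.areas_of(t)))}")
    assign = "\n".join(lines) + "\n"
    strat = None
    if ds.strat is not None:
        rows = ["taxon\tfirst\tlast"]
        for t in ds.taxa:
            first, last = ds.strat[t]
            rows.append(f"{t}\t{first}\t{last}")
        strat = "\n".join(rows) + "\n"
    return newick, assign, strat


_NEXUS_BLOCK = re.compile(r"begin\s+(\w+)\s*;(.*?)end\s*;",
                          re.IGNORECASE | re.DOTALL)


def read_treefitter_nexus(text: str,
                          stage_scale: Optional[StageScale] = None,
                          ) -> BiogeoDataset:
    """Read a Treefitter-dialect NEXUS subset.

    Expects a TREES block (newick tree statements) and a DISTRIBUTION block
    holding a MATRIX of taxon x area 0/1 incidences preceded by an AREAS
    statement listing the area codes in column order::

        begin distribution;
            areas EA CA EU NA SA;
            matrix
                Taxon_1 1 0 0 0 0
                ...
            ;
        end;
    """
    blocks = {m.group(1).lower(): m.group(2)
              for m in _NEXUS_BLOCK.finditer(text)}
    if "trees" not in blocks:
        raise DatasetError("no TREES block found")
    if "distribution" not in blocks:
        raise DatasetError("no DISTRIBUTION block found")

    newicks = []
    for m in re.finditer(r"tree\s+\S+\s*=\s*(?:\[[^\]]*\]\s*)?([^;]+;)",
                         blocks["trees"], re.IGNORECASE):
        newicks.append(m.group(1))
    if not newicks:
        raise DatasetError("TREES block contains no tree statements")
    clades = _parse_trees("\n".join(newicks))

    dist = blocks["distribution"]
    m = re.search(r"areas\s+([^;]+);", dist, re.IGNORECASE)
    if not m:
        raise DatasetError("DISTRIBUTION block lacks an AREAS statement")
    areas = tuple(m.group(1).split())
    m = re.search(r"matrix(.*?);", dist, re.IGNORECASE | re.DOTALL)
    if not m:
        raise DatasetError("DISTRIBUTION block lacks a MATRIX")
    mapping: dict[str, frozenset[str]] = {}
    for ln in m.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        taxon, flags = parts[0], parts[1:]
        if len(flags) != len(areas):
            raise DatasetError(f"matrix row for {taxon} has "
                               f"{len(flags)} columns, expected {len(areas)}")
        assigned = frozenset(a for a, f in zip(areas, flags) if f == "1")
        if not assigned:
            raise DatasetError(f"taxon {taxon} has an empty area set")
        mapping[taxon] = assigned

    assignment = AreaAssignment(mapping, areas)
    ds = BiogeoDataset(tuple(clades), assignment, None,
                       stage_scale or StageScale(MESOZOIC_STAGES))
    return ds.validate()


# ---------------------------------------------------------------------------
# Polytomy resolution
# ---------------------------------------------------------------------------

def resolve_polytomy(tree: Node, policy: str = "error",
                     resolutions: Optional[dict[str, str]] = None) -> Node:
    """Return a binary version of ``tree`` under the given policy.

    ``policy='error'`` raises on any polytomy.  With
    ``policy='listed-resolution'`` each polytomy must be covered by a
    user-supplied nested grouping (a newick fragment over exactly the
    polytomy's child subtree leaf-sets), keyed in ``resolutions`` by any
    leaf name appearing in the polytomy.
    """
    if policy not in ("error", "listed-resolution"):
        raise ValueError(f"unknown polytomy policy {policy!r}")
    if tree.max_out_degree() <= 2:
        return tree
    if policy == "error":
        raise DatasetError("polytomy present under policy='error'")
    if not resolutions:
        raise DatasetError("listed-resolution policy requires resolutions")

    from .trees import parse_newick

    def rec(v: Node) -> Node:
        if v.is_leaf:
            return Node(v.label)
        children = [rec(c) for c in v.children]
        if len(children) == 2:
            return Node(v.label, children)
        leaf_names = set()
        for c in children:
            leaf_names |= set(c.leaf_labels())
        key = next((k for k in resolutions if k in leaf_names), None)
        if key is None:
            raise DatasetError(
                f"no listed resolution covers polytomy over {sorted(leaf_names)}")
        skeleton = parse_newick(resolutions[key])
        if skeleton.max_out_degree() > 2:
            raise DatasetError("listed resolution is itself unresolved")
        # each skeleton leaf names one child subtree by one of its leaves
        by_leaf = {}
        for c in children:
            for name in c.leaf_labels():
                by_leaf[name] = c
        used: set[int] = set()

        def substitute(s: Node) -> Node:
            if s.is_leaf:
                sub = by_leaf.get(s.label)
                if sub is None:
                    raise DatasetError(
                        f"listed resolution names unknown leaf {s.label!r}")
                if id(sub) in used:
                    raise DatasetError(
                        "listed resolution names the same subtree twice")
                used.add(id(sub))
                return sub
            return Node(None, [substitute(c) for c in s.children])

        out = substitute(skeleton)
        if len(used) != len(children):
            raise DatasetError(
                "listed resolution inconsistent with polytomy (it must "
                "arrange every child subtree exactly once)")
        return out

    resolved = rec(tree)
    if set(resolved.leaf_labels()) != set(tree.leaf_labels()):
        raise DatasetError("resolution changed the leaf set")  # defensive
    return resolved


# ---------------------------------------------------------------------------
# Singleton-area pruning
# ---------------------------------------------------------------------------

def prune_singleton_areas(ds: BiogeoDataset,
                          min_taxa: int = 3,
                          ) -> tuple[BiogeoDataset, PruningLog]:
    """Iteratively remove terminals all of whose areas occur only once.

    Congruence between clades cannot be assessed for an area represented by
    a single terminal, so any terminal whose every assigned area is listed
    by exactly one terminal in the data-set is removed.  Removal can create
    new singletons, so the rule is applied to fixpoint; each pass is logged
    (pass number, taxon, offending areas) so one-pass behaviour can be
    audited.  Clades emptied by pruning are dropped with a logged warning.
    """
    log = PruningLog()
    current = ds
    pass_no = 0
    while True:
        pass_no += 1
        taxa = current.taxa
        counts = current.assignment.area_counts(taxa)
        doomed = [t for t in taxa
                  if all(counts[a] == 1 for a in current.assignment.areas_of(t))]
        if not doomed:
            break
        for t in doomed:
            areas = sorted(current.assignment.areas_of(t))
            log.record(f"pass {pass_no}: pruned {t} "
                       f"(singleton area(s): {', '.join(areas)})")
        survivors = set(taxa) - set(doomed)
        n_clades_before = len(current.clades)
        current = current.restrict_to(survivors)
        if len(current.clades) < n_clades_before:
            log.record(f"pass {pass_no}: warning: "
                       f"{n_clades_before - len(current.clades)} clade(s) "
                       "emptied and dropped")
    if current.n_taxa < min_taxa:
        raise DatasetError("dataset too small for biogeographic analysis "
                           f"({current.n_taxa} terminals after pruning)")
    counts = current.assignment.area_counts(current.taxa)
    unused = [a for a in current.area_universe if counts[a] == 0]
    if unused:
        log.record("dropped now-unrepresented area(s) from universe: "
                   + ", ".join(unused))
        current = current.restrict_to(set(current.taxa),
                                      drop_unused_areas=True)
    return current, log
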