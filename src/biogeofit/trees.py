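"""Light-weight rooted trees and topology enumeration.

The analyses in this package operate on small, fully resolved rooted trees
(taxon cladograms with at most ~100 leaves, area cladograms with at most 7
leaves).  A minimal node class keeps the reconciliation dynamic programme
fast; Newick reading/writing is delegated to :mod:`dendropy` at the I/O
boundary (:mod:`biogeofit.dataset`).
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional, Sequence

__all__ = [
    "Node",
    "parse_newick",
    "to_newick",
    "enumerate_topologies",
    "random_topology",
    "n_rooted_topologies",
]


class Node:
    """A vertex of a rooted tree.  Leaves carry a ``label``."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.children: list[Node] = children if children is not None else []
        self.parent: Optional[Node] = None
        for c in self.children:
            c.parent = self

    # -- structure ---------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [v.label for v in self.leaves()]

    def is_binary(self) -> bool:
        return all(len(v.children) in (0, 2) for v in self.postorder())

    def max_out_degree(self) -> int:
        return max((len(v.children) for v in self.postorder()), default=0)

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(self.label)
        return Node(self.label, [c.copy() for c in self.children])

    # -- canonical form ----------------------------------------------------
    def canonical(self) -> str:
        """Label-sorted canonical newick-like string (topology identity)."""
        if self.is_leaf:
            return self.label or ""
        parts = sorted(c.canonical() for c in self.children)
        return "(" + ",".join(parts) + ")"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({to_newick(self)})"


def _tokenize(text: str) -> Iterator[str]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in "(),;":
            yield ch
            i += 1
        elif ch.isspace():
            i += 1
        elif ch == "'":
            j = text.index("'", i + 1)
            yield text[i + 1:j]
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),;:" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def parse_newick(text: str) -> Node:
    """Parse a single Newick tree (topology + labels; lengths ignored)."""
    tokens = list(_tokenize(text))
    pos = 0

    def parse() -> Node:
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            children = [parse()]
            while tokens[pos] == ",":
                pos += 1
                children.append(parse())
            if tokens[pos] != ")":
                raise ValueError("unbalanced parentheses in newick string")
            pos += 1
            label = None
            if pos < len(tokens) and tokens[pos] not in "(),;":
                label = tokens[pos]
                pos += 1
            node = Node(label, children)
            return node
        label = tokens[pos]
        pos += 1
        return Node(label)

    root = parse()
    return root


def to_newick(node: Node, semicolon: bool = True) -> str:
    def fmt(v: Node) -> str:
        if v.is_leaf:
            lab = v.label or ""
            if any(c in lab for c in " (),;:"):
                return f"'{lab}'"
            return lab
        return "(" + ",".join(fmt(c) for c in v.children) + ")"

    return fmt(node) + (";" if semicolon else "")


def n_rooted_topologies(n_leaves: int) -> int:
    """(2n-3)!! rooted binary leaf-labelled topologies on n leaves."""
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    out = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        out *= k
    return out


def _insertion_points(root: Node) -> list[Optional[Node]]:
    """Nodes above which a new cherry can be grafted; None = above root."""
    points: list[Optional[Node]] = [v for v in root.postorder()
                                    if v.parent is not None]
    points.append(None)
    return points


def _graft(root: Node, point: Optional[Node], leaf_label: str) -> Node:
    new_leaf = Node(leaf_label)
    if point is None:
        new_root = Node(None, [root, new_leaf])
        return new_root
    parent = point.parent
    idx = parent.children.index(point)
    joint = Node(None, [point, new_leaf])
    parent.children[idx] = joint
    joint.parent = parent
    return root


def enumerate_topologies(labels: Sequence[str]) -> Iterator[Node]:
    """Yield every rooted binary topology on ``labels``, each exactly once.

    Deterministic order: leaves are attached in the given label order and
    grafting points are visited in postorder (root graft last).
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    if not labels:
        return

    def build(tree: Node, remaining: list[str]) -> Iterator[Node]:
        if not remaining:
            yield tree
            return
        label, rest = remaining[0], remaining[1:]
        n_points = len(_insertion_points(tree))
        for i in range(n_points):
            work = tree.copy()
            points = _insertion_points(work)
            work = _graft(work, points[i], label)
            yield from build(work, rest)

    yield from build(Node(labels[0]), labels[1:])


def random_topology(labels: Sequence[str], rng) -> Node:
    """Uniform draw over rooted binary leaf-labelled topologies.

    Sequential uniform grafting over all (2m-1) attachment points yields the
    equiprobable (PDA) distribution, since each labelled topology has exactly
    one construction history for a fixed leaf-attachment order.
    """
    labels = sorted(labels)
    tree = Node(labels[0])
    for label in labels[1:]:
        points = _insertion_points(tree)
        point = points[int(rng.integers(len(points)))]
        tree = _graft(tree, point, label)
    return tree


def suppress_unary(root: Node) -> Optional[Node]:
    """Remove degree-2 (single-child) internal vertices; return new root.

    Returns ``None`` for an empty tree.  Operates on the tree in place.
    """
    if root is None:
        return None

    def rec(v: Node) -> Optional[Node]:
        if v.is_leaf:
            return v
        kept = [rec(c) for c in v.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].parent = v.parent
            return kept[0]
        v.children = kept
        for c in kept:
            c.parent = v
        return v

    return rec(root)


def filter_leaves(root: Node, keep: Callable[[str], bool]) -> Optional[Node]:
    """Drop leaves failing ``keep`` and suppress resulting unary vertices."""

    def rec(v: Node) -> Optional[Node]:
        if v.is_leaf:
            return v if keep(v.label) else None
        kept = [rec(c) for c in v.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = Node(v.label, kept)
        return out

    return rec(root)
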