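"""Lightweight rooted-tree model shared by all reconciliation stages.

Parsing and syntax validation are delegated to :mod:`dendropy`; this module
only defines the in-memory node structure, traversal helpers and the Newick
writer used for lossless round-trips.  Supports live on the *edge* above a
node (stored as ``node.support``), which matters when a tree is re-rooted.
"""

from __future__ import annotations

import io
import warnings
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "write_newick",
    "mrca",
    "TreeParseError",
]


class TreeParseError(ValueError):
    """Raised when Newick text or a leaf label cannot be interpreted."""


class Node:
    """One node of a rooted tree.

    Leaves carry ``taxon`` (species identifier) and optionally ``gene_id``;
    internal nodes carry an optional bootstrap ``support`` on the 0-100
    scale (``None`` when the input had no support, which is distinct from a
    support of 0) and an optional ``label`` used to address species-tree
    nodes.
    """

    __slots__ = ("children", "parent", "taxon", "gene_id", "label", "support", "length")

    def __init__(
        self,
        taxon: Optional[str] = None,
        gene_id: Optional[str] = None,
        label: Optional[str] = None,
        support: Optional[float] = None,
        length: Optional[float] = None,
    ):
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.taxon = taxon
        self.gene_id = gene_id
        self.label = label
        self.support = support
        self.length = length

    # -- structure -------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_taxa(self) -> frozenset:
        return frozenset(n.taxon for n in self.leaves())

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "Node":
        new = Node(self.taxon, self.gene_id, self.label, self.support, self.length)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def prune_leaves(self, keep: Callable[["Node"], bool]) -> Optional["Node"]:
        """Return a copy retaining only leaves for which ``keep`` is true.

        Unary internal nodes created by the pruning are suppressed (their
        single child is lifted, branch lengths summed).  Returns ``None``
        when no leaf survives.
        """

        if self.is_leaf:
            return self.copy() if keep(self) else None
        kept = [c.prune_leaves(keep) for c in self.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if self.length is not None or child.length is not None:
                child.length = (self.length or 0.0) + (child.length or 0.0)
            child.parent = None
            return child
        new = Node(label=self.label, support=self.support, length=self.length)
        for c in kept:
            new.add_child(c)
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {write_newick(self)}>"


def _leaf_identity(label: str, delimiter: Optional[str]) -> tuple[str, Optional[str]]:
    if delimiter is None:
        return label, None
    parts = label.split(delimiter, 1)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise TreeParseError(
            f"leaf label {label!r} does not match the 'taxon{delimiter}gene' schema"
        )
    return parts[0], parts[1]


def parse_newick(text: str, leaf_delimiter: Optional[str] = "|") -> Node:
    """Parse one Newick tree into a :class:`Node` hierarchy.

    ``leaf_delimiter`` splits leaf labels into ``(taxon, gene_id)``; pass
    ``None`` for species trees whose leaves are bare taxon names.  Internal
    node labels that parse as numbers are interpreted as bootstrap supports;
    values in [0, 1] are rescaled to the 0-100 convention with a warning.
    """

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        node = Node(length=dnode.edge.length)
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node.taxon, node.gene_id = _leaf_identity(label, leaf_delimiter)
        else:
            raw = dnode.label
            if raw is not None:
                try:
                    support = float(raw)
                except ValueError:
                    node.label = raw
                else:
                    if 0.0 <= support <= 1.0 and support != 0 and "." in str(raw):
                        warnings.warn(
                            f"support {support} looks like a 0-1 proportion; rescaling x100",
                            stacklevel=2,
                        )
                        support *= 100.0
                    node.support = support
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    return convert(dtree.seed_node)


def _format_length(x: float) -> str:
    return repr(x) if x != int(x) else str(int(x))


def write_newick(root: Node) -> str:
    """Serialize a tree; inverse of :func:`parse_newick` on its output."""

    buf = io.StringIO()

    def emit(node: Node) -> None:
        if node.is_leaf:
            if node.gene_id is not None:
                buf.write(f"{node.taxon}|{node.gene_id}")
            else:
                buf.write(node.taxon or "")
        else:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(child)
            buf.write(")")
            if node.support is not None:
                buf.write(_format_length(node.support))
            elif node.label is not None:
                buf.write(node.label)
        if node.length is not None:
            buf.write(f":{node.length}")

    emit(root)
    buf.write(";")
    return buf.getvalue()


def mrca(root: Node, taxa) -> Node:
    """Most recent common ancestor of a set of taxon ids under ``root``."""

    target = frozenset(taxa)
    known = root.leaf_taxa()
    missing = target - known
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    best = root
    found = True
    while found:
        found = False
        for child in best.children:
            if target <= child.leaf_taxa():
                best = child
                found = True
                break
    return best
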