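"""Gene-tree / species-tree reconciliation and gene-duplication calling.

Gene trees are rooted against a rooted species tree by minimizing the
duplication + loss cost of LCA reconciliation over every branch, then each
gene-tree node whose two child clades share at least ``min_shared_species``
taxa and whose bootstrap supports clear the ``bp`` / ``sub_bp`` thresholds
is called a gene-duplication (GD) event, placed at the species-tree LCA of
the union of the child species sets.  Missing supports are treated as
uninformative and pass the thresholds.

Species sets are represented as bitmasks over the species-tree leaves, so
reconciling one gene tree is linear in its size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .trees import Node

__all__ = [
    "SpeciesIndex",
    "GDEvent",
    "lca_map",
    "count_dup_loss",
    "root_gene_tree",
    "detect_duplications",
    "summarize_gd",
]

DEFAULT_BP = 70.0
DEFAULT_SUB_BP = 70.0
DEFAULT_MIN_SHARED = 2


class SpeciesIndex:
    """Preprocessed rooted species tree supporting O(depth) LCA queries on
    taxon bitmasks."""

    def __init__(self, species_tree: Node):
        self.root = species_tree
        self.bit: dict[str, int] = {}
        self.mask: dict[int, int] = {}  # id(node) -> leaf bitmask
        self.depth: dict[int, int] = {}
        self.node_id: dict[int, str] = {}  # id(node) -> stable label
        self.nodes: list[Node] = []
        for leaf in species_tree.leaves():
            if leaf.taxon in self.bit:
                raise ValueError(f"duplicate taxon {leaf.taxon!r} in species tree")
            self.bit[leaf.taxon] = len(self.bit)
        counter = 0
        for node in species_tree.preorder():
            self.depth[id(node)] = 0 if node.parent is None else self.depth[id(node.parent)] + 1
            if node.is_leaf:
                self.node_id[id(node)] = node.taxon
            else:
                self.node_id[id(node)] = node.label or f"N{counter}"
                counter += 1
            self.nodes.append(node)
        for node in species_tree.postorder():
            if node.is_leaf:
                self.mask[id(node)] = 1 << self.bit[node.taxon]
            else:
                m = 0
                for c in node.children:
                    m |= self.mask[id(c)]
                self.mask[id(node)] = m

    def taxa_mask(self, taxa: Iterable[str]) -> int:
        m = 0
        for t in taxa:
            try:
                m |= 1 << self.bit[t]
            except KeyError:
                raise KeyError(f"taxon {t!r} not in species tree") from None
        return m

    def taxa_of_mask(self, mask: int) -> frozenset:
        return frozenset(t for t, b in self.bit.items() if mask >> b & 1)

    def lca_of_mask(self, mask: int) -> Node:
        """Lowest species-tree node whose leaf set contains ``mask``."""

        if mask == 0:
            raise ValueError("empty taxon set has no LCA")
        if mask & ~self.mask[id(self.root)]:
            raise KeyError("taxa outside the species tree")
        node = self.root
        descended = True
        while descended:
            descended = False
            for child in node.children:
                if mask & ~self.mask[id(child)] == 0:
                    node = child
                    descended = True
                    break
        return node

    def label_of(self, node: Node) -> str:
        return self.node_id[id(node)]

    def find(self, label: str) -> Node:
        for node in self.nodes:
            if self.node_id[id(node)] == label:
                return node
        raise KeyError(f"no species-tree node labelled {label!r}")


@dataclass
class GDEvent:
    """One gene-duplication call.

    ``species_node`` is the label of the species-tree node the event maps
    to (the LCA of the union of the two child species sets);
    ``child_species_sets`` are the taxa below each child of the duplication
    node; supports are on the 0-100 scale or ``None`` when absent.
    """

    family_id: str
    species_node: str
    support: Optional[float]
    child_species_sets: tuple[frozenset, frozenset]
    child_supports: tuple[Optional[float], Optional[float]]
    gene_node: Optional[Node] = None

    @property
    def shared_species(self) -> frozenset:
        return self.child_species_sets[0] & self.child_species_sets[1]


def lca_map(gene_node: Node, species: SpeciesIndex | Node) -> Node:
    """Map a gene-tree node to the species-tree LCA of its taxa."""

    if isinstance(species, Node):
        species = SpeciesIndex(species)
    mask = species.taxa_mask(n.taxon for n in gene_node.leaves())
    return species.lca_of_mask(mask)


def count_dup_loss(gene_root: Node, species: SpeciesIndex) -> tuple[int, int]:
    """Duplication and loss counts of the LCA reconciliation of a rooted
    gene tree.

    A gene node is a duplication when it maps to the same species node as
    one of its children.  Losses are counted with the standard depth
    formula: an edge from gene node *u* to child *v* contributes
    ``depth(M(v)) - depth(M(u)) - 1`` losses if *u* is a speciation (0 when
    the mapping steps one level) and ``depth(M(v)) - depth(M(u))`` if *u*
    is a duplication.
    """

    mask: dict[int, int] = {}
    mapped: dict[int, Node] = {}
    dups = losses = 0
    for node in gene_root.postorder():
        if node.is_leaf:
            mask[id(node)] = species.taxa_mask((node.taxon,))
        else:
            m = 0
            for c in node.children:
                m |= mask[id(c)]
            mask[id(node)] = m
        mapped[id(node)] = species.lca_of_mask(mask[id(node)])
    for node in gene_root.postorder():
        if node.is_leaf:
            continue
        m_node = mapped[id(node)]
        is_dup = any(mapped[id(c)] is m_node for c in node.children)
        if is_dup:
            dups += 1
        for c in node.children:
            d = species.depth[id(mapped[id(c)])] - species.depth[id(m_node)]
            losses += d if is_dup else max(d - 1, 0)
    return dups, losses


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def _unrooted_edges(root: Node):
    """Adjacency view of a tree with the root suppressed when binary.

    Returns (nodes, adjacency) where adjacency maps id(node) -> list of
    (neighbor, support, length); support/length are the attributes of the
    connecting edge (a child's ``support``/``length`` in the rooted input).
    """

    adj: dict[int, list] = {}
    objs: dict[int, Node] = {}

    def add(a: Node, b: Node, support, length):
        adj.setdefault(id(a), []).append((b, support, length))
        adj.setdefault(id(b), []).append((a, support, length))
        objs[id(a)] = a
        objs[id(b)] = b

    for node in root.postorder():
        for c in node.children:
            add(node, c, c.support, c.length)
    if len(root.children) == 2 and id(root) in adj:
        # suppress the root: merge its two incident edges
        (a, sa, la), (b, sb, lb) = [e for e in adj[id(root)]]
        adj[id(a)] = [e for e in adj[id(a)] if e[0] is not root]
        adj[id(b)] = [e for e in adj[id(b)] if e[0] is not root]
        support = sa if sa is not None else sb
        length = None
        if la is not None or lb is not None:
            length = (la or 0.0) + (lb or 0.0)
        adj[id(a)].append((b, support, length))
        adj[id(b)].append((a, support, length))
        del adj[id(root)]
        del objs[id(root)]
    return objs, adj


def _build_rooted(u: Node, v: Node, support, length, objs, adj) -> Node:
    """Root the unrooted tree on the edge (u, v)."""

    root = Node()

    def build(node: Node, parent: Node, edge_support, edge_length) -> Node:
        new = Node(
            taxon=node.taxon,
            gene_id=node.gene_id,
            label=node.label,
            support=edge_support,
            length=edge_length,
        )
        for (nbr, s, l) in adj[id(node)]:
            if nbr is parent:
                continue
            new.add_child(build(nbr, node, s, l))
        return new

    half = None if length is None else length / 2.0
    root.add_child(build(u, v, support, half))
    root.add_child(build(v, u, support, half))
    return root


def enumerate_rootings(gene_tree: Node):
    """Yield one rooted tree per branch of the unrooted gene tree."""

    objs, adj = _unrooted_edges(gene_tree)
    seen = set()
    for aid, edges in adj.items():
        for (nbr, support, length) in edges:
            key = frozenset((aid, id(nbr)))
            if key in seen:
                continue
            seen.add(key)
            yield _build_rooted(objs[aid], nbr, support, length, objs, adj)


def root_gene_tree(gene_tree: Node, species: SpeciesIndex | Node) -> Node:
    """Root a gene tree by minimum duplication + loss cost.

    The score is evaluated on every branch; ties are broken by fewer
    duplications, then by the species-tree depth of the LCA mapping of the
    smaller (outgroup-side) root clade (deeper taxonomic span preferred),
    then by the lexicographically smallest leaf label on that side, making
    the choice fully deterministic.
    """

    if isinstance(species, Node):
        species = SpeciesIndex(species)
    if len(gene_tree.leaves()) < 3:
        return gene_tree
    best = None
    best_key = None
    for rooted in enumerate_rootings(gene_tree):
        dups, losses = count_dup_loss(rooted, species)
        out_side = min(
            rooted.children,
            key=lambda c: (len(c.leaves()), min(_leaf_label(n) for n in c.leaves())),
        )
        out_map = lca_map(out_side, species)
        key = (
            dups + losses,
            dups,
            species.depth[id(out_map)],
            min(_leaf_label(n) for n in out_side.leaves()),
        )
        if best_key is None or key < best_key:
            best, best_key = rooted, key
    return best


def _leaf_label(leaf: Node) -> str:
    return f"{leaf.taxon}|{leaf.gene_id}" if leaf.gene_id else str(leaf.taxon)


# ---------------------------------------------------------------------------
# duplication detection
# ---------------------------------------------------------------------------


def detect_duplications(
    gene_root: Node,
    species: SpeciesIndex | Node,
    family_id: str = "",
    bp: float = DEFAULT_BP,
    sub_bp: float = DEFAULT_SUB_BP,
    min_shared_species: int = DEFAULT_MIN_SHARED,
) -> list[GDEvent]:
    """Call GD events on a rooted gene tree.

    A node is an event iff its two child clades share at least
    ``min_shared_species`` taxa, its own support is >= ``bp`` and both
    child supports are >= ``sub_bp`` (missing supports pass).  The event is
    placed at the species-tree LCA of the union of the child species sets.
    """

    if isinstance(species, Node):
        species = SpeciesIndex(species)
    mask: dict[int, int] = {}
    for node in gene_root.postorder():
        if node.is_leaf:
            mask[id(node)] = species.taxa_mask((node.taxon,))
        else:
            m = 0
            for c in node.children:
                m |= mask[id(c)]
            mask[id(node)] = m
    events = []
    for node in gene_root.postorder():
        if len(node.children) != 2:
            continue
        left, right = node.children
        shared = mask[id(left)] & mask[id(right)]
        if bin(shared).count("1") < min_shared_species:
            continue
        if node.support is not None and node.support < bp:
            continue
        if any(c.support is not None and c.support < sub_bp for c in (left, right)):
            continue
        placed = species.lca_of_mask(mask[id(node)])
        events.append(
            GDEvent(
                family_id=family_id,
                species_node=species.label_of(placed),
                support=node.support,
                child_species_sets=(
                    species.taxa_of_mask(mask[id(left)]),
                    species.taxa_of_mask(mask[id(right)]),
                ),
                child_supports=(left.support, right.support),
                gene_node=node,
            )
        )
    return events


def summarize_gd(events: Iterable[GDEvent], species: Optional[SpeciesIndex] = None) -> dict:
    """Per-species-tree-node event counts (Fig-1a-style node annotations)."""

    counts = Counter(e.species_node for e in events)
    if species is not None:
        for node in species.nodes:
            counts.setdefault(species.label_of(node), 0)
    return dict(counts)
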