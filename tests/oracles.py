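"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against different primitives than
the package (frozensets and recursion instead of bitmasks, Biopython
translation instead of codon tables) so that agreement is evidence of
correctness rather than shared code.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from riceshift.trees import Node

# ---------------------------------------------------------------------------
# naive LCA reconciliation on frozensets
# ---------------------------------------------------------------------------


def species_nodes(sp_root):
    """All species-tree nodes with (leafset, depth, label)."""

    out = []

    def walk(node, depth):
        leafset = frozenset(l.taxon for l in node.leaves())
        out.append((node, leafset, depth))
        for c in node.children:
            walk(c, depth + 1)

    walk(sp_root, 0)
    return out


def oracle_lca(taxa, sp_root):
    """Lowest species node containing all taxa, by scanning every node."""

    taxa = frozenset(taxa)
    best = None
    for node, leafset, depth in species_nodes(sp_root):
        if taxa <= leafset:
            if best is None or depth > best[2]:
                best = (node, leafset, depth)
    if best is None:
        raise KeyError(f"no species node contains {sorted(taxa)}")
    return best[0], best[2]


def oracle_reconcile(gene_root: Node, sp_root: Node):
    """(duplications, losses, events) of the LCA reconciliation.

    Events are (species-node object, frozenset left taxa, frozenset right
    taxa) for every binary gene node whose children share >= 2 species —
    support thresholds do not apply (simulated trees carry full support).
    """

    dups = 0
    losses = 0
    events = []

    def walk(node):
        nonlocal dups, losses
        taxa = frozenset(l.taxon for l in node.leaves())
        mapped, depth = oracle_lca(taxa, sp_root)
        if node.is_leaf:
            return mapped, depth
        child_info = [walk(c) for c in node.children]
        is_dup = any(m is mapped for m, _ in child_info)
        if is_dup:
            dups += 1
        for m, d in child_info:
            gap = d - depth
            losses += gap if is_dup else max(gap - 1, 0)
        if len(node.children) == 2:
            left = frozenset(l.taxon for l in node.children[0].leaves())
            right = frozenset(l.taxon for l in node.children[1].leaves())
            if len(left & right) >= 2:
                events.append((mapped, left, right))
        return mapped, depth

    walk(gene_root)
    return dups, losses, events


# ---------------------------------------------------------------------------
# exhaustive unrooted topologies and rootings
# ---------------------------------------------------------------------------


def all_unrooted_topologies(n_leaves: int):
    """All unrooted (multi)binary topologies on leaves 0..n-1.

    Each topology is a frozenset of undirected edges (i, j) over integer
    node ids: leaves are 0..n-1, internal nodes n, n+1, ...  Built by the
    standard leaf-insertion recursion, which enumerates each topology
    exactly once: (2k-5)!! trees for k leaves.
    """

    if n_leaves < 3:
        raise ValueError("need >= 3 leaves for an unrooted topology")
    center = n_leaves  # internal ids start above the leaf ids
    base = frozenset({(0, center), (1, center), (2, center)})
    trees = [(base, center + 1)]
    for leaf in range(3, n_leaves):
        nxt = []
        for edges, next_id in trees:
            for edge in sorted(edges):
                a, b = edge
                new = set(edges)
                new.remove(edge)
                new.add((a, next_id))
                new.add((b, next_id))
                new.add((leaf, next_id))
                nxt.append((frozenset(new), next_id + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def adjacency(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def root_topology_on_edge(edges, edge, leaf_taxon):
    """Build a rooted riceshift Node tree from an unrooted topology by
    rooting on ``edge``; ``leaf_taxon`` maps leaf ids to taxon names."""

    adj = adjacency(edges)

    def build(node_id, parent_id):
        node = Node()
        if node_id in leaf_taxon:
            node.taxon = leaf_taxon[node_id]
            node.gene_id = f"g{node_id}"
        for nbr in adj[node_id]:
            if nbr != parent_id:
                node.add_child(build(nbr, node_id))
        return node

    a, b = edge
    root = Node()
    root.add_child(build(a, b))
    root.add_child(build(b, a))
    return root


def oracle_best_rooting(edges, leaf_taxon, sp_root):
    """Minimum duplication+loss score over every rooting, plus the per-
    rooting details, by naive enumeration."""

    results = []
    for edge in sorted(edges):
        rooted = root_topology_on_edge(edges, edge, leaf_taxon)
        dups, losses, events = oracle_reconcile(rooted, sp_root)
        results.append((dups + losses, dups, edge, events))
    best = min(r[0] for r in results)
    return best, results


# ---------------------------------------------------------------------------
# NG86 pathway oracle (Biopython translation, recursive pathways)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def oracle_site_counts(codon: str):
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                syn += 1 / 3
    return syn, 3 - syn


def _codon_paths(c1: str, c2: str):
    """All stop-free mutational pathways c1 -> c2 as (syn, nonsyn) counts;
    falls back to all pathways when every ordering passes a stop."""

    positions = tuple(i for i in range(3) if c1[i] != c2[i])

    def walk(current, remaining, syn, nonsyn, hit_stop):
        if not remaining:
            yield syn, nonsyn, hit_stop
            return
        for i, pos in enumerate(remaining):
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            step_syn = (
                _aa(nxt) != "*" and _aa(current) != "*" and _aa(nxt) == _aa(current)
            )
            yield from walk(
                nxt,
                remaining[:i] + remaining[i + 1 :],
                syn + (1 if step_syn else 0),
                nonsyn + (0 if step_syn else 1),
                hit_stop or _aa(nxt) == "*",
            )

    all_paths = list(walk(c1, positions, 0, 0, False))
    clean = [(s, n) for s, n, stop in all_paths if not stop]
    return clean if clean else [(s, n) for s, n, _ in all_paths]


def oracle_ng86(x: str, y: str):
    """Independent NG86: returns (S, N, Sd, Nd, Ka, Ks)."""

    import math

    codons = [
        (x[i : i + 3], y[i : i + 3])
        for i in range(0, len(x), 3)
        if set(x[i : i + 3] + y[i : i + 3]) <= set("ACGT")
        and _aa(x[i : i + 3]) != "*"
        and _aa(y[i : i + 3]) != "*"
    ]
    s1 = sum(oracle_site_counts(cx)[0] for cx, _ in codons)
    s2 = sum(oracle_site_counts(cy)[0] for _, cy in codons)
    S = (s1 + s2) / 2
    N = 3 * len(codons) - S
    sd = nd = 0.0
    for cx, cy in codons:
        paths = _codon_paths(cx, cy)
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    pS, pN = sd / S, nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, sd, nd, jc(pN), jc(pS)


# ---------------------------------------------------------------------------
# conditional Monte-Carlo p-value for the 2x2 chi-square
# ---------------------------------------------------------------------------


def permutation_p_2x2(a, b, c, d, rng, n_iter=50_000):
    """Label-permutation p-value of the Pearson statistic, sampling the
    hypergeometric null of tables with the observed margins."""

    import numpy as np

    n = a + b + c + d
    row1, col1 = a + b, a + c

    def stat(aa):
        bb = row1 - aa
        cc = col1 - aa
        dd = n - row1 - cc
        det = aa * dd - bb * cc
        denom = row1 * (n - row1) * col1 * (n - col1)
        return n * det * det / denom

    obs = stat(a)
    draws = rng.hypergeometric(row1, n - row1, col1, size=n_iter)
    stats = np.array([stat(int(v)) for v in draws])
    return float((stats >= obs - 1e-12).mean())


# ---------------------------------------------------------------------------
# duplicate-topology truth table
# ---------------------------------------------------------------------------


def oracle_topology_class(left, right, a, b):
    """Direct restatement of the ABAB/ABAX/ABXB definitions."""

    left = frozenset(left) & (a | b)
    right = frozenset(right) & (a | b)
    la, lb_ = bool(left & a), bool(left & b)
    ra, rb = bool(right & a), bool(right & b)
    if la and lb_ and ra and rb:
        return "ABAB"
    if la and lb_ and ra and not rb:
        return "ABAX"
    if ra and rb and la and not lb_:
        return "ABAX"
    if la and lb_ and rb and not ra:
        return "ABXB"
    if ra and rb and lb_ and not la:
        return "ABXB"
    return "OTHER"


def random_gene_topology(rng, taxa, n_leaves):
    """Random rooted binary gene tree over ``taxa`` (with replacement)."""

    nodes = [
        Node(taxon=taxa[rng.integers(0, len(taxa))], gene_id=f"g{i}")
        for i in range(n_leaves)
    ]
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(support=float(rng.integers(0, 101)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        next(counter)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]
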