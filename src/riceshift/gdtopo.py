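"""Duplicate-topology typing at a focal ancestral node.

At a focal species-tree node whose two descendant lineage sets are labelled
A and B, each gene duplication produces two copies.  If both copies retain
descendants from A and from B the event is ABAB; if one copy retains both
while the other retains only A it is ABAX; only B, ABXB.  A strong excess
of ABAB events argues that lineages A and B diverged independently below
the duplication (no hybrid origin of the focal ancestor), which is the
evolutionary question this classification answers for the indica/japonica
split.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from .reconcile import GDEvent, SpeciesIndex

__all__ = ["ABAB", "ABAX", "ABXB", "OTHER", "classify_topology", "tabulate_topologies", "focal_partition"]

ABAB = "ABAB"
ABAX = "ABAX"
ABXB = "ABXB"
OTHER = "OTHER"


def focal_partition(species: SpeciesIndex, focal_label: str) -> tuple[frozenset, frozenset]:
    """Taxon sets of the two children of the focal species-tree node."""

    node = species.find(focal_label)
    if len(node.children) != 2:
        raise ValueError(f"focal node {focal_label!r} is not binary")
    return node.children[0].leaf_taxa(), node.children[1].leaf_taxa()


def classify_topology(
    event: GDEvent,
    focal_label: str,
    partition_a: frozenset,
    partition_b: frozenset,
) -> str:
    """Classify one GD event at the focal node into ABAB/ABAX/ABXB/OTHER.

    Taxa outside A union B (lineages above the focal node, or extraneous)
    are ignored by intersection.  The event must be placed at the focal
    node.
    """

    if event.species_node != focal_label:
        raise ValueError(
            f"event placed at {event.species_node!r}, not focal node {focal_label!r}"
        )
    a = frozenset(partition_a)
    b = frozenset(partition_b)
    if not a or not b:
        raise ValueError("partition sets A and B must be nonempty")
    if a & b:
        raise ValueError("partition sets A and B must be disjoint")
    universe = a | b
    left, right = (s & universe for s in event.child_species_sets)
    return _classify_sets(left, right, a, b)


def _classify_sets(left: frozenset, right: frozenset, a: frozenset, b: frozenset) -> str:
    def kind(s: frozenset) -> str:
        has_a, has_b = bool(s & a), bool(s & b)
        if has_a and has_b:
            return "AB"
        if has_a:
            return "A"
        if has_b:
            return "B"
        return "X"

    kinds = {kind(left), kind(right)}
    if kinds == {"AB"}:
        return ABAB
    if kinds == {"AB", "A"}:
        return ABAX
    if kinds == {"AB", "B"}:
        return ABXB
    return OTHER


def tabulate_topologies(classes: Iterable[str]) -> dict:
    """Counts and proportions per topology class; proportions sum to 1."""

    counts = Counter(classes)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no events to tabulate")
    order = (ABAB, ABAX, ABXB, OTHER)
    return {
        "counts": {k: counts.get(k, 0) for k in order},
        "proportions": {k: counts.get(k, 0) / total for k in order},
        "n": total,
    }
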