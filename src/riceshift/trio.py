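"""Trio variant filtering and inheritance classification.

A trio is one F1 hybrid and its two parents.  Sites are hard-filtered with
the usual GATK-style annotation thresholds, depth-band filtered around each
sample's mean coverage, and then classified by full-genotype comparison:
an F1 genotype equal to exactly one parent is *inherited* from that parent,
equal to both is *shared*, and equal to neither is *de novo*.  Matching is
multiset equality of the genotype, not Mendelian-transmission consistency;
a het F1 from hom-ref x hom-alt parents is therefore de novo under this
rule even though it is Mendelian-consistent (the ``mendelian_consistent``
helper flags such sites for transparency).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "TrioSite",
    "TrioClass",
    "normalize_genotype",
    "hard_filter",
    "depth_filter",
    "classify_trio_site",
    "mendelian_consistent",
    "af_spectrum",
    "ms_ratio",
    "genotype_composition",
    "HARD_FILTER_THRESHOLDS",
]

#: Classes a trio site can take.
TrioClass = str
INHERITED_P1 = "inherited_P1"
INHERITED_P2 = "inherited_P2"
SHARED = "shared"
DE_NOVO = "de_novo"
UNCLASSIFIED = "unclassified"

#: (INFO key, comparison, threshold): fail when ``value <cmp> threshold``.
HARD_FILTER_THRESHOLDS = (
    ("QD", "lt", 10.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("SOR", "gt", 3.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)

_NONSYN_EFFECTS = frozenset(
    {
        "missense",
        "missense_variant",
        "nonsense",
        "stop_gained",
        "stop_lost",
        "start_lost",
    }
)
_SYN_EFFECTS = frozenset({"synonymous", "synonymous_variant", "stop_retained_variant"})


def normalize_genotype(alleles: Optional[Sequence[int]]) -> Optional[tuple[int, ...]]:
    """Normalize a genotype to a sorted allele tuple; ``None`` stays missing.

    Phasing and allele order are discarded: ``(1, 0)`` and ``(0, 1)`` both
    normalize to ``(0, 1)``.
    """

    if alleles is None:
        return None
    if any(a is None or a < 0 for a in alleles):
        return None
    return tuple(sorted(int(a) for a in alleles))


@dataclass
class TrioSite:
    """One biallelic variant site with trio genotypes and filter fields."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt_f1: Optional[tuple[int, ...]]
    gt_p1: Optional[tuple[int, ...]]
    gt_p2: Optional[tuple[int, ...]]
    depths: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)
    effect: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        self.gt_f1 = normalize_genotype(self.gt_f1)
        self.gt_p1 = normalize_genotype(self.gt_p1)
        self.gt_p2 = normalize_genotype(self.gt_p2)


def hard_filter(site: TrioSite) -> tuple[bool, list[str]]:
    """GATK-style hard filter on INFO annotations.

    Fails iff ANY present field violates its threshold (QD < 10, FS > 60,
    MQ < 40, SOR > 3, MQRankSum < -12.5, ReadPosRankSum < -8); absent
    fields never trigger a failure.  Returns ``(passed, reasons)`` where
    ``reasons`` names every violated predicate.
    """

    reasons = []
    for key, cmp_, thr in HARD_FILTER_THRESHOLDS:
        value = site.info.get(key)
        if value is None:
            continue
        value = float(value)
        if (cmp_ == "lt" and value < thr) or (cmp_ == "gt" and value > thr):
            reasons.append(key)
    return (not reasons), reasons


def depth_filter(depths: dict, mean_depth) -> tuple[bool, list[str]]:
    """Depth-band filter: a sample fails when its depth drops strictly below
    one third of its average depth or rises strictly above three times it;
    the site fails if any trio member fails.

    ``mean_depth`` is a per-sample mapping or one scalar applied to all
    samples.  Boundary depths (exactly mean/3 or 3x mean) pass.
    """

    if not isinstance(mean_depth, dict):
        mean_depth = {name: mean_depth for name in depths}
    failed = []
    for name, depth in depths.items():
        if depth is None:
            continue
        mean = float(mean_depth[name])
        if mean <= 0:
            raise ValueError(f"mean depth for {name!r} must be positive")
        if depth < mean / 3.0 or depth > 3.0 * mean:
            failed.append(name)
    return (not failed), failed


def classify_trio_site(
    gt_f1, gt_p1, gt_p2
) -> TrioClass:
    """Classify one site by full-genotype multiset comparison.

    F1 matching both parents -> shared; only one parent -> inherited from
    that parent; neither -> de novo; any missing genotype -> unclassified.
    """

    f1 = normalize_genotype(gt_f1)
    p1 = normalize_genotype(gt_p1)
    p2 = normalize_genotype(gt_p2)
    if f1 is None or p1 is None or p2 is None:
        return UNCLASSIFIED
    matches_p1 = f1 == p1
    matches_p2 = f1 == p2
    if matches_p1 and matches_p2:
        return SHARED
    if matches_p1:
        return INHERITED_P1
    if matches_p2:
        return INHERITED_P2
    return DE_NOVO


def mendelian_consistent(gt_f1, gt_p1, gt_p2) -> Optional[bool]:
    """Whether the F1 genotype could arise by one allele from each parent."""

    f1 = normalize_genotype(gt_f1)
    p1 = normalize_genotype(gt_p1)
    p2 = normalize_genotype(gt_p2)
    if f1 is None or p1 is None or p2 is None:
        return None
    return any(
        tuple(sorted((a, b))) == f1 for a in p1 for b in p2
    )


def af_spectrum(afs: Iterable[float], bin_edges: Sequence[float]) -> dict:
    """Histogram of per-site allele frequencies over right-closed bins.

    Returns counts per bin (bins are ``(edge[i], edge[i+1]]``, with the
    first bin additionally closed at its left edge) plus the fraction of
    sites with AF strictly above 0.9.
    """

    afs = np.asarray(list(afs), dtype=float)
    if afs.size and (afs.min() < 0 or afs.max() > 1):
        bad = afs[(afs < 0) | (afs > 1)][0]
        raise ValueError(f"allele frequency {bad} outside [0, 1]")
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    if afs.size:
        # right-closed: index of the bin whose right edge is >= value
        bins = np.searchsorted(edges, afs, side="left") - 1
        bins = np.clip(bins, 0, len(counts) - 1)
        for b in bins:
            counts[b] += 1
    frac_high = float((afs > 0.9).mean()) if afs.size else 0.0
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "n": int(afs.size),
        "fraction_af_gt_0.9": frac_high,
    }


def ms_ratio(effects: Iterable[Optional[str]]) -> dict:
    """Nonsynonymous/synonymous (M/S) count ratio from annotation labels.

    Labels outside the two recognized classes are ignored for the ratio and
    reported under ``other``.  The ratio is ``None`` when no synonymous
    site was seen.
    """

    n = s = other = 0
    for eff in effects:
        if eff is None:
            other += 1
        elif eff in _NONSYN_EFFECTS:
            n += 1
        elif eff in _SYN_EFFECTS:
            s += 1
        else:
            other += 1
    return {
        "nonsynonymous": n,
        "synonymous": s,
        "other": other,
        "ratio": (n / s) if s else None,
    }


def genotype_composition(classes: Iterable[TrioClass]) -> dict:
    """Proportions of inherited/shared/de-novo among classified sites.

    ``unclassified`` sites are excluded from the denominator and reported
    separately; all-unclassified input is an error.
    """

    counts = Counter(classes)
    unclassified = counts.pop(UNCLASSIFIED, 0)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified sites (all genotypes missing?)")
    order = (INHERITED_P1, INHERITED_P2, SHARED, DE_NOVO)
    return {
        "counts": {k: counts.get(k, 0) for k in order},
        "proportions": {k: counts.get(k, 0) / total for k in order},
        "n_classified": total,
        "n_unclassified": unclassified,
    }
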