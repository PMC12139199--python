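"""Genomic context of duplicated genes: tandem proximity and TE association.

A duplicated gene pair is *tandem* when both genes lie on the same
chromosome with at most ``max_intervening`` (default 10) annotated genes
between them, counted from the ordinal ranking of all genes on that
chromosome.  TE association asks whether any transposable-element interval
overlaps a window extending 2 kb up- and downstream of the gene body; the
duplicated-vs-TE 2x2 contingency is tested with a Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree
from scipy.stats import chi2

from .formats import GeneRecord

__all__ = [
    "TandemCall",
    "TwoByTwo",
    "find_tandem_pairs",
    "te_proximity",
    "chi_square_2x2",
    "te_association_table",
]

DEFAULT_MAX_INTERVENING = 10
DEFAULT_TE_WINDOW = 2000


@dataclass(frozen=True)
class TandemCall:
    pair: tuple[str, str]
    same_chrom: bool
    intervening: Optional[int]  # undefined across chromosomes
    is_tandem: bool


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b, c, d) = (dup&TE, dup&noTE, nondup&TE, nondup&noTE)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")


def find_tandem_pairs(
    dup_pairs: Iterable[tuple[str, str]],
    gene_order: Sequence[GeneRecord],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[TandemCall]:
    """Call tandem duplications from gene ordinals.

    ``intervening`` is |ordinal difference| - 1 for same-chromosome pairs
    and undefined otherwise; a pair is tandem iff it is on one chromosome
    with at most ``max_intervening`` genes in between.
    """

    index = {g.gene_id: g for g in gene_order}
    calls = []
    for g1, g2 in dup_pairs:
        try:
            r1, r2 = index[g1], index[g2]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in gene order") from None
        if r1.chrom != r2.chrom:
            calls.append(TandemCall((g1, g2), False, None, False))
            continue
        intervening = abs(r1.ordinal - r2.ordinal) - 1
        calls.append(
            TandemCall((g1, g2), True, intervening, intervening <= max_intervening)
        )
    return calls


def te_proximity(
    genes: Sequence[GeneRecord],
    te_intervals: Iterable[tuple[str, int, int]],
    window: int = DEFAULT_TE_WINDOW,
) -> dict[str, bool]:
    """Per-gene TE association within ``window`` bp of the gene body.

    A gene is TE-associated iff any TE interval shares at least one base
    with [start - window, end + window] (1-based inclusive, clamped at 1).
    """

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in te_intervals:
        # 1-based inclusive -> half-open for the interval tree
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    out = {}
    for g in genes:
        lo = max(1, g.start - window)
        hi = g.end + window
        tree = trees.get(g.chrom)
        out[g.gene_id] = bool(tree is not None and tree.overlap(lo, hi + 1))
    return out


def chi_square_2x2(table: TwoByTwo, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1, upper-tail
    p-value; with ``yates`` the continuity correction
    n (|ad - bc| - n/2)^2 / (...) is applied instead.
    """

    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError(
            "a margin of the 2x2 table is zero; the chi-square approximation "
            "is undefined (consider an exact test)"
        )
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    stat = n * det * det / margins
    return stat, 1, float(chi2.sf(stat, 1))


def te_association_table(
    te_flags: dict[str, bool], duplicated: Iterable[str]
) -> TwoByTwo:
    """Cross-tabulate duplication status against TE association."""

    dup = set(duplicated)
    a = b = c = d = 0
    for gene, has_te in te_flags.items():
        if gene in dup:
            if has_te:
                a += 1
            else:
                b += 1
        else:
            if has_te:
                c += 1
            else:
                d += 1
    return TwoByTwo(a, b, c, d)
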