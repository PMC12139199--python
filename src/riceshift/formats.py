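"""Readers for the standard formats every stage touches.

Newick gene/species trees, GFF3/TSV gene coordinate tables, trio VCFs and
TSV expression matrices all funnel into one internal data model
(:class:`~riceshift.trees.Node`, :class:`GeneRecord`,
:class:`~riceshift.trio.TrioSite`, :class:`pandas.DataFrame`).  All readers
accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd

from .trees import Node, parse_newick
from .trio import TrioSite, normalize_genotype

__all__ = [
    "TaxonMap",
    "GeneRecord",
    "read_tree",
    "read_species_tree",
    "read_gene_order",
    "read_trio_vcf",
    "read_expression_matrix",
    "read_intervals",
]

#: INFO keys surfaced on TrioSite when present in the VCF.
TRIO_INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum", "DP")


@dataclass(frozen=True)
class TaxonMap:
    """Assignment of taxon ids to subspecies/subgroup labels.

    Subgroup labels (e.g. ``indica``, ``japonica``, ``aus``, ``wild``,
    ``outgroup``) form a finite declared set; every gene-tree leaf's taxon
    must resolve to exactly one entry.
    """

    subgroup_of: dict = field(default_factory=dict)

    def subgroup(self, taxon_id: str) -> str:
        try:
            return self.subgroup_of[taxon_id]
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} has no subgroup assignment") from None

    def taxa(self, subgroup: str) -> frozenset:
        return frozenset(t for t, g in self.subgroup_of.items() if g == subgroup)


@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive coordinates (GFF3 dialect).

    ``ordinal`` is a dense 1..n rank of the gene along its chromosome by
    start position (ties broken by end, then gene_id) and is the substrate
    for tandem-duplication proximity.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    ordinal: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be positive")


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_tree(source: Union[str, Path], leaf_schema: str = "taxon|gene") -> Node:
    """Read one Newick tree whose leaves encode ``taxon<delim>gene``.

    ``leaf_schema`` is the literal pattern with the delimiter between the
    words "taxon" and "gene" (default ``taxon|gene``).
    """

    delim = leaf_schema.replace("taxon", "").replace("gene", "")
    if not delim:
        raise ValueError(f"leaf_schema {leaf_schema!r} has no delimiter")
    text = source if str(source).rstrip().endswith(";") else None
    if text is None:
        with _open_text(source) as fh:
            text = fh.read()
    return parse_newick(text, leaf_delimiter=delim)


def read_species_tree(source: Union[str, Path]) -> Node:
    """Read a rooted species tree whose leaves are bare taxon ids."""

    text = source if str(source).rstrip().endswith(";") else None
    if text is None:
        with _open_text(source) as fh:
            text = fh.read()
    return parse_newick(text, leaf_delimiter=None)


def _iter_gff3_genes(fh) -> Iterator[tuple[str, str, int, int, str]]:
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9 or cols[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"gene feature without ID attribute: {line!r}")
        yield gene_id, cols[0], int(cols[3]), int(cols[4]), cols[6]


def _iter_tsv_genes(fh) -> Iterator[tuple[str, str, int, int, str]]:
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        gene_id, chrom, start, end = cols[0], cols[1], int(cols[2]), int(cols[3])
        strand = cols[4] if len(cols) > 4 else "+"
        yield gene_id, chrom, start, end, strand


def read_gene_order(path: Union[str, Path], fmt: Optional[str] = None) -> list[GeneRecord]:
    """Read gene coordinates (GFF3 or ``gene_id chrom start end [strand]``
    TSV) and assign per-chromosome ordinals.

    Ordinals are strictly increasing with start within each chromosome;
    ties are broken by end, then gene_id.  Duplicate gene ids are an error.
    """

    if fmt is None:
        fmt = "gff3" if str(path).rstrip(".gz").endswith((".gff", ".gff3")) else "tsv"
    rows = []
    with _open_text(path) as fh:
        it = _iter_gff3_genes(fh) if fmt == "gff3" else _iter_tsv_genes(fh)
        for gene_id, chrom, start, end, strand in it:
            rows.append((gene_id, chrom, start, end, strand))
    seen = set()
    for gene_id, *_ in rows:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
    records: list[GeneRecord] = []
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom in by_chrom:
        ordered = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
        for ordinal, (gene_id, chrom_, start, end, strand) in enumerate(ordered, 1):
            records.append(GeneRecord(gene_id, chrom_, start, end, strand, ordinal))
    return records


def read_trio_vcf(path: Union[str, Path], f1: str, p1: str, p2: str) -> Iterator[TrioSite]:
    """Stream trio sites from a VCF, normalizing genotypes to unordered
    allele multisets (so ``1/0`` == ``0/1`` and ``0|1`` == ``0/1``).

    Multiallelic records are decomposed into one biallelic
    :class:`TrioSite` per alternate allele; alleles other than the focal
    alternate are treated as reference for that decomposition.
    """

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (f1, p1, p2):
        if name not in samples:
            raise KeyError(f"sample {name!r} not in VCF header (samples: {samples})")
    idx = [samples.index(f1), samples.index(p1), samples.index(p2)]

    for rec in vcf:
        gts = rec.genotypes  # [[a, b, phased], ...]
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        depths = {}
        for name, i in zip(("F1", "P1", "P2"), idx):
            if dp is not None:
                d = int(dp[i][0])
                depths[name] = None if d < 0 else d
        info = {k: rec.INFO.get(k) for k in TRIO_INFO_KEYS if rec.INFO.get(k) is not None}
        effect = _ann_effect(rec.INFO.get("ANN"))
        for alt_i, alt in enumerate(rec.ALT, start=1):
            trio_gts = []
            for i in idx:
                alleles = [a for a in gts[i][:-1]]
                if any(a < 0 for a in alleles):
                    trio_gts.append(None)
                else:
                    # collapse non-focal alternates onto the reference
                    trio_gts.append(
                        normalize_genotype(tuple(1 if a == alt_i else 0 for a in alleles))
                    )
            yield TrioSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gt_f1=trio_gts[0],
                gt_p1=trio_gts[1],
                gt_p2=trio_gts[2],
                depths=depths,
                info=info,
                effect=effect,
            )


def _ann_effect(ann: Optional[str]) -> Optional[str]:
    """Extract the first effect term of a SnpEff-style ANN INFO field."""

    if not ann:
        return None
    first = str(ann).split(",")[0].split("|")
    return first[1] if len(first) > 1 else first[0]


def read_expression_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (TSV, first column = gene id)."""

    return pd.read_csv(path, sep="\t", index_col=0)


def read_intervals(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    """Read BED-like TSV intervals ``chrom start end`` (1-based inclusive)."""

    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out
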