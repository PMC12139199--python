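"""Synthetic-data generators with planted truth for every pipeline stage.

Each generator is deterministic given (parameters, seed) — byte-identical
outputs on repeated calls — and returns (or writes alongside its output) a
truth record enumerating the planted labels, so downstream classifiers can
be scored exactly.  Class counts are allocated by deterministic
largest-remainder rounding rather than multinomial sampling, so expected
counts are exact rather than stochastic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gdtopo import ABAB, ABAX, ABXB, _classify_sets
from .reconcile import SpeciesIndex
from .trees import Node, write_newick

__all__ = [
    "simulate_gene_trees",
    "simulate_codon_pair",
    "simulate_trio",
    "simulate_expression",
    "largest_remainder",
]


def largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Deterministic integer allocation of ``total`` across ``fractions``.

    Floors each share and distributes the remainder to the largest
    fractional parts (ties broken by index), so counts are exact for any
    fractions summing to 1.
    """

    fractions = np.asarray(fractions, dtype=float)
    if (fractions < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fractions.sum()}, not 1")
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = sorted(range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# gene trees with planted duplications
# ---------------------------------------------------------------------------


@dataclass
class PlantedGD:
    """Truth record for one planted duplication in one family."""

    family_id: str
    species_node: str
    requested_class: str
    copy1_genes: list = field(default_factory=list)
    copy2_genes: list = field(default_factory=list)
    survived: bool = True
    realized_class: Optional[str] = None
    realized_species_node: Optional[str] = None


def _plant_duplication(
    gene_node: Node,
    a_taxa: frozenset,
    b_taxa: frozenset,
    topology_class: str,
    next_gene_id,
) -> tuple[Node, Node, Node]:
    """Replace ``gene_node`` with a duplication node above it.

    Returns (dup_node, copy1, copy2) where copy2 is pruned according to
    the requested topology class.
    """

    copy2 = gene_node.copy()
    for leaf in copy2.leaves():
        leaf.gene_id = next_gene_id()
    if topology_class == ABAX:
        copy2 = copy2.prune_leaves(lambda n: n.taxon in a_taxa)
    elif topology_class == ABXB:
        copy2 = copy2.prune_leaves(lambda n: n.taxon in b_taxa)
    elif topology_class != ABAB:
        raise ValueError(f"unknown topology class {topology_class!r}")
    if copy2 is None:
        raise ValueError(f"class {topology_class} unrealizable: pruned copy is empty")

    parent = gene_node.parent
    dup = Node(support=100.0, length=gene_node.length)
    if parent is not None:
        parent.children[parent.children.index(gene_node)] = dup
        dup.parent = parent
    gene_node.length = 0.0 if gene_node.length is not None else None
    gene_node.parent = None
    dup.add_child(gene_node)
    dup.add_child(copy2)
    return dup, gene_node, copy2


def simulate_gene_trees(
    species_tree: Node,
    n_families: int,
    dup_spec: Sequence[tuple[str, int, str]] = (),
    loss_prob: float = 0.0,
    seed: int = 0,
    min_shared_species: int = 2,
    weak_support_prob: float = 0.0,
    weak_support_value: float = 50.0,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[list[tuple[str, Node]], dict]:
    """Simulate gene family trees with duplications planted at chosen
    species-tree nodes.

    ``dup_spec`` is a list of (species-node label, count, topology class in
    {ABAB, ABAX, ABXB}); every family receives all requested events.  With
    ``loss_prob`` > 0 each leaf inside a planted duplicate clade is lost
    independently; the truth record replays the draws and marks each event
    as surviving when both copies retain leaves whose species sets still
    share at least ``min_shared_species`` taxa, together with its realized
    class and placement.  Internal supports are 100 unless degraded (with
    probability ``weak_support_prob`` per internal node).
    """

    if not (0.0 <= loss_prob < 1.0):
        raise ValueError("loss_prob must be in [0, 1)")
    species = SpeciesIndex(species_tree)
    focal_parts: dict[str, tuple[frozenset, frozenset]] = {}
    for label, count, cls in dup_spec:
        node = species.find(label)
        if node.is_leaf or len(node.children) != 2:
            raise ValueError(f"cannot plant at non-binary node {label!r}")
        a = node.children[0].leaf_taxa()
        b = node.children[1].leaf_taxa()
        focal_parts[label] = (a, b)
        if cls in (ABAB, ABAX) and not a:
            raise ValueError(f"class {cls} unrealizable at {label!r}: no A taxa")
        if cls in (ABAB, ABXB) and not b:
            raise ValueError(f"class {cls} unrealizable at {label!r}: no B taxa")
        if cls == ABAB and (len(a) == 0 or len(b) == 0):
            raise ValueError(f"class ABAB unrealizable at {label!r}")

    rng = np.random.default_rng(seed)
    families: list[tuple[str, Node]] = []
    truth_events: list[PlantedGD] = []

    for fam_i in range(n_families):
        family_id = f"fam{fam_i:04d}"
        counter = [0]

        def next_gene_id() -> str:
            counter[0] += 1
            return f"g{counter[0]}"

        gene_root = species_tree.copy()
        node_map: dict[str, Node] = {}
        for snode, gnode in zip(species_tree.preorder(), gene_root.preorder()):
            gnode.support = None if gnode.is_leaf else 100.0
            gnode.label = None
            if gnode.is_leaf:
                gnode.gene_id = next_gene_id()
            node_map[species.label_of(snode)] = gnode

        events_here: list[tuple[PlantedGD, Node, Node, Node]] = []
        for label, count, cls in dup_spec:
            for _ in range(count):
                target = node_map[label]
                a, b = focal_parts[label]
                dup, c1, c2 = _plant_duplication(target, a, b, cls, next_gene_id)
                if gene_root is target:
                    gene_root = dup
                node_map[label] = c1  # nested plantings duplicate copy 1
                ev = PlantedGD(family_id=family_id, species_node=label, requested_class=cls)
                events_here.append((ev, dup, c1, c2))

        # snapshot copies after all planting (nested events extend copy 1)
        for ev, dup, c1, c2 in events_here:
            ev.copy1_genes = [f"{n.taxon}|{n.gene_id}" for n in c1.leaves()]
            ev.copy2_genes = [f"{n.taxon}|{n.gene_id}" for n in c2.leaves()]

        # lineage loss inside duplicate clades, replayed into the truth
        lost: set[int] = set()
        if loss_prob > 0:
            candidates = []
            seen = set()
            for ev, dup, c1, c2 in events_here:
                for leaf in dup.leaves():
                    if id(leaf) not in seen:
                        seen.add(id(leaf))
                        candidates.append(leaf)
            draws = rng.random(len(candidates))
            lost = {id(leaf) for leaf, u in zip(candidates, draws) if u < loss_prob}

        for ev, dup, c1, c2 in events_here:
            alive1 = [n for n in c1.leaves() if id(n) not in lost]
            alive2 = [n for n in c2.leaves() if id(n) not in lost]
            sp1 = frozenset(n.taxon for n in alive1)
            sp2 = frozenset(n.taxon for n in alive2)
            ev.survived = len(sp1 & sp2) >= min_shared_species
            if alive1 and alive2:
                a, b = focal_parts[ev.species_node]
                ev.realized_class = _classify_sets(sp1 & (a | b), sp2 & (a | b), a, b)
                ev.realized_species_node = species.label_of(
                    species.lca_of_mask(species.taxa_mask(sp1 | sp2))
                )

        if lost:
            pruned = gene_root.prune_leaves(lambda n: id(n) not in lost)
            if pruned is None or len(pruned.leaves()) < 2:
                continue  # family degenerates entirely
            gene_root = pruned

        if weak_support_prob > 0:
            for node in gene_root.postorder():
                if not node.is_leaf and rng.random() < weak_support_prob:
                    node.support = weak_support_value

        families.append((family_id, gene_root))
        truth_events.extend(ev for ev, *_ in events_here)

    truth = {
        "seed": seed,
        "loss_prob": loss_prob,
        "n_families": n_families,
        "events": [vars(e) for e in truth_events],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for family_id, tree in families:
            (out_dir / f"{family_id}.nwk").write_text(write_newick(tree) + "\n")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return families, truth


# ---------------------------------------------------------------------------
# codon pairs with known substitution counts
# ---------------------------------------------------------------------------


def _single_changes(codon: str):
    """All 9 single-nucleotide neighbours with their synonymy."""

    from .molevol import _STANDARD_AA, _STANDARD_STOPS

    aa = _STANDARD_AA[codon]
    out = []
    for pos in range(3):
        for base in "TCAG":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in _STANDARD_STOPS:
                continue  # never create stops in simulated CDS
            out.append((pos, base, _STANDARD_AA[mutant] == aa))
    return out


def simulate_codon_pair(
    n_codons: int,
    n_syn: int,
    n_nonsyn: int,
    seed: int = 0,
    out_prefix: Optional[Union[str, Path]] = None,
) -> tuple[str, str, dict]:
    """Aligned codon-sequence pair with exactly ``n_syn`` synonymous and
    ``n_nonsyn`` nonsynonymous single-nucleotide differences.

    At most one substitution is placed per codon and no substitution
    creates a stop codon, so the planted counts are exactly what NG86
    pathway counting must report.  Raises when the generated sequence does
    not offer enough eligible codons.
    """

    from .molevol import _STANDARD_STOPS

    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    sense = sorted(set("".join(p) for p in itertools.product("TCAG", repeat=3)) - _STANDARD_STOPS)
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]

    syn_eligible = [i for i, c in enumerate(codons) if any(s for *_, s in _single_changes(c))]
    if len(syn_eligible) < n_syn:
        raise ValueError(
            f"only {len(syn_eligible)} codons admit a synonymous change; need {n_syn}"
        )
    syn_idx = list(rng.choice(syn_eligible, size=n_syn, replace=False)) if n_syn else []
    remaining = [
        i
        for i, c in enumerate(codons)
        if i not in set(syn_idx) and any(not s for *_, s in _single_changes(c))
    ]
    if len(remaining) < n_nonsyn:
        raise ValueError(
            f"only {len(remaining)} codons admit a nonsynonymous change; need {n_nonsyn}"
        )
    nonsyn_idx = list(rng.choice(remaining, size=n_nonsyn, replace=False)) if n_nonsyn else []

    derived = list(codons)
    placed = []
    for idx, want_syn in [(i, True) for i in syn_idx] + [(i, False) for i in nonsyn_idx]:
        options = [(p, b) for p, b, s in _single_changes(codons[idx]) if s == want_syn]
        p, b = options[rng.integers(0, len(options))]
        derived[idx] = derived[idx][:p] + b + derived[idx][p + 1 :]
        placed.append({"codon_index": int(idx), "position": int(p), "synonymous": bool(want_syn)})

    seq1, seq2 = "".join(codons), "".join(derived)
    truth = {
        "seed": seed,
        "n_codons": n_codons,
        "n_syn": n_syn,
        "n_nonsyn": n_nonsyn,
        "substitutions": sorted(placed, key=lambda d: d["codon_index"]),
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{out_prefix}.fasta", "w") as fh:
            fh.write(f">ancestral\n{seq1}\n>derived\n{seq2}\n")
        Path(f"{out_prefix}.truth.json").write_text(json.dumps(truth, indent=1))
    return seq1, seq2, truth


# ---------------------------------------------------------------------------
# trio genotype tables
# ---------------------------------------------------------------------------

_TRIO_GT = {
    "inherited_P1": ("0/1", "0/1", "0/0"),
    "inherited_P2": ("0/1", "0/0", "0/1"),
    "shared": ("0/1", "0/1", "0/1"),
    "de_novo": ("0/1", "0/0", "0/0"),
}

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=250000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read pos rank sum">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF1\tP1\tP2
"""


def simulate_trio(
    n_sites: int,
    class_fractions: Sequence[float],
    mean_depth: int = 30,
    seed: int = 0,
    missing_prob: float = 0.0,
    out_path: Optional[Union[str, Path]] = None,
) -> tuple[str, dict]:
    """VCF of trio sites with planted inheritance classes.

    ``class_fractions`` are (inherited_P1, inherited_P2, shared, de_novo)
    summing to 1; counts are the exact largest-remainder allocation.  Per
    sample depths are Poisson(``mean_depth``) and all INFO annotations are
    generated inside the hard-filter pass region.  ``missing_prob`` masks
    individual genotypes to ``./.`` for missingness experiments (replayed
    into the truth).  Returns (VCF text, truth).
    """

    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    classes = ("inherited_P1", "inherited_P2", "shared", "de_novo")
    counts = largest_remainder(class_fractions, n_sites)
    rng = np.random.default_rng(seed)
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    order = rng.permutation(n_sites)
    labels = [labels[i] for i in order]

    bases = "ACGT"
    lines = [_VCF_HEADER.rstrip("\n")]
    truth_sites = []
    for i, label in enumerate(labels):
        pos = 1000 + 100 * i
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(0, 3)) % 4]
        gts = list(_TRIO_GT[label])
        masked = []
        if missing_prob > 0:
            for j in range(3):
                if rng.random() < missing_prob:
                    gts[j] = "./."
                    masked.append(("F1", "P1", "P2")[j])
        depths = rng.poisson(mean_depth, size=3) + 1
        info = (
            f"QD=25.0;FS=1.0;MQ=60.0;SOR=1.0;MQRankSum=0.0;"
            f"ReadPosRankSum=0.0;DP={int(depths.sum())}"
        )
        fields = [
            "chr1",
            str(pos),
            ".",
            ref,
            alt,
            "100",
            ".",
            info,
            "GT:DP",
        ] + [f"{gt}:{d}" for gt, d in zip(gts, depths)]
        lines.append("\t".join(fields))
        truth_sites.append(
            {
                "pos": pos,
                "class": label,
                "masked_samples": masked,
                "observable": not masked,
            }
        )
    text = "\n".join(lines) + "\n"
    truth = {
        "seed": seed,
        "n_sites": n_sites,
        "counts": dict(zip(classes, counts)),
        "sites": truth_sites,
    }
    if out_path is not None:
        Path(out_path).write_text(text)
        Path(str(out_path) + ".truth.json").write_text(json.dumps(truth, indent=1))
    return text, truth


# ---------------------------------------------------------------------------
# expression triplets
# ---------------------------------------------------------------------------

_MODE_ORDER = ("A", "PD", "ND", "PPD", "NPD", "POD", "NOD")


def _f1_mean(mode: str, lp: float, hp: float, fold: float) -> float:
    mp = (lp + hp) / 2.0
    return {
        "A": mp,
        "PD": hp,
        "ND": lp,
        "PPD": (mp + hp) / 2.0,
        "NPD": (mp + lp) / 2.0,
        "POD": hp * fold,
        "NOD": lp / fold,
    }[mode]


def simulate_expression(
    n_genes: int,
    mode_mix: dict,
    fold: float = 4.0,
    n_reps: int = 6,
    cv: float = 0.1,
    seed: int = 0,
    base_range: tuple[float, float] = (10.0, 200.0),
    out_path: Optional[Union[str, Path]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Replicate TPM matrix for P1/P2/F1 with planted inheritance modes.

    Parental means differ by factor ``fold`` (which parent is higher is
    randomized per gene); the F1 mean is placed per mode (A at mid-parent,
    PD/ND at the high/low parent, PPD/NPD halfway between mid and
    high/low, POD/NOD a further factor ``fold`` beyond the high/low
    parent).  Replicate noise is mean-preserving lognormal with
    coefficient of variation ``cv`` (``cv=0`` gives exact means).
    """

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    modes = [m for m in _MODE_ORDER if mode_mix.get(m, 0) > 0]
    fracs = [mode_mix[m] for m in modes]
    counts = largest_remainder(fracs, n_genes)
    rng = np.random.default_rng(seed)
    labels = [m for m, k in zip(modes, counts) for _ in range(k)]
    labels = [labels[i] for i in rng.permutation(n_genes)]

    lo, hi = base_range
    sigma = float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0

    def noisy(mean: float, n: int) -> np.ndarray:
        if sigma == 0:
            return np.full(n, mean)
        return mean * np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=n))

    rows = []
    gene_ids = []
    for i, mode in enumerate(labels):
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lp_mean, hp_mean = base, base * fold
        p1_high = bool(rng.integers(0, 2))
        p1_mean, p2_mean = (hp_mean, lp_mean) if p1_high else (lp_mean, hp_mean)
        f1_mean = _f1_mean(mode, lp_mean, hp_mean, fold)
        rows.append(
            np.concatenate(
                [noisy(p1_mean, n_reps), noisy(p2_mean, n_reps), noisy(f1_mean, n_reps)]
            )
        )
        gene_ids.append(f"gene{i:05d}")

    columns = (
        [f"P1_r{j+1}" for j in range(n_reps)]
        + [f"P2_r{j+1}" for j in range(n_reps)]
        + [f"F1_r{j+1}" for j in range(n_reps)]
    )
    frame = pd.DataFrame(rows, index=gene_ids, columns=columns)
    frame.index.name = "gene_id"
    truth = {
        "seed": seed,
        "fold": fold,
        "cv": cv,
        "n_reps": n_reps,
        "counts": dict(zip(modes, counts)),
        "modes": dict(zip(gene_ids, labels)),
    }
    if out_path is not None:
        frame.to_csv(out_path, sep="\t")
        Path(str(out_path) + ".truth.json").write_text(json.dumps(truth, indent=1))
    return frame, truth
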