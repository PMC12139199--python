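"""Nei-Gojobori (1986) Ka/Ks engine with Jukes-Cantor correction.

For a codon-aligned pair of coding sequences the method counts synonymous
(S) and nonsynonymous (N) *sites* per codon (each position contributes the
fraction of its three possible single-nucleotide changes that are
synonymous; changes to stop codons count as nonsynonymous), counts
synonymous and nonsynonymous *differences* (Sd, Nd) by averaging over all
orderings of the single-step mutational pathways between differing codons,
and corrects the proportions pS = Sd/S and pN = Nd/N for multiple hits
with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).  Ks serves as an
approximate molecular clock for dating duplications and divergences;
Ka/Ks measures selective pressure.

Pathways passing through a stop codon are excluded from the averaging
(when every ordering hits a stop, all orderings are used).  Codon columns
containing gaps, ambiguous bases or stop codons in either sequence are
excluded from all counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "KsResult",
    "SaturationError",
    "codon_site_counts",
    "ng86_pair",
    "jc_correct",
    "ks_distribution",
    "select_clock_genes",
]

_BASES = "TCAG"


class SaturationError(ValueError):
    """Raised when a substitution proportion is beyond the JC domain (p >= 3/4)."""


def _code(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    stops = set(table.stop_codons)
    return aa, stops


_STANDARD_AA, _STANDARD_STOPS = _code(1)


def _translate(codon: str, aa_table) -> Optional[str]:
    return aa_table.get(codon)  # None for stops


def codon_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one sense codon.

    s is the sum over the three positions of the fraction of the three
    possible single-nucleotide changes that preserve the amino acid
    (changes to stop codons are nonsynonymous); n = 3 - s.
    """

    aa_table, stops = _code(table_id) if table_id != 1 else (_STANDARD_AA, _STANDARD_STOPS)
    codon = codon.upper().replace("U", "T")
    if codon in stops:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = aa_table[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if aa_table.get(mutant) == aa:  # stops translate to None
                s += 1.0 / 3.0
    return s, 3.0 - s


def _pathway_diffs(x: str, y: str, aa_table, stops) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts between two codons."""

    positions = [i for i in range(3) if x[i] != y[i]]
    if not positions:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in permutations(positions):
        current = x
        syn = nonsyn = 0.0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + y[pos] + current[pos + 1 :]
            if nxt in stops:
                hit_stop = True
            if aa_table.get(nxt) == aa_table.get(current) and nxt not in stops and current not in stops:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        all_paths.append((syn, nonsyn))
        if not hit_stop:
            valid.append((syn, nonsyn))
    use = valid if valid else all_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


@dataclass
class KsResult:
    """NG86 counts and corrected distances for one codon-aligned pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]
    n_codons_retained: int
    status: str = "ok"


def _clean_codons(x: str, y: str) -> list[tuple[str, str]]:
    x = x.upper().replace("U", "T")
    y = y.upper().replace("U", "T")
    if len(x) != len(y):
        raise ValueError("aligned sequences differ in length")
    if len(x) % 3:
        raise ValueError(f"alignment length {len(x)} is not a multiple of 3")
    retained = []
    for i in range(0, len(x), 3):
        cx, cy = x[i : i + 3], y[i : i + 3]
        if any(b not in _BASES for b in cx + cy):
            continue
        if cx in _STANDARD_STOPS or cy in _STANDARD_STOPS:
            continue
        retained.append((cx, cy))
    return retained


def ng86_pair(x: str, y: str, table_id: int = 1) -> KsResult:
    """NG86 Ka/Ks for one pair of aligned coding sequences.

    Gap-, ambiguity- or stop-containing codon columns are excluded.  Ks
    (or Ka) is ``None`` with status ``saturated`` when the corresponding
    proportion reaches the Jukes-Cantor domain boundary of 3/4; the
    Ka/Ks ratio is ``None`` whenever Ks is 0 or undefined.
    """

    aa_table, stops = _code(table_id) if table_id != 1 else (_STANDARD_AA, _STANDARD_STOPS)
    retained = _clean_codons(x, y)
    if not retained:
        raise ValueError("no retained codons after filtering")
    s_x = s_y = 0.0
    sd = nd = 0.0
    for cx, cy in retained:
        sx, _ = codon_site_counts(cx, table_id)
        sy, _ = codon_site_counts(cy, table_id)
        s_x += sx
        s_y += sy
        d_s, d_n = _pathway_diffs(cx, cy, aa_table, stops)
        sd += d_s
        nd += d_n
    n_codons = len(retained)
    S = (s_x + s_y) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    status = "ok"
    try:
        Ks = jc_correct(pS)
    except SaturationError:
        Ks, status = None, "saturated"
    try:
        Ka = jc_correct(pN)
    except SaturationError:
        Ka, status = None, "saturated"
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KsResult(S, N, sd, nd, pS, pN, Ka, Ks, ratio, n_codons, status)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""

    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4 is beyond the JC domain")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ks_distribution(
    ks_values: Iterable[Optional[float]],
    bandwidth: Optional[float] = None,
    grid_points: int = 512,
) -> dict:
    """Gaussian kernel density of finite Ks values with modal Ks.

    Saturated/undefined values (``None``/NaN) are excluded from the
    density but counted.  The mode is the argmax of the density on a
    ``grid_points``-point grid over [0, max(Ks)]; all local maxima are
    listed.
    """

    from scipy.stats import gaussian_kde

    ks_values = list(ks_values)
    values = [v for v in ks_values if v is not None and math.isfinite(v)]
    n_excluded = len(ks_values) - len(values)
    if len(values) < 2:
        raise ValueError("need at least 2 finite Ks values for a density")
    arr = np.asarray(values, dtype=float)
    hi = float(arr.max())
    grid = np.linspace(0.0, hi if hi > 0 else 1.0, grid_points)
    if np.ptp(arr) == 0:
        # degenerate sample: all mass at one point
        density = np.zeros_like(grid)
        mode = float(arr[0])
        local_maxima = [mode]
    else:
        kde = gaussian_kde(arr, bw_method=bandwidth)
        density = kde(grid)
        mode = float(grid[int(np.argmax(density))])
        interior = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
        local_maxima = [float(g) for g in grid[1:-1][interior]]
        if not local_maxima:
            local_maxima = [mode]
    return {
        "grid": grid,
        "density": density,
        "mode": mode,
        "local_maxima": local_maxima,
        "n_used": len(values),
        "n_excluded": n_excluded,
    }


def select_clock_genes(
    genes: Sequence[dict],
    min_len: int = 900,
    max_len: int = 1200,
    min_coverage: float = 0.0,
) -> list[dict]:
    """Molecular-clock gene filter: retain genes whose CDS length lies in
    [min_len, max_len] bp (inclusive) and whose taxa coverage is at least
    ``min_coverage``.

    ``genes`` is a sequence of mappings with keys ``length`` and optional
    ``coverage`` (fraction of taxa present, default 1.0).
    """

    kept = [
        g
        for g in genes
        if min_len <= g["length"] <= max_len and g.get("coverage", 1.0) >= min_coverage
    ]
    return kept
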