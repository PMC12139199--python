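"""F1-vs-parents expression inheritance-mode classification.

For each gene with replicate TPM values in two parents (P1, P2) and their
F1 hybrid, define LP/HP as the lower/higher-expressed parent and MP as the
mid-parent level (P1+P2)/2.  Three directional significance calls — F1 vs
HP, F1 vs LP and F1 vs MP — place the gene in one of seven inheritance
modes:

======  =============================================================
POD     F1 significantly above the high parent (positive overdominance)
NOD     F1 significantly below the low parent (negative overdominance)
PD      F1 above MP, indistinguishable from HP (positive dominance)
ND      F1 below MP, indistinguishable from LP (negative dominance)
PPD     F1 above MP and below HP (positive partial dominance)
NPD     F1 below MP and above LP (negative partial dominance)
A       F1 at MP, between the parents (additive)
NC      any other combination (not classifiable)
======  =============================================================

Additive inheritance is the null expectation of simple allelic dosage; a
predominance of the non-additive modes among differentially expressed
genes is the transcriptional signature associated with heterosis.

Significance is a Welch two-sided t-test on log2(TPM + 1) at alpha = 0.05
by default; the MP comparison uses the pseudo-sample of per-replicate
parental averages.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTriplet",
    "SigCalls",
    "MODES",
    "sig_call",
    "classify_mode",
    "classify_triplet",
    "classify_matrix",
    "retain_de_genes",
    "tabulate_modes",
]

MODES = ("A", "PD", "ND", "PPD", "NPD", "POD", "NOD")
SIG_HIGHER = "sig_higher"
SIG_LOWER = "sig_lower"
NS = "ns"

DEFAULT_ALPHA = 0.05
#: genes whose mean TPM is below this in every group are left unclassified
MIN_MEAN_TPM = 1.0


@dataclass
class ExpressionTriplet:
    """Replicate expression of one gene in both parents and the F1."""

    gene_id: str
    p1: np.ndarray
    p2: np.ndarray
    f1: np.ndarray

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        for arr in (self.p1, self.p2, self.f1):
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError("each group needs >= 2 replicate values")
            if (arr < 0).any():
                raise ValueError("TPM values must be nonnegative")


@dataclass(frozen=True)
class SigCalls:
    """Directional significance of F1 against HP, LP and MP."""

    vs_hp: str
    vs_lp: str
    vs_mp: str


def _welch_log(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value on log2(x+1); degenerate groups handled."""

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if la.std() == 0 and lb.std() == 0:
        return 1.0 if la.mean() == lb.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(la, lb, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def sig_call(f1: np.ndarray, reference: np.ndarray, alpha: float = DEFAULT_ALPHA) -> str:
    """Directional call of F1 replicates against a reference sample."""

    f1 = np.asarray(f1, dtype=float)
    reference = np.asarray(reference, dtype=float)
    p = _welch_log(f1, reference)
    if p >= alpha:
        return NS
    diff = np.log2(f1 + 1.0).mean() - np.log2(reference + 1.0).mean()
    if diff > 0:
        return SIG_HIGHER
    if diff < 0:
        return SIG_LOWER
    return NS


def classify_mode(calls: SigCalls) -> str:
    """Map one SigCalls combination to its inheritance mode.

    Overdominance takes precedence (a POD gene is also above MP); every
    combination maps to exactly one mode, with combinations inconsistent
    with LP <= MP <= HP falling through to NC.
    """

    if calls.vs_hp == SIG_HIGHER:
        return "POD"
    if calls.vs_lp == SIG_LOWER:
        return "NOD"
    if calls.vs_mp == SIG_HIGHER and calls.vs_hp == NS:
        return "PD"
    if calls.vs_mp == SIG_LOWER and calls.vs_lp == NS:
        return "ND"
    if calls.vs_mp == SIG_HIGHER and calls.vs_hp == SIG_LOWER:
        return "PPD"
    if calls.vs_mp == SIG_LOWER and calls.vs_lp == SIG_HIGHER:
        return "NPD"
    if calls.vs_mp == NS and calls.vs_hp == SIG_LOWER and calls.vs_lp == SIG_HIGHER:
        return "A"
    return "NC"


def classify_triplet(triplet: ExpressionTriplet, alpha: float = DEFAULT_ALPHA) -> tuple[str, SigCalls]:
    """Classify one gene; returns (mode, calls).

    Genes below the expression floor (mean TPM < 1 in all three groups)
    are reported as NC without testing.  HP/LP are decided by parental
    means, so swapping the parent labels cannot change the mode.
    """

    p1, p2, f1 = triplet.p1, triplet.p2, triplet.f1
    if max(p1.mean(), p2.mean(), f1.mean()) < MIN_MEAN_TPM:
        return "NC", SigCalls(NS, NS, NS)
    if p1.mean() >= p2.mean():
        hp, lp = p1, p2
    else:
        hp, lp = p2, p1
    n = min(p1.size, p2.size)
    mp = (p1[:n] + p2[:n]) / 2.0
    calls = SigCalls(
        vs_hp=sig_call(f1, hp, alpha),
        vs_lp=sig_call(f1, lp, alpha),
        vs_mp=sig_call(f1, mp, alpha),
    )
    return classify_mode(calls), calls


# ---------------------------------------------------------------------------
# vectorized matrix interface
# ---------------------------------------------------------------------------


def _welch_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch test on log2(x+1); returns (pvalues, mean differences)."""

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    diff = la.mean(axis=1) - lb.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate] = np.where(diff[degenerate] == 0, 1.0, 0.0)
    return p, diff


def _calls_from(p: np.ndarray, diff: np.ndarray, alpha: float) -> np.ndarray:
    out = np.full(p.shape, NS, dtype=object)
    out[(p < alpha) & (diff > 0)] = SIG_HIGHER
    out[(p < alpha) & (diff < 0)] = SIG_LOWER
    return out


def classify_matrix(
    p1: np.ndarray, p2: np.ndarray, f1: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Classify many genes at once; rows are genes, columns replicates."""

    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    hp_is_p1 = p1.mean(axis=1) >= p2.mean(axis=1)
    hp = np.where(hp_is_p1[:, None], p1, p2)
    lp = np.where(hp_is_p1[:, None], p2, p1)
    n = min(p1.shape[1], p2.shape[1])
    mp = (p1[:, :n] + p2[:, :n]) / 2.0
    calls_hp = _calls_from(*_welch_matrix(f1, hp), alpha)
    calls_lp = _calls_from(*_welch_matrix(f1, lp), alpha)
    calls_mp = _calls_from(*_welch_matrix(f1, mp), alpha)
    floor = np.maximum.reduce([p1.mean(axis=1), p2.mean(axis=1), f1.mean(axis=1)]) < MIN_MEAN_TPM
    modes = []
    for i in range(p1.shape[0]):
        if floor[i]:
            modes.append("NC")
        else:
            modes.append(classify_mode(SigCalls(calls_hp[i], calls_lp[i], calls_mp[i])))
    return modes


def retain_de_genes(
    p1: np.ndarray,
    p2: np.ndarray,
    f1: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = 2.0,
) -> np.ndarray:
    """Differential-expression retention filter.

    A gene is retained when the F1 differs significantly from at least one
    parent (Welch test on log2(TPM+1), Benjamini-Hochberg adjusted within
    each comparison) with |log2 fold change| >= log2(min_fold) on the
    (mean+1) scale.  Returns a boolean mask over genes.
    """

    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    retained = np.zeros(p1.shape[0], dtype=bool)
    for parent in (p1, p2):
        p, _ = _welch_matrix(f1, parent)
        padj = multipletests(p, method="fdr_bh")[1]
        lfc = np.log2(f1.mean(axis=1) + 1.0) - np.log2(parent.mean(axis=1) + 1.0)
        retained |= (padj < alpha) & (np.abs(lfc) >= np.log2(min_fold))
    return retained


def tabulate_modes(modes: Iterable[str]) -> dict:
    """Counts per mode and the additive fraction among classified genes.

    NC genes are excluded from the denominator and reported separately;
    the additive fraction is ``None`` when nothing was classifiable.
    """

    counts = Counter(modes)
    nc = counts.pop("NC", 0)
    total = sum(counts.values())
    return {
        "counts": {m: counts.get(m, 0) for m in MODES},
        "n_classified": total,
        "n_nc": nc,
        "additive_fraction": (counts.get("A", 0) / total) if total else None,
        "nonadditive_fraction": (1.0 - counts.get("A", 0) / total) if total else None,
    }
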