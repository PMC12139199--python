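"""Expression inheritance-mode classification."""

import itertools
from collections import Counter

import numpy as np
import pytest

from riceshift.heterosis import (
    NS,
    SIG_HIGHER,
    SIG_LOWER,
    ExpressionTriplet,
    SigCalls,
    classify_matrix,
    classify_mode,
    classify_triplet,
    retain_de_genes,
    sig_call,
    tabulate_modes,
)
from riceshift.simulate import simulate_expression

H, L, N = SIG_HIGHER, SIG_LOWER, NS

# hard-coded 3^3 decision table (vs_hp, vs_lp, vs_mp) -> mode, written out
# independently from the rule precedence: POD first, then NOD, then the
# dominance/partial-dominance/additive rules.
EXPECTED_TABLE = {
    # vs_hp == sig_higher -> POD regardless of the rest
    **{(H, lp, mp): "POD" for lp in (H, L, N) for mp in (H, L, N)},
    # vs_hp == sig_lower
    (L, L, H): "NOD", (L, L, L): "NOD", (L, L, N): "NOD",
    (L, H, H): "PPD", (L, H, L): "NPD", (L, H, N): "A",
    (L, N, H): "PPD", (L, N, L): "ND", (L, N, N): "NC",
    # vs_hp == ns
    (N, L, H): "NOD", (N, L, L): "NOD", (N, L, N): "NOD",
    (N, H, H): "PD", (N, H, L): "NPD", (N, H, N): "NC",
    (N, N, H): "PD", (N, N, L): "ND", (N, N, N): "NC",
}


class TestDecisionTable:
    def test_expected_table_is_exhaustive(self):
        assert len(EXPECTED_TABLE) == 27

    @pytest.mark.parametrize("combo", sorted(EXPECTED_TABLE))
    def test_each_combination_maps_uniquely(self, combo):
        vs_hp, vs_lp, vs_mp = combo
        assert classify_mode(SigCalls(vs_hp, vs_lp, vs_mp)) == EXPECTED_TABLE[combo]

    def test_rule_precedence_examples(self):
        assert classify_mode(SigCalls(H, H, H)) == "POD"
        assert classify_mode(SigCalls(L, H, N)) == "A"
        assert classify_mode(SigCalls(L, H, H)) == "PPD"


class TestSigCall:
    def test_identical_distributions_ns(self):
        x = np.array([10.0, 11.0, 9.0, 10.5])
        assert sig_call(x, x.copy()) == NS

    def test_strong_difference_called_with_direction(self):
        rng = np.random.default_rng(0)
        ref = 50 * np.exp(rng.normal(0, 0.05, 6))
        assert sig_call(ref * 8, ref) == SIG_HIGHER
        assert sig_call(ref / 8, ref) == SIG_LOWER

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = 20 * np.exp(rng.normal(0, 0.1, 6))
        b = 80 * np.exp(rng.normal(0, 0.1, 6))
        assert sig_call(a, b) == SIG_LOWER
        assert sig_call(b, a) == SIG_HIGHER

    def test_zero_variance_equal_means_ns(self):
        assert sig_call(np.full(4, 5.0), np.full(4, 5.0)) == NS

    def test_power_at_8x_fold(self):
        """F1 = 8x reference with cv 0.05 and n=6 is detected nearly always."""

        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            ref = 30 * np.exp(rng.normal(0, 0.05, 6))
            f1 = 240 * np.exp(rng.normal(0, 0.05, 6))
            hits += sig_call(f1, ref) == SIG_HIGHER
        assert hits / 200 >= 0.99


class TestTriplet:
    def test_parent_label_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p1 = 10 * np.exp(rng.normal(0, 0.2, 5))
            p2 = 40 * np.exp(rng.normal(0, 0.2, 5))
            f1 = 25 * np.exp(rng.normal(0, 0.2, 5))
            m12, _ = classify_triplet(ExpressionTriplet("g", p1, p2, f1))
            m21, _ = classify_triplet(ExpressionTriplet("g", p2, p1, f1))
            assert m12 == m21

    def test_low_expression_floor(self):
        low = np.full(4, 0.1)
        mode, _ = classify_triplet(ExpressionTriplet("g", low, low, low))
        assert mode == "NC"

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTriplet("g", np.array([1.0]), np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_matrix_agrees_with_per_gene_path(self):
        frame, truth = simulate_expression(60, {"A": 0.5, "POD": 0.5}, seed=9)
        p1 = frame.iloc[:, :6].to_numpy()
        p2 = frame.iloc[:, 6:12].to_numpy()
        f1 = frame.iloc[:, 12:].to_numpy()
        vec = classify_matrix(p1, p2, f1)
        for i, gene in enumerate(frame.index):
            mode, _ = classify_triplet(ExpressionTriplet(gene, p1[i], p2[i], f1[i]))
            assert vec[i] == mode


class TestRecovery:
    def test_noise_free_recovery_is_exact(self):
        mix = {m: 1 / 7 for m in ("A", "PD", "ND", "PPD", "NPD", "POD", "NOD")}
        frame, truth = simulate_expression(140, mix, fold=4, n_reps=4, cv=0.0, seed=10)
        modes = classify_matrix(
            frame.iloc[:, :4].to_numpy(),
            frame.iloc[:, 4:8].to_numpy(),
            frame.iloc[:, 8:].to_numpy(),
        )
        truth_modes = [truth["modes"][g] for g in frame.index]
        assert modes == truth_modes

    def test_planted_mode_recovery_under_noise(self):
        """>= 90% of genes of each mode recovered at fold 4, 6 reps, 10% cv."""

        mix = {m: 1 / 7 for m in ("A", "PD", "ND", "PPD", "NPD", "POD", "NOD")}
        frame, truth = simulate_expression(700, mix, fold=4.0, n_reps=6, cv=0.1, seed=11)
        modes = classify_matrix(
            frame.iloc[:, :6].to_numpy(),
            frame.iloc[:, 6:12].to_numpy(),
            frame.iloc[:, 12:].to_numpy(),
        )
        per_mode = Counter()
        hits = Counter()
        for got, gene in zip(modes, frame.index):
            want = truth["modes"][gene]
            per_mode[want] += 1
            hits[want] += got == want
        for mode in mix:
            assert hits[mode] / per_mode[mode] >= 0.9, (mode, hits[mode], per_mode[mode])

    def test_false_overdominance_under_null(self):
        """All-equal parents and F1: POD+NOD calls stay below 2*alpha."""

        rng = np.random.default_rng(12)
        n = 2000
        base = np.exp(rng.uniform(np.log(10), np.log(200), size=n))[:, None]
        shape = (n, 6)
        p1 = base * np.exp(rng.normal(0, 0.1, shape))
        p2 = base * np.exp(rng.normal(0, 0.1, shape))
        f1 = base * np.exp(rng.normal(0, 0.1, shape))
        modes = classify_matrix(p1, p2, f1, alpha=0.05)
        rate = sum(m in ("POD", "NOD") for m in modes) / n
        assert rate <= 0.1


class TestRetention:
    def test_de_gene_retained_if_different_from_either_parent(self):
        rng = np.random.default_rng(13)
        shape = (3, 6)
        p1 = 20 * np.exp(rng.normal(0, 0.05, shape))
        p2 = 20 * np.exp(rng.normal(0, 0.05, shape))
        f1 = np.vstack(
            [
                160 * np.exp(rng.normal(0, 0.05, 6)),  # DE vs both
                20 * np.exp(rng.normal(0, 0.05, 6)),  # DE vs neither
                160 * np.exp(rng.normal(0, 0.05, 6)),  # DE vs both again
            ]
        )
        mask = retain_de_genes(p1, p2, f1)
        assert mask.tolist() == [True, False, True]

    def test_null_false_retention_bounded(self):
        frame, _ = simulate_expression(800, {"A": 1.0}, fold=1.0, n_reps=4, cv=0.1, seed=14)
        mask = retain_de_genes(
            frame.iloc[:, :4].to_numpy(),
            frame.iloc[:, 4:8].to_numpy(),
            frame.iloc[:, 8:].to_numpy(),
            alpha=0.05,
            min_fold=2.0,
        )
        # BH across the null plus the 2-fold requirement: retention is rare
        assert mask.mean() <= 0.05


class TestTabulate:
    def test_additive_fraction(self):
        modes = ["A"] * 25 + ["PD"] * 40 + ["POD"] * 35
        r = tabulate_modes(modes)
        assert r["additive_fraction"] == pytest.approx(0.25)

    def test_nc_reported_separately(self):
        r = tabulate_modes(["A", "NC", "NC", "POD"])
        assert r["n_nc"] == 2 and r["n_classified"] == 2

    def test_all_nc_no_fraction(self):
        r = tabulate_modes(["NC", "NC"])
        assert r["additive_fraction"] is None
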