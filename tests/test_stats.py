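"""Overlap statistics, log-space Fisher test, purity regression."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from intactrna.stats import (
    HomologMap,
    consensus_profiles,
    fisher_log,
    purity_regression,
    spirna_overlap,
)


def one_to_one_map(n, prefix_a="h", prefix_b="m"):
    return HomologMap((f"{prefix_a}{i}", f"{prefix_b}{i}") for i in range(n))


class TestOverlap:
    def test_direct_fraction(self):
        hm = one_to_one_map(10)
        res = spirna_overlap([f"h{i}" for i in range(5)], ["m0", "m1"], hm)
        assert res.fraction_a == pytest.approx(0.4)
        assert (res.a, res.b) == (2, 3)
        assert res.n_universe == 10

    def test_disjoint_sets(self):
        hm = one_to_one_map(10)
        res = spirna_overlap(["h0", "h1"], ["m5", "m6"], hm)
        assert res.fraction_a == 0.0
        assert res.log10_p == pytest.approx(0.0, abs=0.31)  # p ~ 1 for enrichment

    def test_one_to_many_asymmetry(self):
        """A one-to-many homolog makes the two directional fractions differ."""
        hm = HomologMap([("h0", "m0"), ("h0", "m1"), ("h1", "m2")])
        res = spirna_overlap(["h0"], ["m0", "m1"], hm)
        assert res.fraction_a == 1.0  # 1 of 1 A-genes overlaps
        assert res.fraction_b == 1.0  # both B genes covered by h0
        res2 = spirna_overlap(["h0", "h1"], ["m0"], hm)
        assert res2.fraction_a == pytest.approx(0.5)
        assert res2.fraction_b == 1.0

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            spirna_overlap(["a"], ["b"], HomologMap([]))

    def test_random_sets_match_set_oracle(self, rng):
        hm = one_to_one_map(200)
        for _ in range(20):
            a = {f"h{int(i)}" for i in rng.choice(200, size=40, replace=False)}
            b = {f"m{int(i)}" for i in rng.choice(200, size=60, replace=False)}
            res = spirna_overlap(a, b, hm)
            inter = {g for g in a if f"m{g[1:]}" in b}
            assert res.a == len(inter)
            assert res.fraction_a == pytest.approx(len(inter) / len(a))
            assert res.a + res.b + res.c + res.d == 200


def exact_fisher_enrichment(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    n = a + b + c + d
    row, col = a + b, a + c
    denom = math.comb(n, col)
    p = Fraction(0)
    for x in range(a, min(row, col) + 1):
        if col - x > n - row:
            continue
        p += Fraction(math.comb(row, x) * math.comb(n - row, col - x), denom)
    return p


class TestFisherLog:
    def test_closed_form_quarter_table(self):
        assert 10 ** fisher_log(2, 0, 0, 2) == pytest.approx(1 / 6)

    def test_maximal_depletion(self):
        assert fisher_log(0, 5, 5, 0) == pytest.approx(0.0)  # p = 1

    def test_negative_entry_error(self):
        with pytest.raises(ValueError):
            fisher_log(-1, 2, 3, 4)

    def test_exhaustive_small_tables(self):
        """All tables with n <= 12: <= 1e-10 relative error in log space."""
        for n in range(1, 13):
            for row in range(n + 1):
                for col in range(n + 1):
                    for a in range(max(0, row + col - n), min(row, col) + 1):
                        b, c = row - a, col - a
                        d = n - row - c
                        p = exact_fisher_enrichment(a, b, c, d)
                        got = fisher_log(a, b, c, d)
                        want = math.log10(p)
                        if want == 0.0:
                            assert got == pytest.approx(0.0, abs=1e-10)
                        else:
                            assert got == pytest.approx(want, rel=1e-10)

    def test_random_tables_margins_30(self, rng):
        for _ in range(500):
            row = int(rng.integers(1, 31))
            col = int(rng.integers(1, 31))
            n = int(rng.integers(max(row, col), 61))
            a = int(rng.integers(max(0, row + col - n), min(row, col) + 1))
            b, c, d = row - a, col - a, n - row - (col - a)
            p = exact_fisher_enrichment(a, b, c, d)
            got = fisher_log(a, b, c, d)
            want = math.log10(p)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_symmetry_under_row_and_column_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            assert fisher_log(a, b, c, d) == pytest.approx(fisher_log(d, c, b, a))

    def test_monotone_in_overlap_with_fixed_margins(self):
        """p decreases as the observed overlap grows, margins fixed."""
        row, col, n = 10, 12, 40
        ps = [
            fisher_log(a, row - a, col - a, n - row - col + a)
            for a in range(max(0, row + col - n), min(row, col) + 1)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_extreme_table_stays_finite(self):
        """Log-space survives p-values far below float underflow."""
        lp = fisher_log(562, 1323, 200, 15465)
        assert np.isfinite(lp) and lp < -300


def normal_equations_ols(x, y):
    """Independent least squares via the normal equations."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return beta, 1 - np.sum(resid**2) / tss


class TestPurityRegression:
    def make_sc(self, rng, n_cells=60, n_genes=40, n_clusters=4):
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(n_cells, n_genes)),
            index=[f"cell{i}" for i in range(n_cells)],
            columns=[f"g{i}" for i in range(n_genes)],
        )
        labels = [f"c{i % n_clusters}" for i in range(n_cells)]
        return counts, labels

    def test_cell_normalization_sums_to_one(self, rng):
        counts, labels = self.make_sc(rng)
        profiles = consensus_profiles(counts, labels)
        assert profiles.shape == (40, 4)
        norm = counts.div(counts.sum(axis=1), axis=0)
        assert np.allclose(norm.sum(axis=1), 1.0)

    def test_exact_mixture_recovered(self, rng):
        """Y built as an exact combination of two cluster profiles gives
        R^2 = 1 and recovers the mixing weights."""
        counts, labels = self.make_sc(rng)
        x = consensus_profiles(counts, labels)
        y = 0.7 * x["c0"] + 0.3 * x["c2"]
        res = purity_regression(counts, labels, y)
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["c0"] == pytest.approx(0.7, abs=1e-8)
        assert res.coefficients["c2"] == pytest.approx(0.3, abs=1e-8)
        assert res.coefficients["c1"] == pytest.approx(0.0, abs=1e-8)

    def test_permuted_bulk_near_zero(self, rng):
        """Independent Y: R^2 stays below 0.05 in 20 reseeded permutations."""
        counts, labels = self.make_sc(rng, n_cells=80, n_genes=300)
        x = consensus_profiles(counts, labels)
        y = 0.5 * x["c0"] + 0.5 * x["c1"]
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(len(y))
            y_perm = pd.Series(y.to_numpy()[perm], index=y.index)
            res = purity_regression(counts, labels, y_perm)
            assert res.r_squared < 0.05

    def test_scale_invariance_of_r_squared(self, rng):
        counts, labels = self.make_sc(rng)
        x = consensus_profiles(counts, labels)
        y = x["c0"] + 0.1 * pd.Series(rng.random(len(x)), index=x.index)
        r1 = purity_regression(counts, labels, y).r_squared
        r2 = purity_regression(counts, labels, 1000 * y).r_squared
        assert r1 == pytest.approx(r2)

    def test_matches_normal_equations_oracle(self, rng):
        counts, labels = self.make_sc(rng, n_cells=100, n_genes=120)
        x = consensus_profiles(counts, labels)
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        noise = 0.05 * rng.random(len(x)) * x.to_numpy().mean()
        y = pd.Series(x.to_numpy() @ weights + noise, index=x.index)
        res = purity_regression(counts, labels, y)
        design = np.column_stack([np.ones(len(x)), x.to_numpy()])
        beta, r2 = normal_equations_ols(design, y.to_numpy())
        assert res.coefficients.to_numpy() == pytest.approx(beta, abs=1e-8)
        assert res.r_squared == pytest.approx(r2)

    def test_rank_deficiency_flagged(self, rng):
        """Two clusters with identical consensus profiles are reported
        with the degeneracy flag (fit still returned)."""
        counts, labels = self.make_sc(rng, n_clusters=2)
        # third cluster = cell-for-cell copy of the first
        dup = counts[np.array(labels) == "c0"].copy()
        dup.index = [f"dup{i}" for i in range(len(dup))]
        counts2 = pd.concat([counts, dup])
        labels2 = labels + ["c_dup"] * len(dup)
        x = consensus_profiles(counts2, labels2)
        y = x["c0"]
        res = purity_regression(counts2, labels2, y)
        assert res.degenerate is True
        assert res.r_squared == pytest.approx(1.0)
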