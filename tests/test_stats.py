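"""Statistical layer: hypergeometric enrichment, Mann-Whitney, chi-square,
Bonferroni, ANCOVA marginal means, DE filtering, responsiveness."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromdiff.errors import UsageError
from chromdiff.stats import (
    ancova_emm,
    bonferroni,
    chisq_updown,
    de_filter,
    hypergeometric_enrichment,
    mann_whitney,
    responsiveness_by_category,
)


def enum_hypergeom_p(N, na, nb, k_obs):
    """Exact enumeration oracle: P[overlap >= k_obs]."""
    total = math.comb(N, nb)
    p = 0.0
    for k in range(k_obs, min(na, nb) + 1):
        p += math.comb(na, k) * math.comb(N - na, nb - k) / total
    return p


class TestHypergeometric:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(10, 14)}
        res = hypergeometric_enrichment(a, b, universe)
        assert res.n_overlap == 4
        assert res.expected == pytest.approx(2.0)
        assert res.fold == pytest.approx(2.0)
        assert res.p_value == pytest.approx(enum_hypergeom_p(20, 5, 8, 4))

    def test_maximal_overlap(self):
        universe = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(6)}
        res = hypergeometric_enrichment(a, a, universe)
        assert res.fold == pytest.approx(30 / 6)

    def test_disjoint_sets_fold_zero(self):
        universe = {f"g{i}" for i in range(10)}
        res = hypergeometric_enrichment({"g0"}, {"g5"}, universe)
        assert res.fold == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_enumeration_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 26))
        universe = {f"g{i}" for i in range(N)}
        a = set(rng.choice(sorted(universe), rng.integers(1, N // 2), replace=False))
        b = set(rng.choice(sorted(universe), rng.integers(1, N // 2), replace=False))
        res = hypergeometric_enrichment(a, b, universe)
        assert res.p_value == pytest.approx(
            enum_hypergeom_p(N, len(a), len(b), len(a & b))
        )

    def test_empty_set_rejected(self):
        with pytest.raises(UsageError):
            hypergeometric_enrichment(set(), {"g1"}, {"g1", "g2"})


def enum_mw_p(x, y):
    """Label-enumeration oracle for the exact two-sided p (tie-free)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in combinations(range(len(pooled)), n1)
    ]
    le = sum(u <= u_obs for u in us)
    ge = sum(u >= u_obs for u in us)
    return min(1.0, 2 * min(le, ge) / len(us))


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_near_one(self):
        rng = np.random.default_rng(40)
        x = rng.normal(size=200)
        _, p = mann_whitney(x, x)
        assert p == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        vals = rng.choice(1000, n1 + n2, replace=False).astype(float)
        x, y = vals[:n1], vals[n1:]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enum_mw_p(x, y))

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(41)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.5, 1, 90)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            mann_whitney([], [1.0])


class TestChisq:
    def test_hand_arithmetic(self):
        chi2, _ = chisq_updown(30, 10)
        assert chi2 == pytest.approx(10.0)

    def test_equal_split(self):
        chi2, p = chisq_updown(25, 25)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_generic_pearson(self):
        for up, down in [(7, 3), (100, 40), (1, 12)]:
            chi2, p = chisq_updown(up, down)
            ref = sps.chisquare([up, down])
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestBonferroni:
    def test_formula_cap_and_order(self):
        assert bonferroni([0.01], 6) == [pytest.approx(0.06)]
        assert bonferroni([0.5], 6) == [1.0]
        ps = [0.001, 0.01, 0.02]
        assert bonferroni(ps, 6) == sorted(bonferroni(ps, 6))
        with pytest.raises(UsageError):
            bonferroni([0.5], 0)


def balanced_design(cell_means, n_per_cell=10):
    expr, h, k = {}, {}, {}
    i = 0
    for (hv, kv), mu in cell_means.items():
        for _ in range(n_per_cell):
            g = f"g{i}"
            expr[g], h[g], k[g] = mu, bool(hv), bool(kv)
            i += 1
    return expr, h, k


class TestAncova:
    def test_balanced_additive_cells_give_exact_emms(self):
        expr, h, k = balanced_design({(0, 0): 2.0, (1, 0): 4.0, (0, 1): 1.0, (1, 1): 3.0})
        emms, contrasts = ancova_emm(expr, h, k)
        d = {(e.factor, e.level): e.emm for e in emms}
        assert d[("h2aub", "present")] == pytest.approx(3.5)
        assert d[("h2aub", "absent")] == pytest.approx(1.5)
        assert d[("k27", "present")] == pytest.approx(2.0)
        assert d[("k27", "absent")] == pytest.approx(3.0)
        assert len(contrasts) == 6
        assert (contrasts["p_adj"] >= contrasts["p_raw"] - 1e-12).all()

    def test_zero_k27_effect_reduces_to_group_means(self):
        rng = np.random.default_rng(42)
        expr, h, k = {}, {}, {}
        for i in range(200):
            g = f"g{i}"
            h[g] = bool(rng.integers(0, 2))
            k[g] = bool(rng.integers(0, 2))
            expr[g] = 5.0 + 2.0 * h[g] + rng.normal(0, 0.01)
        emms, _ = ancova_emm(expr, h, k)
        d = {(e.factor, e.level): e.emm for e in emms}
        mean_h1 = np.mean([expr[g] for g in expr if h[g]])
        mean_h0 = np.mean([expr[g] for g in expr if not h[g]])
        assert d[("h2aub", "present")] == pytest.approx(mean_h1, abs=0.02)
        assert d[("h2aub", "absent")] == pytest.approx(mean_h0, abs=0.02)

    def test_recovers_planted_factor_effects(self):
        rng = np.random.default_rng(43)
        d1, d2 = 3.0, 2.0
        expr, h, k = {}, {}, {}
        for i in range(400):
            g = f"g{i}"
            h[g] = bool(rng.integers(0, 2))
            k[g] = bool(rng.integers(0, 2))
            expr[g] = 10.0 + d1 * h[g] - d2 * k[g] + rng.normal(0, 1)
        emms, _ = ancova_emm(expr, h, k)
        d = {(e.factor, e.level): e.emm for e in emms}
        assert d[("h2aub", "present")] - d[("h2aub", "absent")] == pytest.approx(d1, abs=0.3)
        assert d[("k27", "present")] - d[("k27", "absent")] == pytest.approx(-d2, abs=0.3)

    def test_empty_cell_warns(self):
        expr, h, k = balanced_design({(0, 0): 2.0, (1, 0): 4.0, (0, 1): 1.0})
        with pytest.warns(UserWarning):
            ancova_emm(expr, h, k)


class TestDeFilter:
    def table(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "log2FC": [1.2, -0.5, -2.0, 5.0, 1.5],
                "p_adj": [0.01, 0.01, 0.001, 0.2, 0.03],
                "cpm_pass": [True, True, True, True, False],
            }
        )

    def test_thresholds(self):
        up, down = de_filter(self.table(), 1.0, 0.05)
        assert up == {"a"}  # d fails p, e fails cpm
        assert down == {"c"}

    def test_stricter_cutoff_is_subset(self):
        up1, down1 = de_filter(self.table(), 1.0, 0.05)
        up4, down4 = de_filter(self.table(), 4.0, 0.05)
        assert up4 <= up1 and down4 <= down1

    def test_up_down_disjoint(self):
        rng = np.random.default_rng(44)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "log2FC": rng.normal(0, 2, 500),
                "p_adj": rng.uniform(0, 1, 500),
            }
        )
        up, down = de_filter(df)
        assert not (up & down)


class TestResponsiveness:
    def make_table(self, n=120, seed=45):
        from chromdiff.marks import categorize

        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        h = {g: bool(rng.integers(0, 2)) for g in genes}
        k = {g: bool(rng.integers(0, 2)) for g in genes}
        return categorize(h, k), rng

    def test_all_equal_scores(self):
        table, _ = self.make_table()
        scores = {g: 3 for g in table.index}
        res = responsiveness_by_category(scores, table)
        assert set(res["medians"].values()) == {3.0}
        assert all(row["p_adj"] == 1.0 for row in res["pairwise"])

    def test_planted_h2aub_shift_detected(self):
        table, rng = self.make_table(n=300)
        scores = {
            g: int(rng.poisson(2)) + (4 if table.loc[g, "h2aub"] else 0)
            for g in table.index
        }
        res = responsiveness_by_category(scores, table)
        split = res["mark_split"]["h2aub"]
        assert split["median_present"] > split["median_absent"]
        assert split["p"] < 0.01
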