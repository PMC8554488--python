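"""Overlap tests, empirical p-values, sign consistency, DE and eQTL machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omicsforest.stats import (
    EmpiricalNull,
    associate_variants,
    bh_adjust,
    correlate_differentials,
    empirical_p,
    fisher_overlap,
    hypergeom_upper,
    permutation_de_null,
    sign_consistency_exact,
    sign_consistency_test,
    simple_de,
    subnet_overlap_null,
    variant_expression_fit,
)


def _enumerate_hypergeom_upper(k, K, n, N):
    """Exhaustive oracle: enumerate all C(N, n) draws."""
    universe = list(range(N))
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_worked_example_five_of_five(self):
        assert hypergeom_upper(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper(0, 5, 5, 10) == 1.0

    def test_matches_enumeration_for_small_backgrounds(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper(k, K, n, N) == pytest.approx(
                _enumerate_hypergeom_upper(k, K, n, N)
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(6, 5, 5, 10)


class TestFisher:
    def test_balanced_2x2_table(self):
        # margins (2,2)x(2,2) on N=4: P(overlap >= 1) = 5/6
        bg = {"a", "b", "c", "d"}
        res = fisher_overlap({"a", "b"}, {"a", "c"}, bg)
        assert res.p == pytest.approx(5 / 6)

    def test_full_overlap_of_background_is_trivial(self):
        bg = {"a", "b", "c"}
        assert fisher_overlap(bg, bg, bg).p == 1.0

    def test_disjoint_sets_are_depleted(self):
        bg = {f"g{i}" for i in range(40)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(10, 20)}
        assert fisher_overlap(a, b, bg).p > 0.95

    def test_requires_subsets_of_background(self):
        with pytest.raises(ValueError):
            fisher_overlap({"x"}, {"y"}, {"y"})


class TestEmpiricalP:
    def test_paper_convention_worked_example(self):
        null = EmpiricalNull(observed=10, null_values=[11] + [0] * 99)
        res = empirical_p(null, "paper")
        assert res["estimate"] == pytest.approx(0.01)
        assert res["bound"] == "<0.02"
        cons = empirical_p(null, "conservative")
        assert cons["estimate"] == pytest.approx(2 / 101)

    def test_conservative_never_below_one_over_r_plus_one(self):
        null = EmpiricalNull(observed=100, null_values=list(range(1000)))
        res = empirical_p(null, "conservative")
        assert res["estimate"] >= 1 / 1001
        none_exceed = EmpiricalNull(observed=1e9, null_values=list(range(1000)))
        assert empirical_p(none_exceed, "conservative")["estimate"] == pytest.approx(
            1 / 1001
        )

    def test_observed_below_all_null_gives_paper_estimate_one(self):
        null = EmpiricalNull(observed=-1, null_values=[0, 1, 2])
        assert empirical_p(null, "paper")["estimate"] == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalNull(observed=0, null_values=[])


class TestSignConsistency:
    def test_published_worked_example(self):
        p = sign_consistency_test(133, 40)
        assert p == pytest.approx(1.5e-12, rel=0.05)

    def test_balanced_counts_give_p_one(self):
        assert sign_consistency_test(10, 10) == pytest.approx(1.0)

    def test_z_formula_hand_value(self):
        # z = 10/sqrt(10) = 3.1623 -> p = 2*(1 - Phi(z))
        assert sign_consistency_test(30, 10) == pytest.approx(1.57e-3, rel=0.01)

    def test_normal_approximation_tracks_exact_binomial(self):
        for n_same, n_opp in [(40, 20), (70, 40), (133, 40), (300, 220)]:
            approx = sign_consistency_test(n_same, n_opp)
            exact = sign_consistency_exact(n_same, n_opp)
            assert approx / 3 <= exact <= approx * 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sign_consistency_test(0, 0)


class TestCorrelations:
    def test_affine_relation_is_perfect_pearson(self):
        x = {f"g{i}": float(i) for i in range(10)}
        y = {k: 2 * v + 1 for k, v in x.items()}
        assert correlate_differentials(x, y, "pearson")["r"] == pytest.approx(1.0)

    def test_monotone_transform_is_perfect_spearman(self):
        x = {f"g{i}": float(i) for i in range(10)}
        y = {k: v**3 + 5 for k, v in x.items()}
        assert correlate_differentials(x, y, "spearman")["r"] == pytest.approx(1.0)

    def test_independent_data_rarely_correlates(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = {f"g{i}": v for i, v in enumerate(rng.normal(size=1000))}
            y = {f"g{i}": v for i, v in enumerate(rng.normal(size=1000))}
            res = correlate_differentials(x, y)
            if abs(res["r"]) < 0.1 and res["p"] > 0.01:
                hits += 1
        assert hits >= 45

    def test_too_few_shared_ids_rejected(self):
        with pytest.raises(ValueError):
            correlate_differentials({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def _nb_counts(rng, mu, n_samples, dispersion=0.1):
    r = 1 / dispersion
    p = (r / (r + mu))[:, None]
    return rng.negative_binomial(r, np.broadcast_to(p, (mu.size, n_samples)))


class TestSimpleDE:
    def test_identical_groups_yield_no_calls(self):
        false_hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mu = np.full(400, 150.0)
            counts = pd.DataFrame(
                _nb_counts(rng, mu, 8), index=[f"g{i}" for i in range(400)]
            )
            res = simple_de(counts, ["A"] * 4 + ["B"] * 4)
            false_hits.append(res["is_de"].sum())
        assert np.mean(false_hits) < 5

    def test_power_on_large_planted_effect(self):
        rng = np.random.default_rng(1)
        mu = np.full(300, 200.0)
        a = _nb_counts(rng, mu, 6)
        mu_b = mu.copy()
        mu_b[:50] *= 2.0**3  # planted lfc = 3
        b = _nb_counts(rng, mu_b, 6)
        counts = pd.DataFrame(
            np.hstack([a, b]), index=[f"g{i}" for i in range(300)]
        )
        res = simple_de(counts, ["A"] * 6 + ["B"] * 6)
        power = res["is_de"][:50].mean()
        assert power >= 0.9

    def test_library_size_scaling_leaves_lfc_unchanged(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(50, 500, size=200)
        counts = pd.DataFrame(
            _nb_counts(rng, mu, 8), index=[f"g{i}" for i in range(200)]
        )
        labels = ["A"] * 4 + ["B"] * 4
        doubled = counts.copy()
        doubled.iloc[:, 4:] *= 2
        base = simple_de(counts, labels)["lfc"]
        scaled = simple_de(doubled, labels)["lfc"]
        assert np.allclose(base, scaled, atol=1e-2)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            simple_de(counts, ["A", "B", "B"])


class TestPermutationNull:
    def _planted(self, seed):
        rng = np.random.default_rng(seed)
        mu = np.full(150, 150.0)
        a = _nb_counts(rng, mu, 4)
        mu_b = mu.copy()
        mu_b[:30] *= 2.0**2
        b = _nb_counts(rng, mu_b, 4)
        return pd.DataFrame(
            np.hstack([a, b]), index=[f"g{i}" for i in range(150)]
        ), ["A"] * 4 + ["B"] * 4

    def test_planted_signal_is_extreme_against_null(self):
        counts, labels = self._planted(0)
        null = permutation_de_null(counts, labels, n_permutations=60, seed=1)
        res = empirical_p(null, "conservative")
        assert res["estimate"] <= 2 / 61

    def test_single_permutation_null_has_length_one(self):
        counts, labels = self._planted(3)
        null = permutation_de_null(counts, labels, n_permutations=1, seed=0)
        assert null.n_replicates == 1

    def test_subnet_overlap_null_construction(self):
        deg_lists = [{"a", "b"}, {"c"}, set()]
        null = subnet_overlap_null(deg_lists, {"a", "c", "z"}, {"a", "z"})
        assert list(null.null_values) == [1, 1, 0]
        assert null.observed == 2
        disjoint = subnet_overlap_null(deg_lists, {"q"}, {"q"})
        assert all(v == 0 for v in disjoint.null_values)


class TestVariantAssociation:
    def test_perfect_fit_has_unit_adjusted_r2(self):
        geno = np.array([0, 1, 2, 0, 1, 2, 1])
        slope, adj_r2, p = variant_expression_fit(2.0 * geno, geno)
        assert slope == pytest.approx(2.0)
        assert adj_r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_permuted_genotype_has_near_zero_r2(self):
        r2s = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            geno = rng.integers(0, 3, size=20)
            expr = 1.5 * geno + rng.normal(0, 0.5, size=20)
            perm = rng.permutation(geno)
            if np.ptp(perm) == 0:
                continue
            _, adj_r2, _ = variant_expression_fit(expr, perm)
            r2s.append(adj_r2)
        assert np.median(r2s) < 0.15

    def test_planted_eqtl_survives_bh_at_m_100(self):
        recovered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            genos = pd.DataFrame(
                rng.integers(0, 3, size=(100, 10)),
                index=[f"v{i}" for i in range(100)],
            )
            expr = pd.DataFrame(
                rng.normal(0, 0.5, size=(100, 10)),
                index=[f"g{i}" for i in range(100)],
            )
            expr.loc["g0"] += 1.5 * genos.loc["v0"]
            pairs = [(f"g{i}", f"v{i}") for i in range(100)]
            res = associate_variants(expr, genos, pairs, fdr=0.1)
            row = res[res.gene_id == "g0"].iloc[0]
            if row.q < 0.1:
                recovered += 1
        assert recovered >= 0.9 * n_seeds

    def test_constant_genotype_flagged_untestable(self):
        genos = pd.DataFrame([[1, 1, 1, 1]], index=["v0"])
        expr = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["g0"])
        res = associate_variants(expr, genos, [("g0", "v0")])
        assert not res.iloc[0].testable
        assert math.isnan(res.iloc[0].q)


class TestBH:
    def test_equal_p_values_stay_put(self):
        q = bh_adjust([0.05] * 10)
        assert np.allclose(q, 0.05)

    def test_hand_stepped_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
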