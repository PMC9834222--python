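import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseflow import stats

from conftest import folded_binomial_scores


def naive_bh(p):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def naive_midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    srt = values[order]
    while i < len(values):
        j = i
        while j < len(values) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def mwu_permutation_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = naive_midranks(pooled)
    observed = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    lo = (sums <= observed + 1e-9).mean()
    hi = (sums >= observed - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def naive_kw_h(groups):
    """Tie-corrected H from first principles with naive midranks."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = naive_midranks(pooled)
    h, offset = 0.0, 0
    for g in groups:
        h += ranks[offset : offset + len(g)].sum() ** 2 / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1.0 - (counts**3 - counts).sum() / (n**3 - n))


class TestNullProbability:
    def test_single_sample_median(self):
        df = pd.DataFrame({"sample_id": "A", "ase_score": [0.5, 0.7, 0.9]})
        assert stats.estimate_null_probability(df).p0 == pytest.approx(0.7)

    def test_median_of_three_sample_medians(self):
        frames = []
        for sid, med in (("A", 0.6), ("B", 0.647), ("C", 0.7)):
            frames.append(
                pd.DataFrame({"sample_id": sid, "ase_score": [med - 0.01, med, med + 0.01]})
            )
        null = stats.estimate_null_probability(pd.concat(frames))
        assert null.p0 == pytest.approx(0.647)
        assert null.per_sample_medians["B"] == pytest.approx(0.647)

    def test_matches_naive_two_pass_median(self):
        rng = np.random.default_rng(5)
        frames = [
            pd.DataFrame(
                {"sample_id": f"S{i}", "ase_score": folded_binomial_scores(rng, 40, 50, 0.5)}
            )
            for i in range(20)
        ]
        df = pd.concat(frames, ignore_index=True)
        null = stats.estimate_null_probability(df)

        def midpoint_median(values):
            v = sorted(values)
            n = len(v)
            return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2

        medians = [
            midpoint_median(df.loc[df["sample_id"] == f"S{i}", "ase_score"])
            for i in range(20)
        ]
        assert null.p0 == pytest.approx(midpoint_median(medians))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            stats.estimate_null_probability(pd.DataFrame(columns=["sample_id", "ase_score"]))


class TestBinomialAseTest:
    def test_fully_imbalanced_closed_form(self):
        assert stats.binomial_ase_test(10, 0, 0.647) == pytest.approx(0.647**10)
        assert stats.binomial_ase_test(0, 10, 0.647) == pytest.approx(0.647**10)

    def test_balanced_locus_is_never_significant(self):
        assert stats.binomial_ase_test(25, 25, 0.647) > 0.95

    def test_matches_brute_force_tail_sum(self):
        p0 = 0.647
        n, k = 20, 18
        expected = sum(
            math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
        )
        assert stats.binomial_ase_test(18, 2, p0) == pytest.approx(expected, rel=1e-12)

    def test_two_sided_doubles_the_tail_when_extreme(self):
        one = stats.binomial_ase_test(50, 2, 0.647)
        two = stats.binomial_ase_test(50, 2, 0.647, alternative="two-sided")
        assert two == pytest.approx(2 * one)

    def test_invalid_p0_raises(self):
        for p0 in (0.4, 1.0):
            with pytest.raises(ValueError):
                stats.binomial_ase_test(5, 5, p0)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        assert stats.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_tied_p(self):
        assert stats.adjust_bh([0.3]) == pytest.approx([0.3])
        assert stats.adjust_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    def test_matches_naive_definition_and_dominates_p(self, p):
        q = stats.adjust_bh(p)
        assert q == pytest.approx(naive_bh(p))
        assert np.all(q >= np.asarray(p) - 1e-15)
        # order preservation
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 40)
        perm = rng.permutation(40)
        assert stats.adjust_bh(p[perm]) == pytest.approx(stats.adjust_bh(p)[perm])


class TestGroupTests:
    def test_one_vs_rest_matches_exhaustive_permutations(self):
        groups = {"t": [0.9, 0.95, 0.99], "r": [0.5, 0.52, 0.55]}
        p = stats.group_test_one_vs_rest(groups, "t", min_per_side=3)
        assert p == pytest.approx(
            mwu_permutation_p(np.array(groups["t"]), np.array(groups["r"]))
        )
        assert p == pytest.approx(0.1)  # 2 * (1/C(6,3)) * ... enumerated

    def test_identical_multisets_give_p_one(self):
        groups = {"t": [0.6, 0.7, 0.8], "r": [0.8, 0.6, 0.7]}
        assert stats.group_test_one_vs_rest(groups, "t") == pytest.approx(1.0)

    def test_small_group_not_testable(self):
        groups = {"t": [0.6, 0.7], "r": [0.5, 0.6, 0.7]}
        assert np.isnan(stats.group_test_one_vs_rest(groups, "t", min_per_side=3))

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError):
            stats.group_test_one_vs_rest({"a": [1.0]}, "zzz")

    def test_omnibus_h_matches_naive_ranking(self):
        base = np.array([0.5, 0.6, 0.7])
        groups = {f"G{i}": base + 0.05 * i for i in range(4)}
        h = stats.kruskal_h(list(groups.values()))
        assert h == pytest.approx(naive_kw_h(list(groups.values())))
        from scipy import stats as sps

        p = stats.group_test_omnibus(groups, min_per_group=3)
        assert p == pytest.approx(float(sps.chi2.sf(h, df=3)))

    def test_omnibus_identical_groups_boundary(self):
        groups = {"a": [0.6, 0.6, 0.6], "b": [0.6, 0.6, 0.6]}
        assert stats.group_test_omnibus(groups) == pytest.approx(1.0)

    def test_omnibus_preconditions(self):
        assert np.isnan(stats.group_test_omnibus({"a": [0.5, 0.6, 0.7]}))
        assert np.isnan(
            stats.group_test_omnibus({"a": [0.5, 0.6, 0.7], "b": [0.5, 0.6]})
        )

    def test_compare_groups_table_shape_and_adjustment(self):
        rng = np.random.default_rng(4)
        rows = []
        for v, pos in (("rs1", 100), ("rs2", 200)):
            for i in range(16):
                rows.append(
                    {
                        "sample_id": f"S{i}",
                        "variant_id": v,
                        "contig": "1",
                        "position": pos,
                        "ase_score": rng.uniform(0.5, 1.0),
                    }
                )
        retained = pd.DataFrame(rows)
        metadata = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(16)],
             "group_label": [f"G{i % 4}" for i in range(16)],
             "genotyped": False}
        )
        out = stats.compare_groups(retained, metadata)
        assert len(out) == 2
        assert {"omnibus_p", "omnibus_q", "p_G0_vs_rest", "q_G0_vs_rest"} <= set(out.columns)
        testable = out["omnibus_p"].notna()
        assert out.loc[testable, "omnibus_q"].to_numpy() == pytest.approx(
            stats.adjust_bh(out.loc[testable, "omnibus_p"].to_numpy())
        )


class TestQQInflation:
    def test_null_uniform_lambda_near_one(self):
        rng = np.random.default_rng(8)
        table, lambdas = stats.qq_inflation(rng.uniform(size=10000), rng.uniform(size=5000))
        assert 0.95 <= lambdas["subset"] <= 1.05
        assert 0.95 <= lambdas["rest"] <= 1.05

    def test_equal_inputs_give_identical_curves(self):
        p = np.linspace(0.01, 0.99, 50)
        table, _ = stats.qq_inflation(p, p)
        sub = table[table["membership"] == "subset"].reset_index(drop=True)
        rest = table[table["membership"] == "rest"].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            sub.drop(columns="membership"), rest.drop(columns="membership")
        )

    def test_inflated_subset_curve_strictly_above(self):
        rest = np.linspace(0.05, 0.95, 40)
        table, lambdas = stats.qq_inflation(rest / 10, rest)
        sub = table[table["membership"] == "subset"]
        rst = table[table["membership"] == "rest"]
        assert np.all(
            sub["observed_neglog10"].to_numpy() > rst["observed_neglog10"].to_numpy()
        )
        assert lambdas["subset"] > lambdas["rest"]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            stats.qq_inflation([], [0.5])


class TestGeneSubsetHitRate:
    @staticmethod
    def table(qs, genes):
        return pd.DataFrame({"gene_id": genes, "best_q": qs})

    def test_all_rows_significant(self):
        t = self.table([0.01] * 4, ["a", "a", "b", "b"])
        assert stats.gene_subset_hit_rate(t, {"a"}) == (1.0, 1.0)

    def test_perfect_split(self):
        t = self.table([0.01, 0.01, 0.5, 0.9], ["a", "a", "b", "b"])
        assert stats.gene_subset_hit_rate(t, {"a"}) == (1.0, 0.0)

    def test_counting_oracle_on_random_table(self):
        rng = np.random.default_rng(3)
        genes = rng.choice([f"g{i}" for i in range(30)], size=300)
        qs = rng.uniform(size=300)
        t = self.table(qs, genes)
        subset = {f"g{i}" for i in range(10)}
        rate_in, rate_out = stats.gene_subset_hit_rate(t, subset, q_cutoff=0.3)
        hits_in = sum(1 for g, q in zip(genes, qs) if g in subset and q < 0.3)
        n_in = sum(1 for g in genes if g in subset)
        assert rate_in == pytest.approx(hits_in / n_in)
        hits_out = sum(1 for g, q in zip(genes, qs) if g not in subset and q < 0.3)
        assert rate_out == pytest.approx(hits_out / (300 - n_in))

    def test_empty_subset_flagged(self):
        t = self.table([0.01, 0.5], ["a", "b"])
        rate_in, rate_out = stats.gene_subset_hit_rate(t, set())
        assert np.isnan(rate_in)
        assert rate_out == pytest.approx(0.5)


class TestGeneSetOverlap:
    def test_matches_direct_tail_summation(self):
        background = {f"g{i}" for i in range(1000)}
        annotation = {f"g{i}" for i in range(100)}
        hit = {f"g{i}" for i in range(150)}  # overlap 100
        p, fold = stats.gene_set_overlap_test(hit, background, annotation)
        N, K, n, k = 1000, 100, 150, 100

        def hyper_pmf(j):
            return (
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
            )

        expected = sum(hyper_pmf(j) for j in range(k, min(K, n) + 1))
        assert p == pytest.approx(expected, rel=1e-9)
        assert fold == pytest.approx(k / (n * K / N))

    def test_disjoint_annotation(self):
        p, fold = stats.gene_set_overlap_test({"a"}, {"a", "b"}, {"zzz"})
        assert p == pytest.approx(1.0)

    def test_hit_must_be_subset_of_background(self):
        with pytest.raises(ValueError):
            stats.gene_set_overlap_test({"x"}, {"a", "b"}, {"a"})

    def test_null_draws_are_superuniform(self):
        # p-values of random hit sets should reject at or below nominal rate
        rng = np.random.default_rng(9)
        background = [f"g{i}" for i in range(300)]
        annotation = set(background[:60])
        ps = []
        for _ in range(400):
            hit = set(rng.choice(background, size=40, replace=False))
            p, _ = stats.gene_set_overlap_test(hit, background, annotation)
            ps.append(p)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.08
        assert (ps <= 0.2).mean() <= 0.25
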