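import numpy as np
import pandas as pd
import pytest

from pathconcord import (GeneSet, GeneSetCollection, GseaParams,
                         enrichment_score, gsea_fdr, gsea_preranked,
                         normalize_es, permutation_null, significant_sets)
from pathconcord.expression import RankedList

from oracles import brute_enrichment_score, brute_gsea_fdr


def ranked_from(scores):
    genes = [f"g{i + 1}" for i in range(len(scores))]
    return RankedList.from_unsorted(genes, scores)


def random_instance(r, max_n=20, max_s=6):
    n = int(r.integers(3, max_n + 1))
    scores = np.sort(r.standard_normal(n))[::-1]
    size = int(r.integers(1, min(max_s, n - 1) + 1))
    members = set(r.choice(n, size=size, replace=False))
    while all(scores[i] == 0 for i in members):
        members = set(r.choice(n, size=size, replace=False))
    return scores, members


class TestEnrichmentScore:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for w in (0.0, 1.0, 2.0):
            for _ in range(100):
                scores, members = random_instance(rng)
                rl = ranked_from(scores)
                flags = [i in members for i in range(len(scores))]
                gene_set = {rl.genes[i] for i in members}
                got = enrichment_score(rl, gene_set, w)
                exp_es, exp_run = brute_enrichment_score(list(scores), flags, w)
                assert got.es == pytest.approx(exp_es, abs=1e-12)
                assert np.allclose(got.running_sum, exp_run, atol=1e-12)

    def test_final_running_sum_is_zero(self, rng):
        for _ in range(50):
            scores, members = random_instance(rng)
            rl = ranked_from(scores)
            res = enrichment_score(rl, {rl.genes[i] for i in members})
            assert abs(res.running_sum[-1]) < 1e-9

    def test_invariant_to_positive_rescaling_at_w1(self, rng):
        scores, members = random_instance(rng)
        rl1 = ranked_from(scores)
        rl2 = ranked_from(scores * 7.3)
        gs = {rl1.genes[i] for i in members}
        assert enrichment_score(rl1, gs, 1.0).es == pytest.approx(
            enrichment_score(rl2, gs, 1.0).es, abs=1e-12)

    def test_w0_reduces_to_ks_statistic(self, rng):
        for _ in range(30):
            scores, members = random_instance(rng, max_n=40, max_s=10)
            rl = ranked_from(scores)
            res = enrichment_score(rl, {rl.genes[i] for i in members}, 0.0)
            n = len(scores)
            n_hit = len(members)
            # direct two-sample KS between member/non-member rank CDFs
            d_best = 0.0
            f_hit = f_miss = 0.0
            for i in range(n):
                if i in members:
                    f_hit += 1 / n_hit
                else:
                    f_miss += 1 / (n - n_hit)
                d_best = max(d_best, abs(f_hit - f_miss))
            assert abs(res.es) == pytest.approx(d_best, abs=1e-12)

    def test_entire_list_membership_is_error(self):
        rl = ranked_from(np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(rl, set(rl.genes))

    def test_all_zero_member_scores_is_error(self):
        rl = RankedList.from_unsorted(["a", "b", "c"], [1.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(rl, {"b"})


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        rl = ranked_from(np.linspace(3, -3, 50))
        params = GseaParams(n_permutations=100)
        a = permutation_null(rl, 5, params, np.random.default_rng(42))
        b = permutation_null(rl, 5, params, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_mean_near_zero_for_symmetric_scores(self):
        rl = ranked_from(np.linspace(2, -2, 101))
        params = GseaParams(n_permutations=2000)
        null = permutation_null(rl, 10, params, np.random.default_rng(0))
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se

    def test_boundary_size_n_minus_one(self):
        rl = ranked_from(np.linspace(1, -1, 20))
        params = GseaParams(n_permutations=50)
        null = permutation_null(rl, 19, params, np.random.default_rng(1))
        assert np.isfinite(null).all()
        assert (np.abs(null) <= 1.0 + 1e-12).all()


class TestNormalizeEs:
    def test_positive_side(self):
        assert normalize_es(0.6, np.array([0.2, 0.4])) == pytest.approx(2.0)

    def test_es_equal_to_null_mean_gives_one(self):
        assert normalize_es(0.3, np.array([0.2, 0.4])) == pytest.approx(1.0)

    def test_negative_side_keeps_sign(self):
        assert normalize_es(-0.5, np.array([-0.25])) == pytest.approx(-2.0)

    def test_no_same_sign_nulls_is_nan(self):
        assert np.isnan(normalize_es(0.5, np.array([-0.25, -0.5])))


class TestGseaFdr:
    def test_worked_example(self):
        q = gsea_fdr(np.array([2.0, -1.0]), np.array([1.0, -1.0, 0.5, -0.5]))
        assert q[0] == 0.0

    def test_null_identical_to_observed_gives_q_near_one(self):
        obs = np.array([1.5, 1.0, 0.5, -0.5, -1.0, -1.5])
        q = gsea_fdr(obs, obs.copy())
        # least extreme positive set: tail fractions agree -> q = 1
        assert q[2] == pytest.approx(1.0)

    def test_matches_bruteforce_double_counting(self, rng):
        for _ in range(25):
            obs = rng.standard_normal(int(rng.integers(3, 15))) * 1.5
            null = rng.standard_normal(60) * 1.2
            got = gsea_fdr(obs, null)
            exp = brute_gsea_fdr(list(obs), list(null))
            assert np.allclose(got, exp, atol=1e-12)

    def test_monotone_nonincreasing_in_abs_nes(self, rng):
        obs = rng.standard_normal(40) * 1.5
        null = rng.standard_normal(500)
        q = gsea_fdr(obs, null)
        for sign in (1, -1):
            side = sorted(
                [(abs(v), qi) for v, qi in zip(obs, q)
                 if (v >= 0) == (sign > 0)]
            )
            qs = [qi for _, qi in side]
            # ascending |NES| must give non-increasing q
            assert all(qs[i] >= qs[i + 1] - 1e-15 for i in range(len(qs) - 1))


class TestGseaPreranked:
    def _collection(self, rng, genes, n_sets=30, size=(15, 30)):
        sets = []
        for i in range(n_sets):
            k = int(rng.integers(size[0], size[1] + 1))
            sets.append(GeneSet(f"S{i:02d}", "", frozenset(
                rng.choice(genes, size=k, replace=False))))
        return GeneSetCollection(sets)

    def test_planted_top_set_is_extreme_with_q_zero(self, rng):
        genes = np.array([f"g{i:04d}" for i in range(1000)], dtype=object)
        scores = np.sort(rng.standard_normal(1000))[::-1]
        scores[:10] += 8.0  # strong head
        rl = RankedList.from_unsorted(genes, scores)
        coll = self._collection(rng, genes)
        planted = GeneSet("PLANTED", "", frozenset(rl.genes[:15]))
        coll = GeneSetCollection(list(coll) + [planted])
        table = gsea_preranked(rl, coll, GseaParams(seed=3))
        top = table.iloc[0]
        assert top["set"] == "PLANTED"
        assert top["nes"] == table["nes"].max()
        assert top["fdr_q"] == 0.0

    def test_deterministic_given_seed(self, rng):
        genes = np.array([f"g{i:03d}" for i in range(300)], dtype=object)
        rl = RankedList.from_unsorted(genes, rng.standard_normal(300))
        coll = self._collection(rng, genes, n_sets=20)
        params = GseaParams(seed=11, n_permutations=200)
        t1 = gsea_preranked(rl, coll, params)
        t2 = gsea_preranked(rl, coll, params)
        pd.testing.assert_frame_equal(t1, t2)

    def test_nominal_p_is_always_positive(self, rng):
        genes = np.array([f"g{i:03d}" for i in range(300)], dtype=object)
        rl = RankedList.from_unsorted(genes, rng.standard_normal(300))
        coll = self._collection(rng, genes, n_sets=20)
        table = gsea_preranked(rl, coll, GseaParams(seed=5, n_permutations=100))
        assert (table["nominal_p"] > 0).all()
        assert (table["nominal_p"] <= 1).all()

    def test_empty_filtered_collection_is_error(self, rng):
        genes = np.array([f"g{i}" for i in range(100)], dtype=object)
        rl = RankedList.from_unsorted(genes, rng.standard_normal(100))
        coll = GeneSetCollection([GeneSet("TINY", "", frozenset(genes[:5]))])
        with pytest.raises(ValueError, match="size filtering"):
            gsea_preranked(rl, coll, GseaParams())

    def test_significant_sets_split_by_direction(self):
        table = pd.DataFrame({
            "set": ["A", "B", "C"],
            "direction": ["up", "down", "up"],
            "fdr_q": [0.01, 0.02, 0.5],
        })
        out = significant_sets(table, 0.05)
        assert out == {"up": ["A"], "down": ["B"]}
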