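import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pathconcord import (GeneSet, GeneSetCollection, assign_snps_to_genes,
                         bh_fdr, build_gene_scores, classify_genes,
                         combine_cohorts, gene_level_p, pathway_enrichment,
                         read_gene_regions, read_snp_stats, run_gwas_arm)
from pathconcord.simulate import SimConfig, make_gwas_cohort, make_study

from oracles import (brute_assign, brute_bh, brute_fisher_even_df,
                     brute_hypergeom_upper_tail)


class TestSnpStatsIO:
    def test_valid_row_parsed(self, tmp_path):
        p = tmp_path / "a.assoc"
        p.write_text("SNP\tCHR\tBP\tP\nrs1\t1\t1000\t0.01\n")
        df = read_snp_stats(p)
        assert len(df) == 1
        assert df.loc[0, "p"] == 0.01

    def test_p_zero_rejected(self, tmp_path):
        p = tmp_path / "a.assoc"
        p.write_text("SNP\tCHR\tBP\tP\nrs1\t1\t1000\t0\nrs2\t1\t2000\t0.5\n")
        df = read_snp_stats(p)
        assert list(df["snp"]) == ["rs2"]

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "a.assoc"
        p.write_text("SNP\tCHR\tBP\nrs1\t1\t1000\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_snp_stats(p)

    def test_generated_file_row_count(self, tmp_path, rng):
        rows = ["SNP\tCHR\tBP\tP"]
        valid = 0
        for i in range(1000):
            p = rng.choice([rng.random(), 0.0, 1.5])
            if 0 < p <= 1:
                valid += 1
            rows.append(f"rs{i}\t1\t{i + 1}\t{p}")
        f = tmp_path / "big.assoc"
        f.write_text("\n".join(rows) + "\n")
        assert len(read_snp_stats(f)) == valid


class TestRegionsIO:
    def test_bed_converted_to_one_based(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t999\t2000\tGENE1\n")
        df = read_gene_regions(p)
        assert df.loc[0, "start"] == 1000
        assert df.loc[0, "end"] == 2000


class TestAssignment:
    def _regions(self):
        return pd.DataFrame(
            [("G1", "1", 200000, 210000)],
            columns=["gene", "chrom", "start", "end"],
        )

    def _snps(self, positions):
        return pd.DataFrame(
            [(f"rs{i}", "1", pos, 0.5) for i, pos in enumerate(positions)],
            columns=["snp", "chrom", "pos", "p"],
        )

    def test_inclusive_flank_boundary(self):
        out = assign_snps_to_genes(self._snps([100000]), self._regions(), 100000)
        assert "G1" in out

    def test_just_outside_flank_not_assigned(self):
        out = assign_snps_to_genes(self._snps([99999]), self._regions(), 100000)
        assert out == {}

    def test_matches_bruteforce_double_loop(self, rng):
        regions = pd.DataFrame(
            [(f"G{i}", str(rng.integers(1, 4)), int(s), int(s) + 5000)
             for i, s in enumerate(rng.integers(1, 500000, size=30))],
            columns=["gene", "chrom", "start", "end"],
        )
        snps = pd.DataFrame(
            [(f"rs{i}", str(rng.integers(1, 4)), int(p), float(rng.random()))
             for i, p in enumerate(rng.integers(1, 600000, size=200))],
            columns=["snp", "chrom", "pos", "p"],
        )
        got = assign_snps_to_genes(snps, regions, 20000)
        exp = brute_assign(
            list(snps.itertuples(index=False)),
            list(regions.itertuples(index=False)),
            20000,
        )
        assert set(got) == set(exp)
        for gene in exp:
            assert sorted(got[gene]) == sorted(exp[gene])


class TestGeneScores:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.001, 0.2, 0.5], 0.003), ([0.5], 0.5), ([0.6, 0.9], 1.0)],
    )
    def test_min_p_bonferroni(self, ps, expected):
        assert gene_level_p(ps) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gene_level_p([])

    def test_monotone_in_snp_count(self, rng):
        base = [0.01]
        prev = gene_level_p(base)
        for extra in range(1, 10):
            cur = gene_level_p(base + [0.9] * extra)
            assert cur >= prev
            prev = cur

    def test_classification_boundary_inclusive(self):
        scores = build_gene_scores({"A": [0.05], "B": [1.0]}, alpha=0.05)
        sig, non = classify_genes(scores, alpha=0.05)
        assert sig == {"A"} and non == {"B"}

    def test_all_adj_p_one_gives_empty_significant(self):
        scores = build_gene_scores({"A": [1.0], "B": [0.9, 0.9]}, alpha=0.05)
        sig, non = classify_genes(scores)
        assert sig == set()
        assert len(sig) + len(non) == 2


class TestPathwayEnrichment:
    def test_worked_case(self):
        coll = GeneSetCollection([GeneSet("S", "", frozenset("abcd"))])
        out = pathway_enrichment(set("abcde"), set("abcdefghij"), coll)
        assert out.loc[0, "p_hyper"] == pytest.approx(5 / 210, abs=1e-12)

    def test_k_zero_gives_p_one(self):
        coll = GeneSetCollection([GeneSet("S", "", frozenset("ab"))])
        out = pathway_enrichment({"x"}, set("abxy"), coll)
        assert out.loc[0, "p_hyper"] == 1.0

    def test_no_significant_genes_warns_all_one(self, caplog):
        coll = GeneSetCollection([GeneSet("S", "", frozenset("ab"))])
        import logging
        with caplog.at_level(logging.WARNING, logger="pathconcord.gwas"):
            out = pathway_enrichment(set(), set("abxy"), coll)
        assert (out["p_hyper"] == 1.0).all()
        assert any("no significant genes" in r.message for r in caplog.records)

    def test_tail_matches_enumeration(self, rng):
        from pathconcord.gwas import _hypergeom_sf
        for _ in range(200):
            n_univ = int(rng.integers(2, 61))
            n_set = int(rng.integers(1, n_univ + 1))
            n_draw = int(rng.integers(0, n_univ + 1))
            k = int(rng.integers(0, min(n_set, n_draw) + 1))
            exp = brute_hypergeom_upper_tail(k, n_univ, n_set, n_draw)
            assert _hypergeom_sf(k, n_univ, n_set, n_draw) == pytest.approx(
                exp, abs=1e-12)

    def test_tail_monotone_in_k(self):
        from pathconcord.gwas import _hypergeom_sf
        vals = [_hypergeom_sf(k, 40, 10, 12) for k in range(11)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCombineCohorts:
    def test_single_cohort_identity(self):
        assert combine_cohorts([0.03]) == 0.03

    def test_all_ones_give_one(self):
        assert combine_cohorts([1.0, 1.0]) == pytest.approx(1.0)

    def test_fisher_closed_form(self):
        got = combine_cohorts([0.05, 0.05])
        assert got == pytest.approx(brute_fisher_even_df([0.05, 0.05]), rel=1e-10)
        assert got == pytest.approx(0.0174, abs=2e-4)

    def test_duplicated_small_p_becomes_smaller(self):
        for p in (0.01, 0.05, 0.1, 0.2):
            assert combine_cohorts([p, p]) < p

    def test_zero_p_is_error(self):
        with pytest.raises(ValueError):
            combine_cohorts([0.0, 0.5])

    def test_stouffer_agrees_in_direction(self):
        assert combine_cohorts([0.01, 0.01], method="stouffer") < 0.01


class TestBhFdr:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.2], [0.2]),
        ],
    )
    def test_worked_examples(self, ps, expected):
        assert np.allclose(bh_fdr(ps), expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_and_permutation_invariant(self, ps):
        got = bh_fdr(ps)
        assert np.allclose(got, brute_bh(ps), atol=1e-12)
        perm = list(reversed(range(len(ps))))
        permuted = bh_fdr([ps[i] for i in perm])
        assert np.allclose([got[i] for i in perm], permuted, atol=1e-12)


class TestGwasArm:
    def test_planted_pathway_attains_minimal_meta_p(self):
        config = SimConfig(seed=5, n_genes=400, n_sets=50,
                           set_size_range=(10, 30), n_cohorts=1,
                           n_expression_datasets=0, n_planted_up=0,
                           n_planted_down=0, n_planted_gwas=1,
                           causal_gene_fraction=1.0, causal_beta_a=0.02)
        bundle = make_study(config)
        result = run_gwas_arm(bundle.cohorts, bundle.collection)
        planted = bundle.truth.planted_gwas[0]
        assert result.meta.loc[0, "set"] == planted
        assert result.meta["meta_p"].min() == result.meta.loc[0, "meta_p"]

    def test_duplicate_cohort_strengthens_enriched_sets(self):
        config = SimConfig(seed=6, n_genes=400, n_sets=50,
                           set_size_range=(10, 30), n_cohorts=1,
                           n_expression_datasets=0, n_planted_up=0,
                           n_planted_down=0, n_planted_gwas=2)
        bundle = make_study(config)
        (snps, regions), = bundle.cohorts.values()
        single = run_gwas_arm({"c1": (snps, regions)}, bundle.collection)
        double = run_gwas_arm(
            {"c1": (snps, regions), "c2": (snps, regions)}, bundle.collection)
        s = single.meta.set_index("set")["meta_p"]
        d = double.meta.set_index("set")["meta_p"]
        for name in bundle.truth.planted_gwas:
            assert d[name] <= s[name]

    def test_type_one_error_roughly_nominal_per_cohort(self):
        config = SimConfig(seed=7, n_expression_datasets=0, n_cohorts=1,
                           causal_gene_fraction=0.0)
        bundle = make_study(config)
        result = run_gwas_arm(bundle.cohorts, bundle.collection)
        enr = result.per_cohort["cohort1"]
        frac = (enr["p_hyper"] < 0.05).mean()
        assert frac < 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(enr))
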