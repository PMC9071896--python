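import numpy as np
import pandas as pd
import pytest

from tmescore import simulate
from tmescore.mutsig import (
    CONTEXT_CATEGORIES,
    build_context_catalog,
    compare_gene_mutation_rates,
    compute_tmb,
    context_category,
    cosine_matrix,
    extract_signatures,
    greedy_match,
    match_signatures,
    select_rank,
    summarize_maf,
)

from oracles import cosine_brute, fisher_enumeration


def _mut(sample, gene, ref, alt, ctx, var_type="SNP",
         var_class="Missense_Mutation", pos=1):
    return {
        "sample_id": sample, "gene": gene, "chrom": "1", "pos": pos,
        "ref": ref, "alt": alt, "var_class": var_class,
        "var_type": var_type, "ref_context": ctx,
    }


@pytest.fixture
def toy_maf():
    return pd.DataFrame([
        _mut("s1", "TP53", "C", "T", "ACA", pos=10),
        _mut("s1", "PIK3CA", "G", "A", "AGA", pos=20),
        _mut("s2", "TP53", "T", "A", "CTG", pos=30),
        _mut("s2", "KRAS", "A", "-", None, var_type="DEL",
             var_class="Frame_Shift_Del", pos=40),
    ])


class TestContextCategories:
    def test_exactly_96_ordered_categories(self):
        assert len(CONTEXT_CATEGORIES) == 96
        assert len(set(CONTEXT_CATEGORIES)) == 96
        assert CONTEXT_CATEGORIES[0] == "A[C>A]A"
        assert CONTEXT_CATEGORIES[1] == "A[C>A]C"
        assert CONTEXT_CATEGORIES[4] == "C[C>A]A"
        assert CONTEXT_CATEGORIES[16] == "A[C>G]A"
        assert CONTEXT_CATEGORIES[-1] == "T[T>G]T"
        # 6 substitution classes x 4 x 4 flanks
        subs = {c[2:5] for c in CONTEXT_CATEGORIES}
        assert subs == {"C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}

    def test_purine_strand_is_reverse_complemented(self):
        assert context_category("G", "T", "AGC") == "G[C>A]T"

    def test_pyrimidine_strand_unchanged(self):
        assert context_category("C", "T", "ACA") == "A[C>T]A"

    def test_strand_collapse_idempotent(self):
        cat = context_category("C", "T", "ACA")
        five, mid, three = cat[0], cat[2:5], cat[6]
        again = context_category(mid[0], mid[2], five + mid[0] + three)
        assert again == cat

    def test_ambiguous_base_returns_none(self):
        assert context_category("C", "T", "NCA") is None


class TestSummaries:
    def test_toy_counts_with_strand_collapse(self, toy_maf):
        s = summarize_maf(toy_maf)
        assert s.by_variant_type["SNP"] == 3
        assert s.by_variant_type["DEL"] == 1
        assert s.by_snv_class["C>T"] == 2  # C>T plus collapsed G>A
        assert s.by_snv_class["T>A"] == 1

    def test_singleton_sample_count(self):
        maf = pd.DataFrame([_mut("only", "G1", "C", "T", "ACA")])
        s = summarize_maf(maf)
        assert s.per_sample_counts.to_dict() == {"only": 1}

    def test_gene_ranking_by_fraction_of_samples(self):
        maf = pd.DataFrame([
            _mut("s1", "GA", "C", "T", "ACA", pos=1),
            _mut("s2", "GA", "C", "T", "ACA", pos=2),
            _mut("s3", "GB", "C", "T", "ACA", pos=3),
        ])
        s = summarize_maf(maf)
        assert s.top_genes.index[0] == "GA"
        assert s.top_genes["GA"] == pytest.approx(2 / 3)

    def test_tmb_counts_and_median_split(self):
        rows = []
        for i, n in enumerate([1, 2, 3, 4]):
            for j in range(n):
                rows.append(_mut(f"s{i}", "G", "C", "T", "ACA", pos=10 * i + j))
        tmb = compute_tmb(pd.DataFrame(rows))
        t = tmb.set_index("sample_id")
        assert t.loc["s3", "tmb"] == 4
        assert set(t.index[t["group"] == "high"]) == {"s2", "s3"}

    def test_tmb_roster_zero_goes_low(self):
        maf = pd.DataFrame([_mut("s1", "G", "C", "T", "ACA")] * 10)
        maf["pos"] = range(1, 11)
        tmb = compute_tmb(maf, roster=["s1", "s2"])
        t = tmb.set_index("sample_id")
        assert t.loc["s1", "tmb"] == 10
        assert t.loc["s2", "tmb"] == 0 and t.loc["s2", "group"] == "low"


class TestCatalog:
    def test_toy_catalog_ignores_non_snp(self, toy_maf):
        cat = build_context_catalog(toy_maf)
        assert cat.counts["s2"].sum() == 1  # the DEL is ignored
        assert cat.counts["s1"].sum() == 2
        assert cat.counts.loc["A[C>T]A", "s1"] == 1
        assert cat.counts.loc["T[C>T]T", "s1"] == 1  # G>A in AGA collapsed

    def test_column_sums_match_snp_counts_minus_skipped(self):
        sigs = simulate.random_signatures(2, seed=4)
        maf, _ = simulate.simulate_maf(10, sigs, tmb_mean=30, seed=4,
                                       other_class_frac=0.2)
        cat = build_context_catalog(maf)
        snp_counts = maf[maf["var_type"] == "SNP"].groupby("sample_id").size()
        assert (cat.counts.sum(axis=0).sort_index()
                == snp_counts.sort_index() - 0).all()
        assert cat.n_skipped == 0

    def test_ambiguous_contexts_skipped_and_counted(self, toy_maf):
        maf = toy_maf.copy()
        maf.loc[0, "ref_context"] = "NCA"
        cat = build_context_catalog(maf)
        assert cat.n_skipped == 1
        assert cat.counts["s1"].sum() == 1

    def test_missing_context_without_fasta_is_error(self, toy_maf):
        maf = toy_maf.copy()
        maf.loc[0, "ref_context"] = None
        with pytest.raises(ValueError, match="lacks ref_context"):
            build_context_catalog(maf)

    def test_context_column_and_fasta_agree(self, tmp_path):
        # hand genome: categories derived from the column match FASTA flanks
        genome = "TTACATTGCATT"
        (tmp_path / "ref.fa").write_text(">chr1\n" + genome + "\n")
        maf = pd.DataFrame([
            {**_mut("s1", "G1", "C", "T", "ACA", pos=4), "chrom": "chr1"},
            {**_mut("s1", "G2", "G", "A", "TGC", pos=8), "chrom": "chr1"},
        ])
        with_col = build_context_catalog(maf)
        maf_nocol = maf.copy()
        maf_nocol["ref_context"] = None
        from_fasta = build_context_catalog(maf_nocol, fasta=tmp_path / "ref.fa")
        pd.testing.assert_frame_equal(with_col.counts, from_fasta.counts)


class TestNMF:
    def test_rank_one_closed_form_is_row_profile(self):
        sigs = simulate.random_signatures(2, seed=5)
        maf, _ = simulate.simulate_maf(20, sigs, tmb_mean=100, seed=5)
        cat = build_context_catalog(maf)
        dec = extract_signatures(cat, rank=1, n_restarts=3, seed=5)
        profile = cat.counts.sum(axis=1).to_numpy(dtype=float)
        profile /= profile.sum()
        assert np.abs(dec.signatures.iloc[:, 0].to_numpy() - profile).max() < 1e-6

    def test_divergence_non_increasing(self):
        sigs = simulate.random_signatures(3, seed=6)
        maf, _ = simulate.simulate_maf(30, sigs, tmb_mean=100, seed=6)
        cat = build_context_catalog(maf)
        dec = extract_signatures(cat, rank=3, n_restarts=1, seed=6)
        assert (np.diff(dec.divergence_history) <= 1e-8).all()

    def test_noise_free_orthogonal_recovery(self):
        # integer catalog built exactly from two disjoint-support signatures
        s1 = np.zeros(96); s1[:8] = 1 / 8
        s2 = np.zeros(96); s2[50:60] = 1 / 10
        S = np.column_stack([s1, s2])
        E = np.array([[400, 0], [0, 400], [200, 200], [320, 80]]).T
        V = (S * 1.0) @ E  # exact integer counts by construction
        counts = pd.DataFrame(V, index=list(CONTEXT_CATEGORIES),
                              columns=[f"s{i}" for i in range(4)])
        dec = extract_signatures(counts, rank=2, n_restarts=10, seed=7)
        pairs = greedy_match(dec.signatures.to_numpy(), S)
        assert all(c >= 0.99 for _, _, c in pairs)

    def test_planted_three_signature_recovery(self):
        sigs = simulate.random_signatures(3, seed=7)
        maf, _ = simulate.simulate_maf(100, sigs, tmb_mean=200, seed=7)
        cat = build_context_catalog(maf)
        dec = extract_signatures(cat, rank=3, n_restarts=10, seed=7)
        pairs = greedy_match(dec.signatures.to_numpy(), sigs.to_numpy())
        assert all(c >= 0.9 for _, _, c in pairs)

    def test_signatures_are_column_stochastic(self):
        sigs = simulate.random_signatures(2, seed=8)
        maf, _ = simulate.simulate_maf(20, sigs, tmb_mean=50, seed=8)
        dec = extract_signatures(build_context_catalog(maf), rank=2,
                                 n_restarts=3, seed=8)
        assert np.allclose(dec.signatures.sum(axis=0), 1.0, atol=1e-9)
        assert (dec.exposures.to_numpy() >= 0).all()

    def test_all_zero_catalog_errors(self):
        counts = pd.DataFrame(np.zeros((96, 3)),
                              index=list(CONTEXT_CATEGORIES))
        with pytest.raises(ValueError, match="all-zero"):
            extract_signatures(counts, rank=1)

    def test_rank_scan_recovers_planted_rank(self):
        sigs = simulate.random_signatures(3, seed=9)
        maf, _ = simulate.simulate_maf(100, sigs, tmb_mean=200, seed=9)
        scan = select_rank(build_context_catalog(maf), ranks=range(1, 7),
                           n_restarts=10, seed=9)
        assert scan.selected_rank == 3


class TestMatching:
    def test_identity_match(self):
        sigs = simulate.random_signatures(3, seed=10)
        dec_like = sigs.copy()
        table, best = match_signatures(dec_like, sigs)
        for i, name in enumerate(sigs.columns):
            assert table.iloc[i, i] == pytest.approx(1.0)
            assert best.iloc[i] == name

    def test_disjoint_support_is_orthogonal(self):
        a = np.zeros((96, 1)); a[:10] = 0.1
        b = np.zeros((96, 1)); b[20:30] = 0.1
        assert cosine_matrix(a, b)[0, 0] == 0.0

    def test_cosine_matches_brute_force(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(size=(3, 4))
        B = rng.uniform(size=(3, 5))
        sim = cosine_matrix(A, B)
        for i in range(4):
            for j in range(5):
                assert sim[i, j] == pytest.approx(
                    cosine_brute(A[:, i], B[:, j]), abs=1e-12
                )

    def test_wrong_reference_shape_errors(self):
        sigs = simulate.random_signatures(2, seed=12)
        with pytest.raises(ValueError, match="96"):
            match_signatures(sigs, sigs.iloc[:50])


class TestGeneRates:
    def _maf_with_rates(self, n_high, n_low, k_high, k_low, gene="G1"):
        rows = []
        for i in range(k_high):
            rows.append(_mut(f"h{i}", gene, "C", "T", "ACA", pos=i + 1))
        for i in range(k_low):
            rows.append(_mut(f"l{i}", gene, "C", "T", "ACA", pos=100 + i))
        groups = pd.Series(
            ["high"] * n_high + ["low"] * n_low,
            index=[f"h{i}" for i in range(n_high)]
            + [f"l{i}" for i in range(n_low)],
        )
        return pd.DataFrame(rows), groups

    def test_hand_case_against_enumeration(self):
        maf, groups = self._maf_with_rates(10, 10, 8, 1)
        out = compare_gene_mutation_rates(maf, groups, min_mutated=5)
        expected = fisher_enumeration(8, 2, 1, 9)
        assert out.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)
        assert out.iloc[0]["p_value"] == pytest.approx(0.005477, abs=5e-7)

    def test_identical_patterns_are_null(self):
        maf, groups = self._maf_with_rates(10, 10, 5, 5)
        out = compare_gene_mutation_rates(maf, groups)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_min_mutated_filter_skips_rare_genes(self):
        maf, groups = self._maf_with_rates(10, 10, 2, 0)
        out = compare_gene_mutation_rates(maf, groups, min_mutated=5)
        assert len(out) == 0
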