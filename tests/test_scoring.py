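import numpy as np
import pandas as pd
import pytest

from tmescore import simulate
from tmescore.scoring import (
    GeneSignatureSets,
    cluster_marker_genes,
    compute_tmescore,
    cox_sign_split,
    prune_redundant,
    validate_score,
)

from oracles import logrank_chi2


def _sets(x=(), y=()):
    genes = list(x) + list(y)
    return GeneSignatureSets(
        set_X=list(x),
        set_Y=list(y),
        coefficients=pd.Series({g: -1.0 if g in x else 1.0 for g in genes}),
        wald_p=pd.Series({g: 0.01 for g in genes}),
    )


class TestClusterMarkers:
    def test_planted_markers_detected_null_controlled(self, planted_cohort):
        expr, _, truth = planted_cohort
        markers = cluster_marker_genes(expr, truth.true_cluster)
        passed = set(markers.loc[markers["passes_filter"], "feature_id"])
        planted = {g for g in expr.index if g.startswith("MRK")}
        noise = {g for g in expr.index if g.startswith("NSE")}
        assert len(planted & passed) / len(planted) >= 0.95
        assert len(noise & passed) / len(noise) <= 0.01

    def test_exact_fold_change_boundary_fails_strict_filter(self):
        rng = np.random.default_rng(0)
        n = 4  # power of two so the group means are float-exact
        labels = pd.Series([1] * n + [2] * n,
                           index=[f"s{i}" for i in range(2 * n)])
        # group 1 at expr 0.5, group 2 at 0: log2 fold change exactly log2(1.5)
        vals = np.array([0.5] * n + [0.0] * n)
        other = 2.0 ** rng.normal(5, 0.1, size=2 * n) - 1.0
        expr = pd.DataFrame([vals, other], index=["boundary", "filler"],
                            columns=labels.index)
        res = cluster_marker_genes(expr, labels)
        row = res[(res["feature_id"] == "boundary")
                  & (res["contrast"] == "cluster1_vs_rest")].iloc[0]
        assert row["log2fc"] == pytest.approx(np.log2(1.5), abs=1e-9)
        assert not row["passes_filter"]

    def test_null_gene_has_zero_fold_change(self):
        labels = pd.Series([1] * 10 + [2] * 10,
                           index=[f"s{i}" for i in range(20)])
        v = np.tile([1.0, 3.0], 10)
        expr = pd.DataFrame([v, v[::-1]], index=["g1", "g2"],
                            columns=labels.index)
        res = cluster_marker_genes(expr, labels)
        g1 = res[(res["feature_id"] == "g1")
                 & (res["contrast"] == "cluster1_vs_rest")].iloc[0]
        assert g1["log2fc"] == pytest.approx(0.0)
        assert not g1["passes_filter"]

    def test_zero_variance_gene_excluded(self, planted_cohort):
        expr, _, truth = planted_cohort
        expr = expr.copy()
        expr.loc["FLAT"] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_marker_genes(expr, truth.true_cluster)
        assert "FLAT" not in set(res["feature_id"])


class TestPruneRedundant:
    def test_informative_genes_survive_noise(self, signature):
        expr, _, truth = simulate.simulate_cohort(
            120, 55, 3, signature, de_effect_log2fc=2.0, noise_sd=0.3, seed=2
        )
        # markers spanning all three clusters so the label is learnable
        informative = ["MRK1_001", "MRK1_002", "MRK2_001", "MRK2_002",
                       "MRK3_001"]
        noise = [g for g in expr.index if g.startswith("NSE")][:50]
        kept = prune_redundant(expr, truth.true_cluster, informative + noise,
                               n_trees=200, seed=2)
        assert set(informative) <= set(kept)
        assert len(set(noise) & set(kept)) <= 5

    def test_duplicated_informative_gene_keeps_a_copy(self, planted_cohort):
        expr, _, truth = planted_cohort
        expr = expr.copy()
        marker = next(g for g in expr.index if g.startswith("MRK"))
        expr.loc["DUP_" + marker] = expr.loc[marker]
        noise = [g for g in expr.index if g.startswith("NSE")][:20]
        kept = prune_redundant(expr, truth.true_cluster,
                               [marker, "DUP_" + marker] + noise,
                               n_trees=200, seed=3)
        assert marker in kept or ("DUP_" + marker) in kept

    def test_seeded_determinism(self, planted_cohort):
        expr, _, truth = planted_cohort
        cand = [g for g in expr.index if g.startswith(("MRK", "NSE"))]
        a = prune_redundant(expr, truth.true_cluster, cand, n_trees=100, seed=4)
        b = prune_redundant(expr, truth.true_cluster, cand, n_trees=100, seed=4)
        assert a == b

    def test_fewer_candidates_than_classes(self, planted_cohort):
        expr, _, truth = planted_cohort
        gene = [expr.index[0]]
        with pytest.warns(UserWarning, match="fewer candidates"):
            kept = prune_redundant(expr, truth.true_cluster, gene)
        assert kept == gene


class TestCoxSignSplit:
    def test_protective_gene_lands_in_x(self, survival_cohort):
        expr, clin, truth = survival_cohort
        sets = cox_sign_split(expr, clin,
                              truth.protective_genes + truth.risk_genes)
        assert set(truth.protective_genes) <= set(sets.set_X)
        assert set(truth.risk_genes) <= set(sets.set_Y)

    def test_null_gene_coefficient_near_zero(self, signature):
        coefs = []
        for seed in range(10):
            expr, clin, _ = simulate.simulate_cohort(
                120, 25, 2, signature, hazard_beta=0.0, seed=seed
            )
            g = next(g for g in expr.index if g.startswith("NSE"))
            sets = cox_sign_split(expr, clin, [g])
            coefs.append(sets.coefficients.get(g, 0.0))
        assert abs(np.mean(coefs)) < 0.15

    def test_constant_gene_excluded(self, survival_cohort):
        expr, clin, truth = survival_cohort
        expr = expr.copy()
        expr.loc["CONST"] = 2.0
        with pytest.warns(UserWarning, match="constant gene"):
            sets = cox_sign_split(expr, clin, ["CONST"] + truth.protective_genes)
        assert "CONST" not in sets.set_X + sets.set_Y

    def test_requires_events(self, planted_cohort):
        expr, clin, truth = planted_cohort
        clin = clin.copy()
        clin["os_event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_sign_split(expr, clin, truth.protective_genes)


class TestComputeTMEscore:
    def _expr(self, data, samples):
        return pd.DataFrame(data, columns=samples)

    def test_hand_arithmetic_single_genes(self):
        expr = pd.DataFrame({"s1": [3.0, 1.0], "s2": [0.0, 0.0]},
                            index=["g1", "g2"])
        res = compute_tmescore(expr, _sets(x=["g1"], y=["g2"]))
        s1 = res.table.set_index("sample_id").loc["s1", "tmescore"]
        assert s1 == pytest.approx(np.log2(4) - np.log2(2))  # = 1

    def test_hand_arithmetic_three_genes(self):
        expr = pd.DataFrame({"s1": [3.0, 7.0, 1.0]},
                            index=["g1", "g2", "g3"])
        expr["s2"] = 0.0
        res = compute_tmescore(expr, _sets(x=["g1", "g2"], y=["g3"]))
        s1 = res.table.set_index("sample_id").loc["s1", "tmescore"]
        assert s1 == pytest.approx(2 + 3 - 1)

    def test_all_zero_expression_scores_zero(self):
        expr = pd.DataFrame(np.zeros((2, 3)), index=["g1", "g2"],
                            columns=["a", "b", "c"])
        res = compute_tmescore(expr, _sets(x=["g1"], y=["g2"]))
        assert (res.table["tmescore"] == 0).all()

    def test_strict_median_split_ties_go_low(self):
        expr = pd.DataFrame([[1.0, 1.0, 3.0, 7.0]], index=["g1"],
                            columns=list("abcd"))
        res = compute_tmescore(expr, _sets(x=["g1"]))
        table = res.table.set_index("sample_id")
        # median of scores: ties at the two lowest; strict > for high
        med = res.median
        assert ((table["tmescore"] > med) == (table["group"] == "high")).all()

    def test_additive_over_disjoint_x_sets(self, planted_cohort):
        expr, _, _ = planted_cohort
        genes = list(expr.index[:6])
        a = compute_tmescore(expr, _sets(x=genes[:3]))
        b = compute_tmescore(expr, _sets(x=genes[3:]))
        both = compute_tmescore(expr, _sets(x=genes))
        assert np.allclose(
            both.table["tmescore"], a.table["tmescore"] + b.table["tmescore"]
        )

    def test_sample_permutation_permutes_scores(self, planted_cohort):
        expr, _, _ = planted_cohort
        genes = list(expr.index[:4])
        perm = expr[expr.columns[::-1]]
        a = compute_tmescore(expr, _sets(x=genes)).table.set_index("sample_id")
        b = compute_tmescore(perm, _sets(x=genes)).table.set_index("sample_id")
        assert np.allclose(a["tmescore"], b["tmescore"].loc[a.index])

    def test_empty_sets_error(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            compute_tmescore(expr, _sets(x=["zz"], y=["ww"]))


class TestValidateScore:
    def test_frozen_sets_validate_on_new_cohort(self, signature, survival_cohort):
        _, _, truth = survival_cohort
        expr_new, clin_new, truth_new = simulate.simulate_cohort(
            300, 40, 3, signature, hazard_beta=-1.0, seed=11
        )
        sets = _sets(x=truth_new.protective_genes, y=truth_new.risk_genes)
        res = validate_score(expr_new, clin_new, sets)
        assert res["hr"] < 1.0
        assert res["logrank_p"] < 0.01

    def test_identical_survival_in_both_groups_gives_unit_hr(self):
        # symmetric arms with identical survival: likelihood maximized at 0
        samples = list("abcdefghij")
        expr = pd.DataFrame([[1.0] * 5 + [9.0] * 5], index=["g1"],
                            columns=samples)
        clin = pd.DataFrame({
            "sample_id": samples,
            "os_time": [10.0, 20.0, 30.0, 40.0, 50.0] * 2,
            "os_event": [1] * 10,
        })
        res = validate_score(expr, clin, _sets(x=["g1"]))
        assert res["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_score_reports_missing_hr(self, planted_cohort):
        expr, clin, _ = planted_cohort
        flat = expr.copy()
        flat.loc["g_const"] = 5.0
        with pytest.warns(UserWarning, match="constant score"):
            res = validate_score(flat, clin, _sets(x=["g_const"]))
        assert np.isnan(res["hr"])

    def test_noise_score_null_calibration(self, signature):
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            expr, clin, _ = simulate.simulate_cohort(
                100, 25, 2, signature, hazard_beta=0.0, de_effect_log2fc=0.0,
                seed=1000 + rep,
            )
            noise_gene = [g for g in expr.index if g.startswith("NSE")][0]
            score = np.log2(expr.loc[noise_gene].to_numpy() + 1)
            high = score > np.median(score)
            chi2, p = logrank_chi2(clin["os_time"], clin["os_event"],
                                   high.astype(int))
            hits += p < 0.05
        # binomial(50, 0.05): central 99% range
        assert hits <= 9
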