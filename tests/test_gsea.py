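"""Enrichment: ranking rules, set filtering, running-sum score against an
enumeration oracle, phenotype-permutation significance, enrichment map."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import lungsexage as lx
from conftest import null_gene_matrix, planted_gene_matrix, simple_truth


def brute_force_es(genes, members, weight=0.0, scores=None):
    """Direct enumeration of the running sum; independent of the package's
    incremental implementation."""
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    if weight == 0:
        incs = [1.0 / k] * n
    else:
        w = [abs(s) ** weight for s in scores]
        tot = sum(wi for wi, h in zip(w, hits) if h)
        incs = [wi / tot for wi in w]
    run, best = 0.0, 0.0
    for j in range(n):
        run += incs[j] if hits[j] else -1.0 / (n - k)
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return best


def assoc_table(t_by_gene):
    return pd.DataFrame(
        {"t_stat": pd.Series(t_by_gene), "beta": 0.0, "p_value": 0.5}
    ).rename_axis("gene")


class TestRankGenes:
    def test_descending_by_t(self):
        ranked = lx.rank_genes(assoc_table({"A": 2.0, "B": -1.0, "C": 0.5}))
        assert list(ranked.index) == ["A", "C", "B"]

    def test_ties_broken_alphabetically(self):
        ranked = lx.rank_genes(assoc_table({"B": 1.0, "A": 1.0, "C": 2.0}))
        assert list(ranked.index) == ["C", "A", "B"]

    def test_sign_flip_reverses_tie_free_ranking(self):
        t = {"A": 2.0, "B": -1.0, "C": 0.5, "D": 3.3}
        fwd = list(lx.rank_genes(assoc_table(t)).index)
        rev = list(lx.rank_genes(assoc_table({g: -v for g, v in t.items()})).index)
        assert rev == fwd[::-1]

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            lx.rank_genes(assoc_table({"A": np.nan, "B": 1.0}))


class TestFilterSets:
    def test_post_intersection_size_governs(self):
        universe = [f"G{i}" for i in range(400)]
        big = tuple(f"G{i}" for i in range(400)) + tuple(f"OUT{i}" for i in range(200))
        coll = lx.GeneSetCollection({"S": big})
        assert "S" in lx.filter_sets(coll, universe, 15, 500).sets

    def test_below_minimum_removed(self):
        universe = [f"G{i}" for i in range(100)]
        coll = lx.GeneSetCollection({"S": tuple(f"G{i}" for i in range(14))})
        assert len(lx.filter_sets(coll, universe, 15, 500)) == 0

    def test_boundaries_inclusive(self):
        universe = [f"G{i}" for i in range(600)]
        coll = lx.GeneSetCollection(
            {
                "LO": tuple(f"G{i}" for i in range(15)),
                "HI": tuple(f"G{i}" for i in range(500)),
            }
        )
        kept = lx.filter_sets(coll, universe, 15, 500)
        assert set(kept.sets) == {"LO", "HI"}

    def test_empty_universe_empties_collection(self):
        coll = lx.GeneSetCollection({"S": tuple(f"G{i}" for i in range(20))})
        assert len(lx.filter_sets(coll, [], 1, 500)) == 0


class TestEnrichmentScore:
    def test_matches_enumeration_exhaustively(self):
        # every hit-position pattern for N=12, set sizes 1..4
        genes = [f"G{i:02d}" for i in range(12)]
        scores = pd.Series(np.linspace(3, -3, 12), index=genes)
        for k in range(1, 5):
            for pos in itertools.combinations(range(12), k):
                members = [genes[j] for j in pos]
                es = lx.enrichment_score(scores, members).es
                assert es == pytest.approx(brute_force_es(genes, members), abs=1e-12)

    def test_weighted_form_matches_enumeration(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i:02d}" for i in range(15)]
        for rep in range(50):
            scores = pd.Series(np.sort(rng.normal(size=15))[::-1], index=genes)
            members = list(rng.choice(genes, size=5, replace=False))
            es = lx.enrichment_score(scores, members, weight=1.0).es
            ref = brute_force_es(genes, members, weight=1.0, scores=scores.to_numpy())
            assert es == pytest.approx(ref, abs=1e-12)

    def test_all_members_at_top(self):
        genes = [f"G{i:02d}" for i in range(20)]
        scores = pd.Series(np.linspace(5, -5, 20), index=genes)
        members = genes[:5]
        es = lx.enrichment_score(scores, members)
        assert es.es == pytest.approx(brute_force_es(genes, members))
        assert es.es == pytest.approx(1.0, abs=1e-9)  # perfect front-loading
        assert es.leading_edge == members

    def test_interleaved_members_score_low(self):
        genes = [f"G{i:02d}" for i in range(20)]
        scores = pd.Series(np.linspace(5, -5, 20), index=genes)
        members = genes[1::4]  # evenly spread
        es = lx.enrichment_score(scores, members).es
        assert abs(es) < 0.35

    def test_complement_symmetry_on_tie_free_ranking(self):
        genes = [f"G{i:02d}" for i in range(12)]
        scores = pd.Series(np.linspace(3, -3, 12), index=genes)
        members = ["G01", "G04", "G05", "G09"]
        complement = [g for g in genes if g not in members]
        es_a = lx.enrichment_score(scores, members).es
        es_b = lx.enrichment_score(scores, complement).es
        assert abs(es_a) == pytest.approx(abs(es_b), abs=1e-12)

    def test_degenerate_sets_rejected(self):
        genes = [f"G{i}" for i in range(5)]
        scores = pd.Series(np.arange(5, 0, -1, dtype=float), index=genes)
        with pytest.raises(ValueError):
            lx.enrichment_score(scores, [])
        with pytest.raises(ValueError):
            lx.enrichment_score(scores, genes)


def matrix_with_enriched_set(seed, n_genes=300, set_size=15, slope=0.02):
    genes = {f"E{i}": (8.0, 0.0, slope, "1") for i in range(set_size)}
    genes.update({f"N{i}": (8.0, 0.0, 0.0, "1") for i in range(n_genes - set_size)})
    truth = simple_truth(genes, residual_sd=0.3)
    spec = lx.CohortSpec(
        name="gsea",
        n_samples=100,
        n_male=50,
        age_range_male=(36, 85),
        age_range_female=(36, 85),
        smoking_levels={"current": 1.0},
    )
    mat = planted_gene_matrix(truth, spec=spec, seed=seed)
    members = tuple(f"E{i}" for i in range(set_size))
    return mat, members


class TestEnrichmentSignificance:
    def test_planted_set_reaches_fdr(self):
        for rep in range(3):
            mat, members = matrix_with_enriched_set(seed=100 + rep)
            decoys = {
                f"D{j}": tuple(f"N{15 * j + i}" for i in range(15)) for j in range(10)
            }
            coll = lx.GeneSetCollection({"PLANTED": members, **decoys})
            res = lx.enrichment_significance(
                mat, lx.AssociationConfig(variable="age"), coll,
                n_permutations=300, seed=rep,
            )
            assert res.loc["PLANTED", "fdr"] < 0.05
            assert res.loc["PLANTED", "es"] > 0

    def test_null_sets_have_calibrated_pvalues(self):
        mat = null_gene_matrix(n_samples=80, n_genes=600, seed=7)
        sets = {
            f"S{j}": tuple(mat.expr.columns[15 * j: 15 * (j + 1)]) for j in range(40)
        }
        res = lx.enrichment_significance(
            mat, lx.AssociationConfig(variable="sex"), lx.GeneSetCollection(sets),
            n_permutations=200, seed=1,
        )
        frac = (res["p_value"] < 0.05).mean()
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_pvalues_stable_across_seed_batches(self):
        from scipy import stats

        mat = null_gene_matrix(n_samples=60, n_genes=300, seed=8)
        sets = {
            f"S{j}": tuple(mat.expr.columns[15 * j: 15 * (j + 1)]) for j in range(20)
        }
        coll = lx.GeneSetCollection(sets)
        cfg = lx.AssociationConfig(variable="sex")
        p1 = lx.enrichment_significance(mat, cfg, coll, n_permutations=150, seed=2)["p_value"]
        p2 = lx.enrichment_significance(mat, cfg, coll, n_permutations=150, seed=9_999)["p_value"]
        assert stats.ks_2samp(p1, p2).pvalue > 0.001

    def test_zero_permutations_refused(self):
        mat = null_gene_matrix(n_samples=40, n_genes=60, seed=9)
        coll = lx.GeneSetCollection({"S": tuple(mat.expr.columns[:15])})
        with pytest.raises(ValueError):
            lx.enrichment_significance(
                mat, lx.AssociationConfig(variable="sex"), coll, n_permutations=0
            )


class TestEnrichmentMap:
    def result_frame(self, fdrs):
        return pd.DataFrame(
            {"es": 0.5, "fdr": pd.Series(fdrs), "p_value": 0.01}
        ).rename_axis("set")

    def test_subset_gives_unit_overlap_edge(self):
        coll = lx.GeneSetCollection({"A": ("g1", "g2"), "B": ("g1", "g2", "g3")})
        g = lx.build_enrichment_map(self.result_frame({"A": 0.01, "B": 0.01}), coll)
        assert g.has_edge("A", "B")
        assert g.edges["A", "B"]["overlap"] == pytest.approx(1.0)

    def test_disjoint_sets_unconnected(self):
        coll = lx.GeneSetCollection({"A": ("g1", "g2"), "B": ("g3", "g4")})
        g = lx.build_enrichment_map(self.result_frame({"A": 0.01, "B": 0.01}), coll)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_overlap_cutoff_inclusive_at_half(self):
        a = tuple(f"a{i}" for i in range(15)) + tuple(f"s{i}" for i in range(5))
        b = tuple(f"b{i}" for i in range(5)) + tuple(f"s{i}" for i in range(5))
        coll = lx.GeneSetCollection({"A": a, "B": b})
        assert lx.overlap_coefficient(a, b) == pytest.approx(0.5)
        g = lx.build_enrichment_map(self.result_frame({"A": 0.01, "B": 0.01}), coll)
        assert g.has_edge("A", "B")
        assert g.edges["A", "B"]["weight"] == 5

    def test_nonsignificant_sets_excluded_and_no_self_edges(self):
        coll = lx.GeneSetCollection({"A": ("g1", "g2"), "B": ("g1", "g2")})
        g = lx.build_enrichment_map(self.result_frame({"A": 0.01, "B": 0.5}), coll)
        assert set(g.nodes) == {"A"}
        assert not any(a == b for a, b in g.edges)

    def test_connected_components_partition_nodes(self):
        coll = lx.GeneSetCollection(
            {"A": ("g1", "g2"), "B": ("g1", "g2", "g3"), "C": ("x1", "x2")}
        )
        g = lx.build_enrichment_map(
            self.result_frame({"A": 0.01, "B": 0.01, "C": 0.01}), coll
        )
        comps = list(nx.connected_components(g))
        assert sorted(len(c) for c in comps) == [1, 2]
        assert set().union(*comps) == set(g.nodes)
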