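"""Preprocessing: detection filter boundaries, collapse rule, quantile
normalization semantics and the empirical-Bayes batch adjustment (checked
against the Bioconductor reference implementation)."""

import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import lungsexage as lx
from lungsexage.preprocess import collapse_probes, filter_probes, quantile_normalize
from conftest import make_study, simple_truth


def study_with_rates(rates, gene_of=None, n=100):
    """n-sample study whose probes are detected in the given sample counts."""
    p = len(rates)
    expr = np.random.default_rng(0).normal(8, 1, size=(n, p))
    det = np.ones((n, p))
    for j, k in enumerate(rates):
        det[:k, j] = 0.001
    return make_study(expr, det, gene_of=gene_of)


class TestFilterProbes:
    def test_boundary_at_ten_percent_is_kept(self):
        study = study_with_rates([10, 9, 100])
        kept = filter_probes(study)
        assert list(kept.probes.index) == ["P001", "P003"]

    def test_unannotated_probe_removed_despite_full_detection(self):
        study = study_with_rates([100, 100], gene_of={"P001": "", "P002": "G2"})
        kept = filter_probes(study)
        assert list(kept.probes.index) == ["P002"]

    def test_order_preserved_and_idempotent(self):
        study = study_with_rates([50, 9, 80, 12])
        once = filter_probes(study)
        twice = filter_probes(once)
        assert list(once.probes.index) == ["P001", "P003", "P004"]
        pd.testing.assert_frame_equal(once.expr, twice.expr)

    def test_empty_result_warns(self):
        study = study_with_rates([5, 3])
        with pytest.warns(UserWarning):
            filter_probes(study)


class TestCollapseProbes:
    def test_highest_detection_rate_wins(self):
        study = study_with_rates([95, 80], gene_of={"P001": "G", "P002": "G"})
        mat = collapse_probes(study)
        assert mat.genes.loc["G", "probe_id"] == "P001"
        assert mat.genes.loc["G", "detection_rate"] == pytest.approx(0.95)

    def test_single_probe_column_equals_probe_values(self):
        study = study_with_rates([60])
        mat = collapse_probes(study)
        np.testing.assert_array_equal(
            mat.expr["G1"].to_numpy(), study.expr["P001"].to_numpy()
        )

    def test_tie_broken_by_smallest_probe_id(self):
        study = study_with_rates([90, 90], gene_of={"P001": "G", "P002": "G"})
        mat = collapse_probes(study)
        assert mat.genes.loc["G", "probe_id"] == "P001"

    def test_collapse_of_one_probe_per_gene_is_identity(self):
        study = study_with_rates([50, 60, 70])
        mat = collapse_probes(study)
        np.testing.assert_allclose(mat.expr.to_numpy(), study.expr.to_numpy())


class TestQuantileNormalize:
    def test_hand_computed_order_statistic_means(self):
        study = make_study([[1, 2, 3], [4, 5, 6]], np.full((2, 3), 0.001))
        mat = quantile_normalize(collapse_probes(study))
        np.testing.assert_allclose(mat.expr.to_numpy(), [[2.5, 3.5, 4.5]] * 2)

    def test_already_normalized_input_unchanged(self):
        # same value multiset in both samples, shuffled across genes
        study = make_study([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]], np.full((2, 3), 0.001))
        mat = quantile_normalize(collapse_probes(study))
        np.testing.assert_allclose(
            mat.expr.to_numpy(), [[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]]
        )

    def test_sorted_rows_identical_after_normalization(self):
        rng = np.random.default_rng(3)
        study = make_study(rng.normal(8, 2, (5, 40)), np.full((5, 40), 0.001))
        mat = quantile_normalize(collapse_probes(study))
        rows = np.sort(mat.expr.to_numpy(), axis=1)
        for i in range(1, 5):
            np.testing.assert_allclose(rows[i], rows[0])

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        study = make_study(rng.normal(8, 2, (6, 30)), np.full((6, 30), 0.001))
        once = quantile_normalize(collapse_probes(study))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.expr.to_numpy(), twice.expr.to_numpy(), atol=1e-12
        )

    def test_ties_get_mean_of_tied_reference_values(self):
        study = make_study([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]], np.full((2, 3), 0.001))
        mat = quantile_normalize(collapse_probes(study))
        # reference = [1.5, 2.5, 5.5]; tied pair in sample 1 -> mean(1.5, 2.5)
        np.testing.assert_allclose(mat.expr.iloc[0].to_numpy(), [2.0, 2.0, 5.5])

    def test_single_sample_returned_unchanged(self):
        study = make_study([[3.0, 1.0, 2.0]], np.full((1, 3), 0.001))
        mat = quantile_normalize(collapse_probes(study))
        np.testing.assert_allclose(mat.expr.to_numpy(), [[3.0, 1.0, 2.0]])


def two_batch_matrix(n1=100, n2=50, n_genes=200, loc2=0.0, seed=0, sex_fc=0.0):
    genes = {
        f"G{i:04d}": (8.0, sex_fc if i < 10 else 0.0, 0.0, "1") for i in range(n_genes)
    }
    truth = simple_truth(genes, residual_sd=0.3)
    spec = lx.CohortSpec(
        name="cb",
        n_samples=n1 + n2,
        n_male=(n1 + n2) // 2,
        age_range_male=(40, 80),
        age_range_female=(40, 80),
        smoking_levels={"current": 1.0},
        batch_sizes=(n1, n2),
    )
    loc = pd.DataFrame(
        np.vstack([np.zeros(n_genes), np.full(n_genes, loc2)]),
        index=spec.batch_names,
        columns=list(truth.symbols),
    )
    scale = pd.DataFrame(
        np.ones((2, n_genes)), index=spec.batch_names, columns=list(truth.symbols)
    )
    batches = lx.BatchEffect(location=loc, scale=scale)
    study = lx.generate_study(spec, truth, batches=batches, seed=seed)
    return collapse_probes(study)


class TestCombat:
    def test_near_null_data_left_near_unchanged(self):
        mat = two_batch_matrix(loc2=0.0, seed=1)
        adj = lx.combat_adjust(mat)
        rms = np.sqrt(np.mean((adj.expr.to_numpy() - mat.expr.to_numpy()) ** 2))
        assert rms < 0.05

    def test_planted_location_shift_removed(self):
        mat = two_batch_matrix(loc2=1.0, seed=2)
        adj = lx.combat_adjust(mat)
        b = mat.samples["batch"]
        delta = (
            adj.expr[b == b.unique()[0]].mean() - adj.expr[b == b.unique()[1]].mean()
        )
        assert np.abs(delta).mean() < 0.05

    def test_identical_batches_give_zero_location_estimates(self):
        rng = np.random.default_rng(5)
        block = rng.normal(8, 1, size=(20, 50))
        expr = np.vstack([block, block])
        study = make_study(expr, np.full((40, 50), 0.001))
        mat = collapse_probes(study)
        mat.samples["batch"] = ["b1"] * 20 + ["b2"] * 20
        adj = lx.combat_adjust(mat)
        # symmetric batches: adjustment collapses both onto their common mean
        top = adj.expr.iloc[:20].to_numpy()
        bottom = adj.expr.iloc[20:].to_numpy()
        np.testing.assert_allclose(top, bottom, atol=1e-8)

    def test_biological_signal_preserved(self):
        # paired comparison: sex-effect recovery error with planted batch
        # effects + adjustment vs the clean no-batch scenario
        diffs = []
        for rep in range(15):
            clean = two_batch_matrix(loc2=0.0, seed=100 + rep, sex_fc=0.6)
            noisy = two_batch_matrix(loc2=0.8, seed=100 + rep, sex_fc=0.6)
            adj = lx.combat_adjust(noisy)
            cfg = lx.AssociationConfig(variable="sex")
            planted = [f"G{i:04d}" for i in range(10)]
            err_clean = (
                lx.fit_associations(clean, cfg).loc[planted, "beta"] - 0.6
            ).abs().mean()
            err_adj = (
                lx.fit_associations(adj, cfg).loc[planted, "beta"] - 0.6
            ).abs().mean()
            diffs.append(err_adj - err_clean)
        assert abs(np.mean(diffs)) < 0.02

    def test_single_batch_rejected(self):
        mat = two_batch_matrix(seed=3)
        mat.samples["batch"] = "only"
        with pytest.raises(ValueError):
            lx.combat_adjust(mat)

    def test_tiny_batch_rejected(self):
        mat = two_batch_matrix(seed=4)
        labels = mat.samples["batch"].copy()
        labels.iloc[:] = labels.unique()[0]
        labels.iloc[0] = "lonely"
        with pytest.raises(ValueError):
            lx.combat_adjust(mat, batch_labels=labels)

    def test_confounded_covariate_rejected(self):
        mat = two_batch_matrix(seed=6)
        conf = pd.DataFrame(
            {"x": (mat.samples["batch"] == mat.samples["batch"].unique()[0]).astype(float)}
        )
        with pytest.raises(ValueError):
            lx.combat_adjust(mat, covariates=conf)


class TestCombatAgainstReference:
    def test_matches_bioconductor_sva(self, tmp_path):
        """Cross-check against sva::ComBat on a small two-batch matrix."""
        mat = two_batch_matrix(n1=18, n2=12, n_genes=40, loc2=0.7, seed=9)
        dat = mat.expr.T  # genes x samples, as the reference expects
        dat.to_csv(tmp_path / "dat.tsv", sep="\t")
        mat.samples["batch"].to_csv(tmp_path / "batch.tsv", sep="\t")
        script = tmp_path / "combat.R"
        script.write_text(
            """
            suppressMessages(library(sva))
            dat <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t", header=TRUE, row.names=1, check.names=FALSE))
            batch <- read.table(commandArgs(TRUE)[2], sep="\\t", header=TRUE, row.names=1)$batch
            out <- ComBat(dat=dat, batch=batch)
            write.table(out, commandArgs(TRUE)[3], sep="\\t", quote=FALSE)
            """
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "dat.tsv"),
             str(tmp_path / "batch.tsv"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0).T
        adj = lx.combat_adjust(mat)
        np.testing.assert_allclose(
            adj.expr.to_numpy(), ref.to_numpy(), atol=1e-3, rtol=1e-3
        )


class TestPreprocessStudy:
    def test_full_pipeline_yields_gene_matrix(self):
        truth = lx.default_truth_from_tables(100, seed=2)
        spec = lx.discovery_spec()
        study = lx.generate_study(spec, truth, seed=3, n_unannotated_probes=4)
        mat = lx.preprocess_study(study)
        assert mat.expr.shape[0] == 284
        assert set(mat.expr.columns) <= set(truth.symbols)
        assert "" not in set(mat.genes.index)
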