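import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from aimsel.fda import FeatureMatrix
from aimsel.io_formats import GenotypeMatrix, PopulationLabels
from aimsel.report import (
    ReportBundle,
    RunConfig,
    genotype_frequency_report,
    marker_impact_report,
    mds_coordinates,
    misclassification_report,
    run_pipeline,
    write_bundle,
)
from aimsel.selection import (
    CandidateModelSet,
    SelectionConfig,
    SelectionTrace,
    make_cv_partition,
    run_cross_validation,
)
from aimsel.synthetic import SimulationConfig, simulate_dataset


def _fm(values, ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"f{j}" for j in range(p)]
    return FeatureMatrix([f"s{i}" for i in range(n)], ids, values, ["ge"] * p,
                         {f: 0.0 for f in ids})


class TestMDS:
    def test_two_samples_symmetric_coordinates(self):
        # one standardized feature, two samples -> z = (-1, 1), distance 2
        fm = _fm([[0.0], [10.0]])
        coords = mds_coordinates(fm)
        np.testing.assert_allclose(sorted(coords["mds1"]), [-1.0, 1.0], atol=1e-10)

    def test_reproduces_euclidean_distances_of_2d_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 2))
        # pre-standardize so the internal standardization is a no-op
        x = (x - x.mean(0)) / x.std(0)
        coords = mds_coordinates(_fm(x))
        d_in = squareform(pdist(x))
        d_out = squareform(pdist(coords[["mds1", "mds2"]].to_numpy()))
        np.testing.assert_allclose(d_out, d_in, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        fm = _fm([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        coords = mds_coordinates(fm)
        np.testing.assert_allclose(
            coords.loc[0, ["mds1", "mds2"]].to_numpy(dtype=float),
            coords.loc[1, ["mds1", "mds2"]].to_numpy(dtype=float),
            atol=1e-7,
        )

    def test_degenerate_input_zero_filled(self):
        fm = _fm(np.zeros((1, 1)))
        with np.errstate(all="ignore"):
            coords = mds_coordinates(fm)
        assert (coords[["mds1", "mds2"]].to_numpy() == 0).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 3))
        a = mds_coordinates(_fm(x))
        b = mds_coordinates(_fm(x))
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestGenotypeFrequencyReport:
    def _g(self):
        calls = np.array([[0], [0], [1], [2], [2], [2], [1], [1]], dtype=np.int8)
        return GenotypeMatrix([f"s{i}" for i in range(8)], ["m1"], calls)

    def _labels(self):
        return PopulationLabels([f"s{i}" for i in range(8)], ["A"] * 4 + ["B"] * 4)

    def test_single_snp_frequencies(self):
        table = genotype_frequency_report(["m1"], self._g(), self._labels())
        row = table[table["population"] == "A"].iloc[0]
        assert row["AA"] == 0.5 and row["AB"] == 0.25 and row["BB"] == 0.25

    def test_rows_sum_to_one(self):
        table = genotype_frequency_report(["m1"], self._g(), self._labels())
        sums = table[["AA", "AB", "BB"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_pair_mode_nine_columns(self):
        calls = np.array([[0, 1], [1, 2], [2, 0], [0, 0]], dtype=np.int8)
        g = GenotypeMatrix([f"s{i}" for i in range(4)], ["m1", "m2"], calls)
        labels = PopulationLabels([f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        table = genotype_frequency_report(["m1", "m2"], g, labels, pairs=True)
        combo_cols = [c for c in table.columns if "/" in c]
        assert len(combo_cols) == 9
        np.testing.assert_allclose(table[combo_cols].sum(axis=1), 1.0, atol=1e-12)

    def test_missing_calls_excluded(self):
        calls = np.array([[0], [0], [-1], [2]], dtype=np.int8)
        g = GenotypeMatrix([f"s{i}" for i in range(4)], ["m1"], calls)
        labels = PopulationLabels([f"s{i}" for i in range(4)], ["A", "A", "A", "B"])
        table = genotype_frequency_report(["m1"], g, labels)
        row = table[table["population"] == "A"].iloc[0]
        assert row["n"] == 2 and row["AA"] == 1.0


class TestMarkerImpact:
    def test_counts_and_steps(self):
        traces = [
            SelectionTrace(f, ["m1", "m2"] if f < 2 else ["m1"], ["snp"] * 2,
                           [0.9, 1.0], [0.1, 0.2])
            for f in range(3)
        ]
        traces[2].marker_types = ["snp"]
        traces[2].training_accuracies = [1.0]
        traces[2].ssw_ssb_values = [0.1]
        table = marker_impact_report(CandidateModelSet(traces))
        m1 = table[table["marker_id"] == "m1"].iloc[0]
        assert m1["selection_times"] == 3
        assert m1["steps"] == "1;1;1"
        m2 = table[table["marker_id"] == "m2"].iloc[0]
        assert m2["selection_times"] == 2

    def test_never_selected_marker_absent(self):
        traces = [SelectionTrace(0, ["m1"], ["snp"], [1.0], [0.0])]
        table = marker_impact_report(CandidateModelSet(traces))
        assert "m9" not in set(table["marker_id"])

    def test_counts_bounded_by_fold_count(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=5, seed=0)
        cms = run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp"))
        table = marker_impact_report(cms)
        assert (table["selection_times"] <= 5).all()


class TestMisclassification:
    @pytest.fixture
    def cv_run(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=5, seed=0)
        cms = run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp"))
        return cms, cv, labels, g

    def test_perfectly_classified_samples_zero(self, cv_run):
        cms, cv, labels, g = cv_run
        per_sample, _ = misclassification_report(cms, cv, labels, g, None)
        # planted fixed-difference SNP -> all test misclassification 0
        assert (per_sample["test_misclassification"] == 0.0).all()
        assert (per_sample["n_test_folds"] == 1).all()

    def test_misclassified_sample_gets_one(self):
        # degenerate pool: constant marker, majority class predicted
        calls = np.zeros((6, 1), dtype=np.int8)
        g = GenotypeMatrix([f"s{i}" for i in range(6)], ["m1"], calls)
        labels = PopulationLabels([f"s{i}" for i in range(6)], ["A"] * 4 + ["B"] * 2)
        cv = make_cv_partition(labels, k=2, seed=0)
        cms = run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp"))
        per_sample, _ = misclassification_report(cms, cv, labels, g, None)
        b_rows = per_sample[per_sample["label"] == "B"]
        assert (b_rows["test_misclassification"] == 1.0).all()

    def test_step_table_bookkeeping(self, cv_run):
        cms, cv, labels, g = cv_run
        _, by_step = misclassification_report(cms, cv, labels, g, None)
        for t in cms.traces:
            steps = by_step[by_step["fold"] == t.fold]
            assert len(steps) == t.n_markers
            final = steps[steps["step"] == t.n_markers].iloc[0]
            assert final["test_misclassification"] == pytest.approx(
                1.0 - t.testing_accuracy
            )


class TestPipeline:
    def _dataset(self, tmp_path, seed=5):
        from aimsel.synthetic import write_dataset

        cfg = SimulationConfig(
            populations=[("P1", 20), ("P2", 20)],
            n_noise_snps=30,
            n_info_snps=1,
            info_snp_freqs=np.array([[0.05, 0.95]]),
            n_noise_ge=15,
            n_info_ge=1,
            ge_shift=3.0,
            missing_rate=0.02,
            seed=seed,
        )
        return write_dataset(simulate_dataset(cfg), tmp_path / "data")

    def _cfg(self, paths, out_dir, **kw):
        defaults = dict(
            genotypes=str(paths["genotypes"]),
            expression=str(paths["expression"]),
            labels=str(paths["labels"]),
            probe_annotation=str(paths["probe_annotation"]),
            snp_annotation=str(paths["snp_annotation"]),
            mode="snp+ge",
            folds=5,
            seed=7,
            out_dir=str(out_dir),
        )
        defaults.update(kw)
        return RunConfig(**defaults)

    def test_deterministic_rerun_byte_identical(self, tmp_path):
        paths = self._dataset(tmp_path)
        cfg1 = self._cfg(paths, tmp_path / "out1")
        cfg2 = self._cfg(paths, tmp_path / "out2")
        b1 = run_pipeline(cfg1)
        b2 = run_pipeline(cfg2)
        write_bundle(b1, cfg1, tmp_path / "out1")
        write_bundle(b2, cfg2, tmp_path / "out2")
        for f in sorted((tmp_path / "out1").iterdir()):
            if f.suffix in (".tsv", ".txt"):
                assert f.read_bytes() == (tmp_path / "out2" / f.name).read_bytes(), f.name

    def test_rerun_from_manifest_reproduces_tables(self, tmp_path):
        paths = self._dataset(tmp_path)
        cfg = self._cfg(paths, tmp_path / "out1")
        bundle = run_pipeline(cfg)
        write_bundle(bundle, cfg, tmp_path / "out1")
        cfg2 = RunConfig.from_yaml(tmp_path / "out1" / "run_manifest.yaml")
        cfg2.out_dir = str(tmp_path / "out2")
        bundle2 = run_pipeline(cfg2)
        write_bundle(bundle2, cfg2, tmp_path / "out2")
        for f in sorted((tmp_path / "out1").iterdir()):
            if f.suffix in (".tsv", ".txt"):
                assert f.read_bytes() == (tmp_path / "out2" / f.name).read_bytes(), f.name

    def test_ge_mode_without_expression_fails_early(self, tmp_path):
        paths = self._dataset(tmp_path)
        cfg = self._cfg(paths, tmp_path / "out", mode="ge", expression=None)
        with pytest.raises(ValueError, match="expression"):
            run_pipeline(cfg)

    def test_bundle_tables_reference_run_entities(self, tmp_path):
        paths = self._dataset(tmp_path)
        cfg = self._cfg(paths, tmp_path / "out")
        bundle = run_pipeline(cfg)
        best_markers = set(bundle.best_model_summary["markers"])
        assert best_markers <= set(bundle.marker_impact["marker_id"])
        assert set(bundle.mds["sample_id"]) == set(bundle.misclassification["sample_id"])
        assert len(bundle.candidate_models) == 5

    def test_planted_signal_wins(self, tmp_path):
        paths = self._dataset(tmp_path)
        cfg = self._cfg(paths, tmp_path / "out")
        bundle = run_pipeline(cfg)
        top = {m for m in bundle.best_model_summary["markers"]}
        assert top & {"snp_info_0001", "ge_info_0001"}
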