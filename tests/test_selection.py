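import numpy as np
import pytest

from _oracles import exhaustive_forward_step
from aimsel.fda import FeatureMatrix, encode_features
from aimsel.io_formats import PopulationLabels
from aimsel.selection import (
    CandidateModelSet,
    SelectionConfig,
    SelectionTrace,
    forward_select,
    make_cv_partition,
    run_cross_validation,
    select_best_model,
)
from aimsel.synthetic import SimulationConfig, simulate_dataset


def _fm(values, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    return FeatureMatrix(
        [f"s{i}" for i in range(n)],
        feature_ids,
        values,
        ["ge"] * p,
        {f: float(values[:, j].mean()) for j, f in enumerate(feature_ids)},
    )


def _labels(y):
    return PopulationLabels([f"s{i}" for i in range(len(y))], list(y))


class TestCVPartition:
    def test_stratified_45_45_k10(self):
        labels = PopulationLabels(
            [f"s{i}" for i in range(90)], ["CHB"] * 45 + ["JPT"] * 45
        )
        cv = make_cv_partition(labels, k=10, seed=0)
        lab = np.asarray(labels.labels)
        for pop in ("CHB", "JPT"):
            sizes = np.bincount(cv.fold_assignment[lab == pop], minlength=10)
            assert set(sizes.tolist()) <= {4, 5}
            assert sizes.sum() == 45

    def test_k2_balanced(self):
        labels = PopulationLabels(
            [f"s{i}" for i in range(8)], ["A"] * 4 + ["B"] * 4
        )
        cv = make_cv_partition(labels, k=2, seed=1)
        lab = np.asarray(labels.labels)
        for pop in ("A", "B"):
            sizes = np.bincount(cv.fold_assignment[lab == pop], minlength=2)
            assert sizes.tolist() == [2, 2]

    def test_same_seed_identical(self, two_pop_labels):
        a = make_cv_partition(two_pop_labels, k=4, seed=9)
        b = make_cv_partition(two_pop_labels, k=4, seed=9)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_small_population_spread_over_distinct_folds(self):
        labels = PopulationLabels(
            [f"s{i}" for i in range(13)], ["A"] * 10 + ["B"] * 3
        )
        cv = make_cv_partition(labels, k=5, seed=2)
        b_folds = cv.fold_assignment[np.asarray(labels.labels) == "B"]
        assert len(set(b_folds.tolist())) == 3

    def test_k_below_two_rejected(self, two_pop_labels):
        with pytest.raises(ValueError):
            make_cv_partition(two_pop_labels, k=1, seed=0)


class TestForwardSelect:
    def test_perfect_marker_beats_noise(self):
        rng = np.random.default_rng(0)
        y = "A" * 10 + "B" * 10
        perfect = np.array([0.0] * 10 + [2.0] * 10)
        noise = rng.normal(size=20)
        fm = _fm(np.column_stack([perfect, noise]), ["M1", "M2"])
        trace = forward_select(fm, _labels(y), SelectionConfig())
        assert trace.selected_markers == ["M1"]
        assert trace.training_accuracies == [1.0]

    def test_ssw_ssb_tie_break(self):
        y = "A" * 6 + "B" * 6
        sep_clean = np.array([0.0] * 6 + [2.0] * 6)         # SSW/SSB = 0
        sep_noisy = np.array([0, 0, 0, 0, 0, 0.9, 2, 2, 2, 2, 2, 1.1])  # separates, larger ratio
        fm = _fm(np.column_stack([sep_noisy, sep_clean]), ["M_b", "M_a"])
        trace = forward_select(fm, _labels(y), SelectionConfig())
        assert trace.selected_markers[0] == "M_a"

    def test_lexicographic_final_tie_break(self):
        y = "A" * 4 + "B" * 4
        sep = np.array([0.0] * 4 + [2.0] * 4)
        fm = _fm(np.column_stack([sep, sep]), ["M2", "M1"])
        trace = forward_select(fm, _labels(y), SelectionConfig())
        assert trace.selected_markers == ["M1"]

    def test_all_constant_pool_single_marker_majority(self):
        fm = _fm(np.ones((5, 3)), ["M1", "M2", "M3"])
        trace = forward_select(fm, _labels(["A", "A", "B", "B", "B"]), SelectionConfig())
        assert trace.n_markers == 1
        assert trace.training_accuracies == [pytest.approx(3 / 5)]

    def test_max_markers_cap(self):
        rng = np.random.default_rng(1)
        y = "A" * 15 + "B" * 15
        x = rng.normal(size=(30, 10)) + np.array([0.0] * 15 + [0.8] * 15)[:, None]
        cfg = SelectionConfig(max_markers=2, min_increment=1e-9)
        trace = forward_select(_fm(x), _labels(y), cfg)
        assert trace.n_markers <= 2

    def test_increment_threshold_stops_without_adding(self):
        # one strong marker, rest constant: step 2's best increment is 0
        y = "A" * 6 + "B" * 6
        strong = np.array([0.0] * 6 + [2.0] * 5 + [0.0])  # accuracy 11/12
        flat = np.ones(12)
        fm = _fm(np.column_stack([strong, flat, flat * 2]), ["M1", "M2", "M3"])
        trace = forward_select(fm, _labels(y), SelectionConfig())
        assert trace.selected_markers == ["M1"]

    def test_monotone_training_accuracy(self):
        rng = np.random.default_rng(5)
        y = "A" * 20 + "B" * 20
        x = rng.normal(size=(40, 15)) + np.array([0.0] * 20 + [0.6] * 20)[:, None]
        trace = forward_select(_fm(x), _labels(y), SelectionConfig(min_increment=1e-6))
        accs = trace.training_accuracies
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_each_step(self, seed):
        """Chosen marker at every step equals the exhaustive-search argmax."""
        rng = np.random.default_rng(seed)
        k = 2 if seed % 2 == 0 else 3
        n_per = 12
        y = [f"C{j}" for j in range(k) for _ in range(n_per)]
        shift = rng.normal(scale=0.7, size=(k, 10))
        x = np.concatenate(
            [rng.normal(shift[j], 1.0, size=(n_per, 10)) for j in range(k)]
        )
        ids = [f"f{j:02d}" for j in range(10)]
        fm = _fm(x, ids)
        cfg = SelectionConfig(min_increment=1e-9, max_markers=4, ridge=1e-10)
        trace = forward_select(fm, _labels(y), cfg)
        current: list[int] = []
        for marker in trace.selected_markers:
            j_oracle = exhaustive_forward_step(x, y, ids, current)
            assert ids.index(marker) == j_oracle
            current.append(ids.index(marker))

    def test_prescreen_keeps_informative_marker(self):
        rng = np.random.default_rng(3)
        y = "A" * 20 + "B" * 20
        noise = rng.normal(size=(40, 30))
        strong = np.array([0.0] * 20 + [2.0] * 20)[:, None]
        fm = _fm(np.column_stack([noise, strong]), [f"n{j:02d}" for j in range(30)] + ["strong"])
        cfg = SelectionConfig(prescreen_top=5)
        trace = forward_select(fm, _labels(y), cfg)
        assert trace.selected_markers[0] == "strong"


class TestRunCrossValidation:
    def test_structure(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=10, seed=1)
        cms = run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp"))
        assert cms.k == 10
        for t in cms.traces:
            assert 0.0 <= t.testing_accuracy <= 1.0

    def test_fixed_difference_snp_selected_everywhere(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=10, seed=1)
        cms = run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp"))
        assert cms.marker_selection_times["snp_info_0001"] == 10
        for t in cms.traces:
            assert t.selected_markers[0] == "snp_info_0001"

    def test_sample_order_invariance(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=5, seed=1)
        cfg = SelectionConfig(candidate_sets="snp")
        cms1 = run_cross_validation(g, None, labels, cv, cfg)

        order = np.random.default_rng(0).permutation(len(labels.sample_ids))
        shuffled_ids = [labels.sample_ids[i] for i in order]
        g2 = g.subset_samples(shuffled_ids)
        cms2 = run_cross_validation(g2, None, labels, cv, cfg)
        for t1, t2 in zip(cms1.traces, cms2.traces):
            assert t1.selected_markers == t2.selected_markers
            assert t1.testing_accuracy == t2.testing_accuracy

    def test_mode_requires_inputs(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=5, seed=1)
        with pytest.raises(ValueError, match="expression"):
            run_cross_validation(g, None, labels, cv, SelectionConfig(candidate_sets="snp+ge"))

    def test_ge_only_mode_ignores_genotypes(self, planted_dataset):
        g, e, labels, *_ = planted_dataset
        cv = make_cv_partition(labels, k=5, seed=1)
        cms = run_cross_validation(g, e, labels, cv, SelectionConfig(candidate_sets="ge"))
        for t in cms.traces:
            assert all(ty == "ge" for ty in t.marker_types)


def _trace(fold, markers, test_acc):
    return SelectionTrace(
        fold=fold,
        selected_markers=list(markers),
        marker_types=["snp"] * len(markers),
        training_accuracies=[1.0] * len(markers),
        ssw_ssb_values=[0.0] * len(markers),
        testing_accuracy=test_acc,
    )


class TestSelectBestModel:
    def test_highest_testing_accuracy_wins(self):
        cms = CandidateModelSet(
            [_trace(0, ["a"], 0.8), _trace(1, ["b"], 1.0), _trace(2, ["c"], 0.9)]
        )
        best, _ = select_best_model(cms)
        assert best.fold == 1

    def test_fewest_markers_breaks_tie(self):
        cms = CandidateModelSet(
            [_trace(0, ["a", "b", "c", "d", "e"], 1.0), _trace(1, ["x", "y", "z"], 1.0)]
        )
        best, _ = select_best_model(cms)
        assert best.fold == 1

    def test_cvc_breaks_remaining_tie(self):
        traces = (
            [_trace(f, ["p", "q", "r"], 1.0) for f in range(4)]
            + [_trace(4, ["x", "y", "z"], 1.0)]
        )
        cms = CandidateModelSet(traces)
        best, _ = select_best_model(cms)
        assert set(best.selected_markers) == {"p", "q", "r"}
        assert cms.set_consistency(frozenset(best.selected_markers)) == 4

    def test_fold_index_final_tie_break(self):
        cms = CandidateModelSet([_trace(1, ["a"], 1.0), _trace(0, ["b"], 1.0)])
        best, _ = select_best_model(cms)
        assert best.fold == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_best_model(CandidateModelSet([]))

    def test_report_contains_all_folds(self):
        cms = CandidateModelSet([_trace(0, ["a"], 0.5), _trace(1, ["b"], 0.6)])
        _, report = select_best_model(cms)
        assert [r["fold"] for r in report] == [0, 1]
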