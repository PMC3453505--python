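"""Stratified cross-validation partitioning and forward stepwise marker
selection.

The procedure: (1) samples of every population are randomly split over k
folds; (2) within each training set, markers are added greedily — at each
step the candidate giving the maximum increment of training accuracy wins,
ties resolved by the smaller univariate SSW/SSB of the candidate, then by
lexicographic marker ID — until the training accuracy reaches the target,
the increment falls below the threshold, or a marker cap is hit; (3) the
resulting model is scored on the held-out fold; (4) steps repeat for every
fold, giving k candidate models; (5) the best model is the one with the
highest testing accuracy, ties resolved by fewer markers, then by higher
cross-validation consistency of its marker set, then by fold index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from aimsel.fda import (
    FDAModel,
    FeatureMatrix,
    _class_codes,
    _train_accuracy_fast,
    encode_features,
    fit_fda,
    predict,
    ssw_ssb_columns,
)
from aimsel.io_formats import ExpressionMatrix, GenotypeMatrix, PopulationLabels

Mode = Literal["ge", "snp", "snp+ge"]


@dataclass
class CVPartition:
    """Per-sample fold assignment, stratified by population."""

    sample_ids: list[str]
    fold_assignment: np.ndarray  # fold index in 0..k-1 per sample
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
        if self.fold_assignment.shape != (len(self.sample_ids),):
            raise ValueError("fold assignment length mismatch")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def test_samples(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.fold_assignment) if f == fold]

    def train_samples(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.fold_assignment) if f != fold]


@dataclass
class SelectionConfig:
    """Stopping rules and candidate pool for forward selection."""

    max_markers: int | None = None
    target_accuracy: float = 1.0
    min_increment: float = 0.001
    candidate_sets: Mode = "snp+ge"
    ridge: float = 1e-8
    prescreen_top: int | None = None  # optional univariate cap, off by default

    def __post_init__(self) -> None:
        if not 0.0 < self.min_increment <= 1.0:
            raise ValueError("min_increment must be in (0, 1]")
        if not 0.0 < self.target_accuracy <= 1.0:
            raise ValueError("target_accuracy must be in (0, 1]")
        if self.max_markers is not None and self.max_markers < 1:
            raise ValueError("max_markers must be >= 1")


@dataclass
class SelectionTrace:
    """One fold's forward-selection path and its final model."""

    fold: int
    selected_markers: list[str]
    marker_types: list[str]
    training_accuracies: list[float]  # after each addition
    ssw_ssb_values: list[float]       # univariate ratio of each added marker
    final_model: FDAModel | None = None
    testing_accuracy: float | None = None

    @property
    def n_markers(self) -> int:
        return len(self.selected_markers)


@dataclass
class CandidateModelSet:
    """The k per-fold models plus cross-validation-consistency statistics."""

    traces: list[SelectionTrace]
    best_fold: int | None = None
    marker_selection_times: dict[str, int] = field(default_factory=dict)
    model_cvc: int | None = None

    @property
    def k(self) -> int:
        return len(self.traces)

    def set_consistency(self, marker_set: frozenset[str]) -> int:
        """Number of folds whose selected marker set equals ``marker_set``."""
        return sum(frozenset(t.selected_markers) == marker_set for t in self.traces)


def make_cv_partition(
    labels: PopulationLabels, k: int = 10, seed: int | None = None
) -> CVPartition:
    """Stratified random fold assignment: within every population the fold
    sizes differ by at most one. Deterministic for a fixed seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels.sample_ids), -1, dtype=int)
    lab = np.asarray(labels.labels, dtype=object)
    for pop in labels.classes:
        idx = np.flatnonzero(lab == pop)
        perm = rng.permutation(idx)
        # random fold rotation keeps overall fold sizes balanced across pops
        start = int(rng.integers(k))
        assignment[perm] = (np.arange(perm.size) + start) % k
    return CVPartition(list(labels.sample_ids), assignment, k, seed)


def _evaluate_candidates(
    values: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    current: list[int],
    candidates: np.ndarray,
    ridge: float,
) -> np.ndarray:
    """Training accuracy of current-set + each candidate (one fit per
    candidate; exhaustive by construction)."""
    accs = np.empty(candidates.size)
    base = values[:, current] if current else None
    for i, j in enumerate(candidates):
        if base is None:
            x = values[:, [j]]
        else:
            x = np.concatenate([base, values[:, [j]]], axis=1)
        accs[i] = _train_accuracy_fast(x, y, counts, ridge)
    return accs


def forward_select(
    train: FeatureMatrix,
    labels: PopulationLabels,
    cfg: SelectionConfig,
    fold: int = 0,
) -> SelectionTrace:
    """Greedy forward marker selection on an encoded training set.

    Always returns at least one marker: the first marker is measured against
    the majority-class baseline but is added even when its increment falls
    below ``min_increment``. Later candidates whose best increment is below
    the threshold are not added.
    """
    if train.n_features < 1:
        raise ValueError("need at least one candidate marker")
    if list(train.sample_ids) != list(labels.sample_ids):
        labels = labels.subset(train.sample_ids)
    _, y, counts = _class_codes(list(labels.labels))
    values = train.values
    ratios = ssw_ssb_columns(values, np.asarray(labels.labels, dtype=object))

    order = np.arange(train.n_features)
    if cfg.prescreen_top is not None and cfg.prescreen_top < order.size:
        # keep the best candidates by univariate ratio (stable in marker order)
        keep = np.argsort(ratios, kind="stable")[: cfg.prescreen_top]
        order = np.sort(keep)

    feature_ids = np.asarray(train.feature_ids, dtype=object)
    selected: list[int] = []
    acc_path: list[float] = []
    prev_acc = counts.max() / values.shape[0]  # majority-class baseline

    while True:
        remaining = np.asarray([j for j in order if j not in selected], dtype=int)
        if remaining.size == 0:
            break
        accs = _evaluate_candidates(values, y, counts, selected, remaining, cfg.ridge)
        best_acc = accs.max()
        tied = remaining[np.flatnonzero(accs >= best_acc - 1e-12)]
        if tied.size > 1:
            best_ratio = ratios[tied].min()
            tied = tied[np.flatnonzero(ratios[tied] <= best_ratio + 1e-12)]
        if tied.size > 1:
            tied = np.asarray(sorted(tied, key=lambda j: str(feature_ids[j])))
        j_best = int(tied[0])
        increment = best_acc - prev_acc
        if selected and increment < cfg.min_increment:
            break
        selected.append(j_best)
        acc_path.append(float(best_acc))
        prev_acc = best_acc
        if best_acc >= cfg.target_accuracy - 1e-12:
            break
        if cfg.max_markers is not None and len(selected) >= cfg.max_markers:
            break

    return SelectionTrace(
        fold=fold,
        selected_markers=[str(feature_ids[j]) for j in selected],
        marker_types=[train.feature_types[j] for j in selected],
        training_accuracies=acc_path,
        ssw_ssb_values=[float(ratios[j]) for j in selected],
    )


def _spawn_seeds(seed: int | None, k: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(k)


def run_cross_validation(
    g: GenotypeMatrix | None,
    e: ExpressionMatrix | None,
    labels: PopulationLabels,
    cv: CVPartition,
    cfg: SelectionConfig,
) -> CandidateModelSet:
    """Run the per-fold forward selection and assemble the candidate set.

    For every fold: encode features on the training samples (missing calls
    imputed with training means), select markers, fit the final model, and
    score the held-out fold. Inputs are expected to be QC-filtered already.
    """
    if cfg.candidate_sets == "snp":
        e = None
    elif cfg.candidate_sets == "ge":
        g = None
    if cfg.candidate_sets in ("snp", "snp+ge") and g is None:
        raise ValueError(f"mode {cfg.candidate_sets!r} requires genotype data")
    if cfg.candidate_sets in ("ge", "snp+ge") and e is None:
        raise ValueError(f"mode {cfg.candidate_sets!r} requires expression data")

    traces: list[SelectionTrace] = []
    for fold in range(cv.k):
        train_ids = cv.train_samples(fold)
        test_ids = cv.test_samples(fold)
        g_tr = g.subset_samples(train_ids) if g is not None else None
        e_tr = e.subset_samples(train_ids) if e is not None else None
        train_fm = encode_features(g_tr, e_tr)
        train_labels = labels.subset(train_ids)
        trace = forward_select(train_fm, train_labels, cfg, fold=fold)

        sel_fm = FeatureMatrix(
            train_fm.sample_ids,
            trace.selected_markers,
            train_fm.columns(trace.selected_markers),
            trace.marker_types,
            {m: train_fm.imputation_values[m] for m in trace.selected_markers},
        )
        model = fit_fda(sel_fm, train_labels, ridge=cfg.ridge)
        trace.final_model = model

        if test_ids:
            g_te = g.subset_samples(test_ids) if g is not None else None
            e_te = e.subset_samples(test_ids) if e is not None else None
            test_fm = encode_features(g_te, e_te, impute_from=train_fm.imputation_values)
            result = predict(model, test_fm, labels.subset(test_ids))
            trace.testing_accuracy = result.accuracy
        else:
            trace.testing_accuracy = float("nan")
        traces.append(trace)

    cms = CandidateModelSet(traces=traces)
    times: dict[str, int] = {}
    for t in traces:
        for m in t.selected_markers:
            times[m] = times.get(m, 0) + 1
    cms.marker_selection_times = times
    best, _ = select_best_model(cms)
    cms.best_fold = best.fold
    cms.model_cvc = cms.set_consistency(frozenset(best.selected_markers))
    return cms


def select_best_model(c: CandidateModelSet) -> tuple[SelectionTrace, list[dict]]:
    """Choose the best fold model.

    Criteria, in order: highest testing accuracy; fewest markers; highest
    cross-validation consistency of the trace's marker set; lowest fold
    index. Also returns a per-fold report of all criteria.
    """
    if not c.traces:
        raise ValueError("empty candidate model set")
    report = []
    keyed = []
    for t in c.traces:
        cvc = c.set_consistency(frozenset(t.selected_markers))
        acc = t.testing_accuracy if t.testing_accuracy == t.testing_accuracy else -1.0
        keyed.append(((-acc, t.n_markers, -cvc, t.fold), t))
        report.append(
            {
                "fold": t.fold,
                "testing_accuracy": t.testing_accuracy,
                "n_markers": t.n_markers,
                "cvc": cvc,
                "markers": ";".join(t.selected_markers),
            }
        )
    best = min(keyed, key=lambda kt: kt[0])[1]
    return best, report
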