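"""End-to-end pipeline and tabular report bundle.

The tables are the contract; plots (overlay accuracy curves, parallel
coordinates, box-whisker, MDS scatter) are optional best-effort renderings
of the same tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import aimsel
from aimsel.fda import FeatureMatrix, encode_features, fit_fda, predict
from aimsel.io_formats import (
    CODE_TO_CALL,
    ExpressionMatrix,
    GenotypeMatrix,
    PopulationLabels,
    align_to_labels,
    attach_probe_annotation,
    read_expression,
    read_genotypes_tabular,
    read_genotypes_vcf,
    read_labels,
    read_probe_annotation,
)
from aimsel.qc import QCReport, SNPQCConfig, filter_probes, filter_snps
from aimsel.selection import (
    CandidateModelSet,
    CVPartition,
    SelectionConfig,
    make_cv_partition,
    run_cross_validation,
    select_best_model,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    genotypes: str | None = None
    genotypes_vcf: str | None = None
    expression: str | None = None
    labels: str | None = None
    probe_annotation: str | None = None
    snp_annotation: str | None = None
    mode: str = "snp+ge"
    folds: int = 10
    seed: int = 0
    qc: SNPQCConfig = field(default_factory=SNPQCConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    skip_qc: bool = False
    out_dir: str = "aimsel_out"
    plots: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("ge", "snp", "snp+ge"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.selection.candidate_sets = self.mode  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "config" in raw:  # accept a run manifest directly
            raw = raw["config"]
        qc = SNPQCConfig(**raw.pop("qc", {}))
        sel = SelectionConfig(**raw.pop("selection", {}))
        return cls(qc=qc, selection=sel, **raw)

    def to_dict(self) -> dict:
        return {
            "genotypes": self.genotypes,
            "genotypes_vcf": self.genotypes_vcf,
            "expression": self.expression,
            "labels": self.labels,
            "probe_annotation": self.probe_annotation,
            "snp_annotation": self.snp_annotation,
            "mode": self.mode,
            "folds": self.folds,
            "seed": self.seed,
            "skip_qc": self.skip_qc,
            "out_dir": self.out_dir,
            "plots": self.plots,
            "qc": vars(self.qc).copy(),
            "selection": {
                k: v for k, v in vars(self.selection).items()
            },
        }


@dataclass
class ReportBundle:
    """All tabular outputs of one pipeline run."""

    overlay: pd.DataFrame            # fold x step train/test accuracy curves
    parallel_coordinates: pd.DataFrame
    mds: pd.DataFrame                # sample coordinates on best-model markers
    marker_distribution: pd.DataFrame
    misclassification: pd.DataFrame
    misclassification_by_step: pd.DataFrame
    marker_impact: pd.DataFrame
    candidate_models: pd.DataFrame
    best_model_summary: dict
    qc_report: QCReport | None = None
    candidate_set: CandidateModelSet | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "overlay": self.overlay,
            "parallel_coordinates": self.parallel_coordinates,
            "mds": self.mds,
            "marker_distribution": self.marker_distribution,
            "misclassification": self.misclassification,
            "misclassification_by_step": self.misclassification_by_step,
            "marker_impact": self.marker_impact,
            "candidate_models": self.candidate_models,
        }


# ---------------------------------------------------------------------------
# individual reports
# ---------------------------------------------------------------------------

def marker_impact_report(c: CandidateModelSet) -> pd.DataFrame:
    """Per selected marker: selecting folds, count, and selection steps."""
    rows = []
    steps: dict[str, list[tuple[int, int]]] = {}
    for t in c.traces:
        for step, m in enumerate(t.selected_markers, start=1):
            steps.setdefault(m, []).append((t.fold, step))
    for marker in sorted(steps):
        folds = steps[marker]
        rows.append(
            {
                "marker_id": marker,
                "selection_times": len(folds),
                "folds": ";".join(str(f) for f, _ in folds),
                "steps": ";".join(str(s) for _, s in folds),
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "selection_times", "folds", "steps"])


def misclassification_report(
    c: CandidateModelSet,
    cv: CVPartition,
    labels: PopulationLabels,
    g: GenotypeMatrix | None,
    e: ExpressionMatrix | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample misclassification proportions over the CV, plus per-step
    aggregate misclassification per fold.

    Each final fold model is applied to its training and testing samples;
    per-step rates refit the model on every prefix of the selected panel.
    """
    label_map = labels.as_dict()
    test_err: dict[str, list[int]] = {s: [] for s in cv.sample_ids}
    train_err: dict[str, list[int]] = {s: [] for s in cv.sample_ids}
    step_rows = []
    for t in c.traces:
        fold = t.fold
        train_ids = cv.train_samples(fold)
        test_ids = cv.test_samples(fold)
        g_tr = g.subset_samples(train_ids) if g is not None else None
        e_tr = e.subset_samples(train_ids) if e is not None else None
        train_fm = encode_features(g_tr, e_tr)
        test_fm = None
        if test_ids:
            g_te = g.subset_samples(test_ids) if g is not None else None
            e_te = e.subset_samples(test_ids) if e is not None else None
            test_fm = encode_features(g_te, e_te, impute_from=train_fm.imputation_values)
        train_labels = labels.subset(train_ids)
        for step in range(1, t.n_markers + 1):
            prefix = t.selected_markers[:step]
            fm = FeatureMatrix(
                train_fm.sample_ids,
                prefix,
                train_fm.columns(prefix),
                t.marker_types[:step],
                {m: train_fm.imputation_values[m] for m in prefix},
            )
            model = fit_fda(fm, train_labels) if step < t.n_markers else t.final_model
            tr_res = predict(model, fm if step < t.n_markers else train_fm, train_labels)
            te_acc = float("nan")
            if test_fm is not None:
                te_res = predict(model, test_fm, labels.subset(test_ids))
                te_acc = te_res.accuracy
            step_rows.append(
                {
                    "fold": fold,
                    "step": step,
                    "marker_id": t.selected_markers[step - 1],
                    "train_misclassification": 1.0 - tr_res.accuracy,
                    "test_misclassification": (
                        1.0 - te_acc if te_acc == te_acc else float("nan")
                    ),
                }
            )
            if step == t.n_markers:
                for s, pred_label in zip(tr_res.sample_ids, tr_res.predicted_label):
                    train_err[s].append(int(pred_label != label_map[s]))
                if test_fm is not None:
                    for s, pred_label in zip(te_res.sample_ids, te_res.predicted_label):
                        test_err[s].append(int(pred_label != label_map[s]))

    rows = []
    for s in cv.sample_ids:
        te = test_err[s]
        tr = train_err[s]
        rows.append(
            {
                "sample_id": s,
                "label": label_map[s],
                "n_test_folds": len(te),
                "test_misclassification": (sum(te) / len(te)) if te else float("nan"),
                "n_train_folds": len(tr),
                "train_misclassification": (sum(tr) / len(tr)) if tr else float("nan"),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(step_rows)


def genotype_frequency_report(
    markers: list[str],
    g: GenotypeMatrix,
    labels: PopulationLabels,
    pairs: bool = False,
) -> pd.DataFrame:
    """Per-population genotype frequencies of selected SNPs.

    With ``pairs=True``, each pair of markers yields the frequencies of the
    nine genotype combinations; rows sum to 1 over non-missing calls.
    """
    lab = np.asarray(labels.labels, dtype=object)
    snp_markers = [m for m in markers if m in set(g.marker_ids)]
    gsub = g.subset_markers(snp_markers) if snp_markers else None
    rows = []
    if gsub is None:
        return pd.DataFrame(rows)
    if not pairs:
        for j, m in enumerate(snp_markers):
            for pop in labels.classes:
                col = gsub.calls[lab == pop, j]
                col = col[col >= 0]
                n = col.size
                freqs = {
                    CODE_TO_CALL[c]: (np.count_nonzero(col == c) / n if n else float("nan"))
                    for c in (0, 1, 2)
                }
                rows.append({"marker_id": m, "population": pop, "n": n, **freqs})
        return pd.DataFrame(rows)
    for (j1, m1), (j2, m2) in combinations(enumerate(snp_markers), 2):
        for pop in labels.classes:
            c1 = gsub.calls[lab == pop, j1]
            c2 = gsub.calls[lab == pop, j2]
            ok = (c1 >= 0) & (c2 >= 0)
            c1, c2 = c1[ok], c2[ok]
            n = c1.size
            row = {"marker_1": m1, "marker_2": m2, "population": pop, "n": n}
            for a in (0, 1, 2):
                for b in (0, 1, 2):
                    key = f"{CODE_TO_CALL[a]}/{CODE_TO_CALL[b]}"
                    row[key] = (
                        np.count_nonzero((c1 == a) & (c2 == b)) / n if n else float("nan")
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def expression_summary_report(
    probes: list[str], e: ExpressionMatrix, labels: PopulationLabels
) -> pd.DataFrame:
    """Per-population summary statistics for selected expression probes."""
    lab = np.asarray(labels.labels, dtype=object)
    keep = [p for p in probes if p in set(e.probe_ids)]
    rows = []
    if not keep:
        return pd.DataFrame(rows)
    esub = e.subset_probes(keep)
    for j, p in enumerate(keep):
        for pop in labels.classes:
            v = esub.values[lab == pop, j]
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "probe_id": p,
                    "population": pop,
                    "n": v.size,
                    "mean": float(v.mean()) if v.size else float("nan"),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                    "median": float(np.median(v)) if v.size else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def mds_coordinates(fm: FeatureMatrix) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on per-feature-standardized
    markers; top-2 coordinates, sign fixed so the first nonzero loading of
    each axis is positive."""
    n = fm.n_samples
    if n < 2 or fm.n_features < 1:
        logger.warning("degenerate MDS input; returning zero coordinates")
        return pd.DataFrame(
            {"sample_id": fm.sample_ids, "mds1": np.zeros(n), "mds2": np.zeros(n)}
        )
    x = np.asarray(fm.values, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    xs = (x - mu) / sd
    sq = (xs ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (xs @ xs.T)
    np.clip(d2, 0.0, None, out=d2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    coords = np.zeros((n, 2))
    for axis, i in enumerate(order):
        lam = max(w[i], 0.0)
        col = v[:, i] * np.sqrt(lam)
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            col = -col
        coords[:, axis] = col
    return pd.DataFrame(
        {"sample_id": fm.sample_ids, "mds1": coords[:, 0], "mds2": coords[:, 1]}
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig):
    g = e = None
    if cfg.mode in ("snp", "snp+ge"):
        if cfg.genotypes:
            g = read_genotypes_tabular(cfg.genotypes)
        elif cfg.genotypes_vcf:
            g = read_genotypes_vcf(cfg.genotypes_vcf)
        else:
            raise ValueError(f"mode {cfg.mode!r} requires genotype input")
        if cfg.snp_annotation and g is not None:
            ann = read_probe_annotation(cfg.snp_annotation)
            chrom = ann["chrom"].reindex(g.marker_ids).fillna("")
            g.chrom = chrom.to_numpy(dtype=object)
    if cfg.mode in ("ge", "snp+ge"):
        if not cfg.expression:
            raise ValueError(f"mode {cfg.mode!r} requires expression input")
        e = read_expression(cfg.expression)
        if cfg.probe_annotation:
            e = attach_probe_annotation(e, read_probe_annotation(cfg.probe_annotation))
    if not cfg.labels:
        raise ValueError("a label file is required")
    labels = read_labels(cfg.labels)
    return g, e, labels


def run_pipeline(
    cfg: RunConfig,
    g: GenotypeMatrix | None = None,
    e: ExpressionMatrix | None = None,
    labels: PopulationLabels | None = None,
) -> ReportBundle:
    """QC -> encoding -> CV forward selection -> best model -> reports.

    Inputs may be passed in memory; otherwise they are loaded from the paths
    in ``cfg``. All randomness derives from ``cfg.seed``.
    """
    if labels is None:
        g, e, labels = _load_inputs(cfg)
    if cfg.mode in ("snp", "snp+ge") and g is None:
        raise ValueError(f"mode {cfg.mode!r} requires genotype data")
    if cfg.mode in ("ge", "snp+ge") and e is None:
        raise ValueError(f"mode {cfg.mode!r} requires expression data")
    labels, g, e = align_to_labels(labels, g, e)

    qc_report = QCReport()
    if not cfg.skip_qc:
        if g is not None:
            cfg.qc.seed = cfg.qc.seed if cfg.qc.seed is not None else cfg.seed
            g, snp_rep = filter_snps(g, labels, cfg.qc)
            qc_report.snp_records = snp_rep.snp_records
            qc_report.counts.update(snp_rep.counts)
        if e is not None and e.probe_annotation is not None:
            e, probe_rep = filter_probes(e)
            qc_report.probe_records = probe_rep.probe_records
            qc_report.counts.update(probe_rep.counts)

    cv = make_cv_partition(labels, k=cfg.folds, seed=cfg.seed)
    cms = run_cross_validation(
        g if cfg.mode != "ge" else None,
        e if cfg.mode != "snp" else None,
        labels,
        cv,
        cfg.selection,
    )
    best, fold_report = select_best_model(cms)

    g_used = g if cfg.mode != "ge" else None
    e_used = e if cfg.mode != "snp" else None
    misclass, by_step = misclassification_report(cms, cv, labels, g_used, e_used)
    overlay = by_step.rename(
        columns={
            "train_misclassification": "train_accuracy",
            "test_misclassification": "test_accuracy",
        }
    )
    overlay["train_accuracy"] = 1.0 - overlay["train_accuracy"]
    overlay["test_accuracy"] = 1.0 - overlay["test_accuracy"]

    parallel = pd.DataFrame(
        [
            {
                "fold": t.fold,
                "n_markers": t.n_markers,
                "train_accuracy": t.training_accuracies[-1] if t.training_accuracies else float("nan"),
                "test_accuracy": t.testing_accuracy,
            }
            for t in cms.traces
        ]
    )

    full_fm = encode_features(g_used, e_used)
    best_fm = FeatureMatrix(
        full_fm.sample_ids,
        best.selected_markers,
        full_fm.columns(best.selected_markers),
        best.marker_types,
        {m: full_fm.imputation_values[m] for m in best.selected_markers},
    )
    mds = mds_coordinates(best_fm)
    mds["label"] = [labels.as_dict()[s] for s in mds["sample_id"]]

    dist_frames = []
    if g_used is not None:
        snp_freq = genotype_frequency_report(best.selected_markers, g_used, labels)
        if not snp_freq.empty:
            snp_freq.insert(0, "kind", "snp")
            dist_frames.append(snp_freq)
    if e_used is not None:
        ge_sum = expression_summary_report(best.selected_markers, e_used, labels)
        if not ge_sum.empty:
            ge_sum.insert(0, "kind", "ge")
            ge_sum = ge_sum.rename(columns={"probe_id": "marker_id"})
            dist_frames.append(ge_sum)
    marker_distribution = (
        pd.concat(dist_frames, ignore_index=True) if dist_frames else pd.DataFrame()
    )

    bundle = ReportBundle(
        overlay=overlay,
        parallel_coordinates=parallel,
        mds=mds,
        marker_distribution=marker_distribution,
        misclassification=misclass,
        misclassification_by_step=by_step,
        marker_impact=marker_impact_report(cms),
        candidate_models=pd.DataFrame(fold_report),
        best_model_summary={
            "best_fold": best.fold,
            "markers": best.selected_markers,
            "marker_types": best.marker_types,
            "testing_accuracy": best.testing_accuracy,
            "training_accuracy": (
                best.training_accuracies[-1] if best.training_accuracies else float("nan")
            ),
            "cvc": cms.model_cvc,
        },
        qc_report=qc_report,
        candidate_set=cms,
    )
    return bundle


def _fmt_float(x) -> str:
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_bundle(bundle: ReportBundle, cfg: RunConfig, out_dir: str | Path) -> None:
    """Write every table (TSV, one-line header), the best-model summary,
    the QC report, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables().items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.12g")
    if bundle.qc_report is not None:
        qc = bundle.qc_report
        if not qc.snp_records.empty:
            qc.snp_records.to_csv(out / "qc_report_snp.tsv", sep="\t", float_format="%.12g")
        if not qc.probe_records.empty:
            qc.probe_records.to_csv(out / "qc_report_probes.tsv", sep="\t")
    with open(out / "best_model.txt", "w") as fh:
        for key, val in bundle.best_model_summary.items():
            if isinstance(val, list):
                val = ";".join(str(v) for v in val)
            fh.write(f"{key}\t{_fmt_float(val)}\n")
    if bundle.candidate_set is not None:
        rows = []
        for t in bundle.candidate_set.traces:
            for step, (m, acc, r) in enumerate(
                zip(t.selected_markers, t.training_accuracies, t.ssw_ssb_values), start=1
            ):
                rows.append(
                    {
                        "fold": t.fold,
                        "step": step,
                        "marker_id": m,
                        "type": t.marker_types[step - 1],
                        "train_accuracy": acc,
                        "ssw_ssb": r,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "selection_trace.tsv", sep="\t", index=False,
                                  float_format="%.12g")
        times = bundle.candidate_set.marker_selection_times
        pd.DataFrame(
            sorted(times.items()), columns=["marker_id", "selection_times"]
        ).to_csv(out / "selection_times.tsv", sep="\t", index=False)
    manifest = {
        "aimsel_version": aimsel.__version__,
        "config": cfg.to_dict(),
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    if cfg.plots:
        try:
            render_plots(bundle, out)
        except Exception as exc:  # plots are best-effort
            logger.warning("plot rendering failed: %s", exc)


def render_plots(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Optional matplotlib renderings of the report tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig, ax = plt.subplots(figsize=(6, 4))
    for fold, grp in bundle.overlay.groupby("fold"):
        ax.plot(grp["step"], grp["train_accuracy"], alpha=0.6)
        ax.plot(grp["step"], grp["test_accuracy"], alpha=0.6, linestyle="--")
    ax.set_xlabel("markers in model")
    ax.set_ylabel("accuracy")
    fig.savefig(out / "overlay.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, grp in bundle.mds.groupby("label"):
        ax.scatter(grp["mds1"], grp["mds2"], label=str(lab), s=12)
    ax.legend()
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.savefig(out / "mds.png", dpi=100)
    plt.close(fig)
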