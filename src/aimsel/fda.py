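"""Flexible discriminant analysis by optimal scoring with a linear
regression basis.

The class-indicator matrix is regressed on centered features (with a small
ridge term on the Gram matrix for rank safety); optimal scores come from the
eigen-decomposition of the indicator/fitted-value cross-product, yielding up
to K-1 discriminant directions. With a linear basis this is equivalent to
linear discriminant analysis: classification is nearest class centroid in
the discriminant space after whitening by the pooled within-class
covariance of the discriminant variates (equal class priors). Prediction
ties are broken by sorted class-label order.

Genotypes are encoded additively (AA=0, AB=1, BB=2, count of the
alphabetically later allele); missing calls are imputed with the
training-set per-feature mean, which the fitted model retains for
test-time use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from aimsel.io_formats import (
    CALL_TO_CODE,
    ExpressionMatrix,
    GenotypeMatrix,
    PopulationLabels,
)

_MISS = CALL_TO_CODE["MISSING"]

#: eigenvalues of the optimal-scoring problem below this are treated as zero
_EIG_TOL = 1e-9


@dataclass
class FeatureMatrix:
    """Samples x features real matrix after encoding.

    ``feature_types`` tags each column ``"snp"`` or ``"ge"``;
    ``imputation_values`` records the per-feature mean used (or available)
    for filling missing genotype calls.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_types: list[str]
    imputation_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("feature matrix shape mismatch")
        if len(self.feature_types) != len(self.feature_ids):
            raise ValueError("feature_types length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def columns(self, feature_ids: list[str]) -> np.ndarray:
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            cols = [idx[f] for f in feature_ids]
        except KeyError as exc:
            raise KeyError(f"unknown feature {exc.args[0]!r}") from None
        return self.values[:, cols]


@dataclass
class FDAModel:
    """Fitted optimal-scoring discriminant.

    ``coefficient_matrix`` maps centered features to the whitened
    discriminant space; ``class_centroids`` are training class means there.
    A degenerate fit (no usable discriminant direction) predicts
    ``majority_label`` for every sample.
    """

    feature_ids: list[str]
    class_labels: list[str]
    coefficient_matrix: np.ndarray  # (p, d)
    optimal_scores: np.ndarray      # (K, d)
    class_centroids: np.ndarray     # (K, d)
    training_accuracy: float
    imputation_values: dict[str, float]
    feature_means: np.ndarray       # (p,) centering offsets
    ridge: float
    majority_label: str | None = None

    @property
    def n_dimensions(self) -> int:
        return self.coefficient_matrix.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project raw (encoded, imputed) feature rows to discriminant space."""
        return (np.asarray(x, dtype=float) - self.feature_means) @ self.coefficient_matrix

    def predict_values(self, x: np.ndarray) -> np.ndarray:
        """Predicted labels for raw encoded feature rows (model's columns)."""
        x = np.asarray(x, dtype=float)
        if self.majority_label is not None or self.n_dimensions == 0:
            lab = self.majority_label or self.class_labels[0]
            return np.full(x.shape[0], lab, dtype=object)
        z = self.transform(x)
        d2 = ((z[:, None, :] - self.class_centroids[None, :, :]) ** 2).sum(axis=2)
        # argmin takes the first minimum; class_labels is sorted, so ties
        # resolve to the earliest label in sorted order
        best = np.argmin(np.round(d2, 9), axis=1)
        return np.asarray([self.class_labels[k] for k in best], dtype=object)


@dataclass
class ClassificationResult:
    sample_ids: list[str]
    true_label: list[str]
    predicted_label: list[str]

    @property
    def accuracy(self) -> float:
        n = len(self.sample_ids)
        hits = sum(t == p for t, p in zip(self.true_label, self.predicted_label))
        return hits / n if n else float("nan")


def encode_genotype_column(calls: np.ndarray) -> np.ndarray:
    """Additive encoding of one marker: AA->0, AB->1, BB->2, MISSING->NaN."""
    out = np.asarray(calls, dtype=float)
    out = out.copy()
    out[out == _MISS] = np.nan
    return out


def encode_features(
    g: GenotypeMatrix | None = None,
    e: ExpressionMatrix | None = None,
    impute_from: "FDAModel | dict[str, float] | None" = None,
) -> FeatureMatrix:
    """Build the numeric feature matrix from genotype and/or expression data.

    SNP calls are encoded 0/1/2; missing calls (NaN after encoding) are
    imputed with the per-feature mean — taken from ``impute_from`` (a fitted
    model or an explicit mapping) when provided, otherwise from the observed
    values of the column itself (training-time behaviour).
    """
    if g is None and e is None:
        raise ValueError("need at least one of genotypes/expression")
    sample_ids = None
    blocks: list[np.ndarray] = []
    feature_ids: list[str] = []
    feature_types: list[str] = []
    if g is not None:
        sample_ids = list(g.sample_ids)
        enc = g.calls.astype(float)
        enc[g.calls == _MISS] = np.nan
        blocks.append(enc)
        feature_ids.extend(g.marker_ids)
        feature_types.extend(["snp"] * g.n_markers)
    if e is not None:
        if sample_ids is None:
            sample_ids = list(e.sample_ids)
        elif list(e.sample_ids) != sample_ids:
            raise ValueError("genotype and expression sample sets are not aligned")
        blocks.append(e.values.astype(float))
        feature_ids.extend(e.probe_ids)
        feature_types.extend(["ge"] * e.n_probes)
    values = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0].copy()

    given: dict[str, float] = {}
    if isinstance(impute_from, FDAModel):
        given = impute_from.imputation_values
    elif isinstance(impute_from, dict):
        given = impute_from

    imputation: dict[str, float] = {}
    col_missing = np.isnan(values)
    for j, fid in enumerate(feature_ids):
        col = values[:, j]
        miss = col_missing[:, j]
        if fid in given:
            fill = given[fid]
        else:
            observed = col[~miss]
            if observed.size == 0:
                raise ValueError(f"feature {fid!r} is entirely missing")
            fill = float(observed.mean())
        imputation[fid] = fill
        if miss.any():
            col[miss] = fill
    return FeatureMatrix(sample_ids, feature_ids, values, feature_types, imputation)


def _class_codes(labels: list[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    classes = sorted(set(labels))
    lut = {c: k for k, c in enumerate(classes)}
    y = np.asarray([lut[l] for l in labels], dtype=np.intp)
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    return classes, y, counts


def _fit_core(
    x: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Optimal-scoring fit on encoded data.

    Returns (feature_means, coefficient_matrix, optimal_scores, centroids)
    in the whitened discriminant space, or None when the fit is degenerate
    (no direction with positive canonical correlation).
    """
    n, p = x.shape
    k = counts.size
    mu = x.mean(axis=0)
    xc = x - mu
    # indicator cross-products without materializing the one-hot matrix
    xty = np.zeros((p, k))
    np.add.at(xty.T, y, xc)
    gram = xc.T @ xc
    if ridge:
        gram = gram + ridge * np.eye(p)
    try:
        b = scipy.linalg.solve(gram, xty, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError):
        b = np.linalg.lstsq(gram, xty, rcond=None)[0]
    m = xty.T @ b  # K x K: Y' Xc (G)^-1 Xc' Y
    inv_sqrt = 1.0 / np.sqrt(counts)
    s = m * inv_sqrt[:, None] * inv_sqrt[None, :]
    # deflate the trivial constant-score direction
    v0 = np.sqrt(counts / n)
    s = s - np.outer(v0, v0 @ s) - np.outer(s @ v0, v0) + np.outer(v0, v0) * (v0 @ s @ v0)
    s = (s + s.T) / 2.0
    w, v = np.linalg.eigh(s)
    order = np.argsort(w)[::-1]
    keep = [i for i in order[: min(k - 1, p)] if w[i] > _EIG_TOL]
    if not keep:
        return None
    theta = np.sqrt(n) * (v[:, keep] * inv_sqrt[:, None])  # K x d
    a = b @ theta  # p x d
    z = xc @ a
    centroids = np.zeros((k, z.shape[1]))
    np.add.at(centroids, y, z)
    centroids /= counts[:, None]
    resid = z - centroids[y]
    dof = max(n - k, 1)
    within = resid.T @ resid / dof
    d = within.shape[0]
    within = within + (1e-12 * max(np.trace(within) / d, 1.0)) * np.eye(d)
    chol = np.linalg.cholesky(within)
    # whiten so nearest-centroid distance is Mahalanobis w.r.t. within-class cov
    a = scipy.linalg.solve_triangular(chol, a.T, lower=True).T
    centroids = scipy.linalg.solve_triangular(chol, centroids.T, lower=True).T
    return mu, a, theta, centroids


def _train_accuracy_fast(
    x: np.ndarray, y: np.ndarray, counts: np.ndarray, ridge: float
) -> float:
    """Training accuracy of the optimal-scoring fit, minimal overhead
    (used per-candidate inside forward selection)."""
    fit = _fit_core(x, y, counts, ridge)
    n = x.shape[0]
    if fit is None:
        return counts.max() / n
    mu, a, _, centroids = fit
    z = (x - mu) @ a
    d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.argmin(np.round(d2, 9), axis=1)
    return float(np.count_nonzero(pred == y) / n)


def fit_fda(
    x: FeatureMatrix,
    labels: PopulationLabels,
    ridge: float = 1e-8,
) -> FDAModel:
    """Fit the optimal-scoring discriminant on an encoded feature matrix.

    Raises when there are fewer samples than classes. A feature set with no
    discriminating direction (e.g. all features constant) yields a
    degenerate model that predicts the majority class.
    """
    if list(x.sample_ids) != list(labels.sample_ids):
        labels = labels.subset(x.sample_ids)
    classes, y, counts = _class_codes(list(labels.labels))
    n = x.n_samples
    if n < len(classes):
        raise ValueError(f"need at least {len(classes)} samples, got {n}")
    if x.n_features < 1:
        raise ValueError("need at least one feature")

    fit = _fit_core(x.values, y, counts, ridge)
    if fit is None:
        # majority class; ties on count resolve to earliest sorted label
        maj = classes[int(np.argmax(counts))]
        model = FDAModel(
            feature_ids=list(x.feature_ids),
            class_labels=classes,
            coefficient_matrix=np.zeros((x.n_features, 0)),
            optimal_scores=np.zeros((len(classes), 0)),
            class_centroids=np.zeros((len(classes), 0)),
            training_accuracy=float(counts.max() / n),
            imputation_values={f: x.imputation_values[f] for f in x.feature_ids},
            feature_means=x.values.mean(axis=0),
            ridge=ridge,
            majority_label=maj,
        )
        return model
    mu, a, theta, centroids = fit
    model = FDAModel(
        feature_ids=list(x.feature_ids),
        class_labels=classes,
        coefficient_matrix=a,
        optimal_scores=theta,
        class_centroids=centroids,
        training_accuracy=0.0,
        imputation_values={f: x.imputation_values[f] for f in x.feature_ids},
        feature_means=mu,
        ridge=ridge,
    )
    pred = model.predict_values(x.values)
    model.training_accuracy = float(
        np.count_nonzero(pred == np.asarray(labels.labels, dtype=object)) / n
    )
    return model


def predict(
    m: FDAModel,
    x: FeatureMatrix,
    true_labels: PopulationLabels | None = None,
) -> ClassificationResult:
    """Classify samples in ``x`` with a fitted model.

    ``x`` must contain all of the model's features (extra columns are
    ignored); its missing values should already have been imputed via
    ``encode_features(..., impute_from=m)``.
    """
    values = x.columns(m.feature_ids)
    pred = m.predict_values(values)
    truth = ["" for _ in x.sample_ids]
    if true_labels is not None:
        d = true_labels.as_dict()
        truth = [d[s] for s in x.sample_ids]
    return ClassificationResult(list(x.sample_ids), truth, list(pred))


def ssw_ssb(values: np.ndarray, labels: list[str] | np.ndarray) -> float:
    """Within- over between-population sum-of-squares ratio for one feature.

    Smaller is more discriminative. Returns ``inf`` when the between-group
    sum of squares is zero (feature constant across group means).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("values/labels length mismatch")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    grand = values.mean()
    ssw = 0.0
    ssb = 0.0
    for c in classes:
        grp = values[labels == c]
        gm = grp.mean()
        ssw += float(((grp - gm) ** 2).sum())
        ssb += grp.size * (gm - grand) ** 2
    if ssb <= 0.0:
        return float("inf")
    return ssw / ssb


def ssw_ssb_columns(values: np.ndarray, labels: list[str] | np.ndarray) -> np.ndarray:
    """Vectorized :func:`ssw_ssb` over the columns of a feature matrix."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    grand = x.mean(axis=0)
    ssw = np.zeros(x.shape[1])
    ssb = np.zeros(x.shape[1])
    for c in classes:
        grp = x[labels == c]
        gm = grp.mean(axis=0)
        ssw += ((grp - gm) ** 2).sum(axis=0)
        ssb += grp.shape[0] * (gm - grand) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ssb > 0.0, ssw / np.where(ssb > 0.0, ssb, 1.0), np.inf)
    return ratio


# ---------------------------------------------------------------------------
# plain-text model serialization
# ---------------------------------------------------------------------------

def save_model(m: FDAModel, path: str | Path) -> None:
    """Write a model as a plain-text key=value + matrix file."""
    with open(Path(path), "w") as fh:
        fh.write("format=aimsel-fda-model-v1\n")
        fh.write(f"ridge={m.ridge!r}\n")
        fh.write(f"training_accuracy={m.training_accuracy!r}\n")
        fh.write(f"majority_label={m.majority_label or ''}\n")
        fh.write("classes=" + "\t".join(m.class_labels) + "\n")
        fh.write("features=" + "\t".join(m.feature_ids) + "\n")
        fh.write("imputation=" + "\t".join(repr(float(m.imputation_values[f])) for f in m.feature_ids) + "\n")
        fh.write("feature_means=" + "\t".join(repr(float(v)) for v in m.feature_means) + "\n")
        for name, mat in (
            ("coefficient_matrix", m.coefficient_matrix),
            ("optimal_scores", m.optimal_scores),
            ("class_centroids", m.class_centroids),
        ):
            fh.write(f"[{name} {mat.shape[0]} {mat.shape[1]}]\n")
            for row in mat:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_model(path: str | Path) -> FDAModel:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "format=aimsel-fda-model-v1":
        raise ValueError(f"{path} is not an aimsel model file")
    kv: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("["):
        key, _, val = lines[i].partition("=")
        kv[key] = val
        i += 1
    mats: dict[str, np.ndarray] = {}
    while i < len(lines):
        header = lines[i].strip("[]").split()
        name, rows, cols = header[0], int(header[1]), int(header[2])
        block = lines[i + 1 : i + 1 + rows]
        mat = np.array(
            [[float(v) for v in row.split("\t")] for row in block] if rows else []
        ).reshape(rows, cols)
        mats[name] = mat
        i += 1 + rows
    features = kv["features"].split("\t") if kv["features"] else []
    return FDAModel(
        feature_ids=features,
        class_labels=kv["classes"].split("\t"),
        coefficient_matrix=mats["coefficient_matrix"],
        optimal_scores=mats["optimal_scores"],
        class_centroids=mats["class_centroids"],
        training_accuracy=float(kv["training_accuracy"]),
        imputation_values=dict(
            zip(features, [float(v) for v in kv["imputation"].split("\t")] if kv["imputation"] else [])
        ),
        feature_means=np.array([float(v) for v in kv["feature_means"].split("\t")]),
        ridge=float(kv["ridge"]),
        majority_label=kv["majority_label"] or None,
    )
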