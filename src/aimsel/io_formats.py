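"""On-disk representations: genotype matrices (tabular and VCF), expression
matrices, population labels, probe/marker annotation, and report tables.

Genotype calls are kept categorical throughout (``AA``, ``AB``, ``BB``,
``MISSING``); numeric encoding happens only in :mod:`aimsel.fda`. Internally
the call table is an int8 code matrix using :data:`CALL_TO_CODE`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: int8 codes for the four genotype categories.
CALL_TO_CODE = {"AA": 0, "AB": 1, "BB": 2, "MISSING": -1}
CODE_TO_CALL = {v: k for k, v in CALL_TO_CODE.items()}

#: the literal missing token in tabular genotype files
MISSING_TOKEN = "NA"

SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "chrX", "chrY", "chrXY"})


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


def _check_unique(ids: Sequence[str], kind: str, path: str | Path | None = None) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        where = f" in {path}" if path else ""
        raise ParseError(f"duplicate {kind}{where}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Samples x SNP markers of categorical calls with chromosome annotation.

    Attributes
    ----------
    sample_ids : list of str
    marker_ids : list of str
    calls : (n_samples, n_markers) int8 array of codes per :data:`CALL_TO_CODE`
    chrom : (n_markers,) object array of chromosome labels ('1'..'22', 'X',
        'Y', 'XY', 'MT'); empty string when unknown
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"call table shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.marker_ids)})"
            )
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.marker_ids, "marker_id")
        bad = ~np.isin(self.calls, list(CODE_TO_CALL))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal call code {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]}, marker {self.marker_ids[j]}"
            )
        if self.chrom is None:
            self.chrom = np.full(len(self.marker_ids), "", dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
            if self.chrom.shape != (len(self.marker_ids),):
                raise ValueError("chrom annotation length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def calls_as_strings(self) -> np.ndarray:
        """Object array of category strings (for display/round-trip)."""
        out = np.empty(self.calls.shape, dtype=object)
        for code, name in CODE_TO_CALL.items():
            out[self.calls == code] = name
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.marker_ids),
                              self.calls[rows, :], self.chrom.copy())

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [idx[m] for m in marker_ids]
        return GenotypeMatrix(list(self.sample_ids), list(marker_ids),
                              self.calls[:, cols], self.chrom[cols])


@dataclass
class ExpressionMatrix:
    """Samples x probes of continuous normalized intensities.

    ``probe_annotation`` is a DataFrame indexed by probe_id with columns
    ``source`` (RefSeq/UniGene/Gnomon), ``chrom`` and ``gene_symbol``; it may
    be None until attached via :func:`read_probe_annotation`.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    probe_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"value table shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.probe_ids)})"
            )
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.probe_ids, "probe_id")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), list(self.probe_ids),
                                self.values[rows, :], self.probe_annotation)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: j for j, p in enumerate(self.probe_ids)}
        cols = [idx[p] for p in probe_ids]
        ann = self.probe_annotation
        return ExpressionMatrix(list(self.sample_ids), list(probe_ids),
                                self.values[:, cols], ann)


@dataclass
class PopulationLabels:
    """Per-sample population assignment; K = number of distinct labels."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        _check_unique(self.sample_ids, "sample_id")
        if self.K < 2:
            raise ValueError("K >= 2 required: need at least two populations")

    @property
    def K(self) -> int:
        return len(set(self.labels))

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def subset(self, sample_ids: Sequence[str]) -> "PopulationLabels":
        d = self.as_dict()
        return PopulationLabels(list(sample_ids), [d[s] for s in sample_ids])


def align_to_labels(
    labels: PopulationLabels,
    genotypes: GenotypeMatrix | None = None,
    expression: ExpressionMatrix | None = None,
) -> tuple[PopulationLabels, GenotypeMatrix | None, ExpressionMatrix | None]:
    """Restrict matrices and labels to their common samples, in label order.

    Samples present in a matrix but absent from the label file are dropped
    with a warning; labeled samples missing from any supplied matrix raise.
    """
    keep = list(labels.sample_ids)
    for mat, kind in ((genotypes, "genotype"), (expression, "expression")):
        if mat is None:
            continue
        have = set(mat.sample_ids)
        missing = [s for s in keep if s not in have]
        if missing:
            raise ValueError(
                f"labeled samples absent from {kind} matrix: {missing[:5]}"
            )
        extra = [s for s in mat.sample_ids if s not in set(keep)]
        if extra:
            warnings.warn(
                f"{len(extra)} unlabeled samples dropped from {kind} matrix",
                stacklevel=2,
            )
    g = genotypes.subset_samples(keep) if genotypes is not None else None
    e = expression.subset_samples(keep) if expression is not None else None
    return labels, g, e


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes_tabular(path: str | Path) -> GenotypeMatrix:
    """Read a TSV of genotype calls: header = marker IDs, first column =
    sample IDs, cells in {AA, AB, BB, NA}."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.name is None and df.columns.empty:
        raise ParseError(f"malformed header in {path}")
    sample_ids = [str(s) for s in df.index]
    marker_ids = [str(m) for m in df.columns]
    _check_unique(sample_ids, "sample_id", path)
    _check_unique(marker_ids, "marker_id", path)
    token_map = {"AA": 0, "AB": 1, "BB": 2, MISSING_TOKEN: -1}
    calls = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy(dtype=object)
    for token, code in token_map.items():
        calls[raw == token] = code
    legal = np.isin(raw, list(token_map))
    if not legal.all():
        i, j = np.argwhere(~legal)[0]
        raise ParseError(
            f"illegal call token {raw[i, j]!r} at row {sample_ids[i]!r}, "
            f"column {marker_ids[j]!r} in {path}"
        )
    return GenotypeMatrix(sample_ids, marker_ids, calls)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Import biallelic records from a VCF 4.x file.

    GT 0/0 -> AA, 0/1 or 1/0 -> AB, 1/1 -> BB, ./. -> MISSING; the CHROM
    column populates the chromosome annotation. Multi-allelic records are
    skipped with a logged warning. Phased separators are accepted.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such VCF: {path}")
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or rec.ALT[0] in (".", "*", None):
            n_skipped += 1
            logger.warning("skipping non-biallelic record %s:%s", rec.CHROM, rec.POS)
            continue
        if "GT" not in (rec.FORMAT or "GT"):
            raise ParseError(f"record {rec.CHROM}:{rec.POS} lacks GT field")
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = -1
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        marker_ids.append(mid)
        chroms.append(str(rec.CHROM))
        columns.append(gt)
    if n_skipped:
        logger.warning("skipped %d non-biallelic records in %s", n_skipped, path)
    if not columns:
        calls = np.empty((len(sample_ids), 0), dtype=np.int8)
    else:
        calls = np.column_stack(columns).astype(np.int8)
    return GenotypeMatrix(sample_ids, marker_ids, calls,
                          np.asarray(chroms, dtype=object))


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a probes-x-samples TSV (series-matrix orientation); the returned
    matrix is transposed to samples-x-probes. Empty cells become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(probe_ids, "probe_id", path)
    _check_unique(sample_ids, "sample_id", path)
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    flat = raw.ravel()
    out = values.ravel()
    for k, cell in enumerate(flat):
        cell = cell.strip() if isinstance(cell, str) else cell
        if cell in ("", MISSING_TOKEN):
            out[k] = np.nan
            continue
        try:
            out[k] = float(cell)
        except (TypeError, ValueError):
            i, j = divmod(k, raw.shape[1])
            raise ParseError(
                f"non-numeric cell {cell!r} at probe {probe_ids[i]!r}, "
                f"sample {sample_ids[j]!r} in {path}"
            ) from None
    return ExpressionMatrix(sample_ids, probe_ids, values.T)


def read_labels(path: str | Path) -> PopulationLabels:
    """Read a two-column (sample_id, label) TSV, with or without header.

    A header row is assumed when the first line's second field is one of
    ``label``/``population`` (case-insensitive).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"label file {path} needs two columns")
    first = [str(x).lower() for x in df.iloc[0]]
    if first[1] in ("label", "population", "pop"):
        df = df.iloc[1:]
    return PopulationLabels([str(s) for s in df.iloc[:, 0]],
                            [str(l) for l in df.iloc[:, 1]])


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe/marker annotation TSV with columns probe_id (or
    marker_id), chrom, source, gene_symbol; indexed by the id column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    _check_unique(df[id_col].tolist(), id_col, path)
    df = df.set_index(id_col)
    for col in ("chrom", "source", "gene_symbol"):
        if col not in df.columns:
            df[col] = ""
    return df


def attach_probe_annotation(e: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Return a copy of ``e`` with ``ann`` attached (reindexed to probes)."""
    return ExpressionMatrix(list(e.sample_ids), list(e.probe_ids), e.values.copy(),
                            ann.reindex(e.probe_ids))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genotypes_tabular(g: GenotypeMatrix, path: str | Path) -> None:
    strings = g.calls_as_strings()
    strings[g.calls == CALL_TO_CODE["MISSING"]] = MISSING_TOKEN
    df = pd.DataFrame(strings, index=g.sample_ids, columns=g.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with synthetic positions (one per marker)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom_set = sorted({c if c else "1" for c in g.chrom}, key=str)
        for c in chrom_set:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            chrom = g.chrom[j] if g.chrom[j] else "1"
            gts = "\t".join(gt_strings[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{j + 1}\t{mid}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    """Write probes-x-samples TSV (inverse of :func:`read_expression`)."""
    df = pd.DataFrame(e.values.T, index=e.probe_ids, columns=e.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="")


def write_labels(labels: PopulationLabels, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_probe_annotation(ann: pd.DataFrame, path: str | Path, id_name: str = "probe_id") -> None:
    out = ann.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t")
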