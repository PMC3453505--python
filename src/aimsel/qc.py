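"""Marker quality control.

SNP rules (union, not cascade): call rate below threshold, minor allele
frequency of exactly zero, Hardy-Weinberg disequilibrium at an FDR-adjusted
permutation p below alpha, and sex-chromosome location. Expression probe
rules: non-RefSeq source, sex-chromosome location, missing gene symbol.
Every rule that fires is recorded, so the report is auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aimsel.io_formats import (
    CALL_TO_CODE,
    SEX_CHROMOSOMES,
    ExpressionMatrix,
    GenotypeMatrix,
    PopulationLabels,
)

logger = logging.getLogger(__name__)

_MISS = CALL_TO_CODE["MISSING"]

SNP_REASONS = ("CALL_RATE", "MAF_ZERO", "HWE", "SEX_CHROM")
PROBE_REASONS = ("NON_REFSEQ", "SEX_CHROM", "NO_GENE_INFO")


@dataclass
class SNPQCConfig:
    """Thresholds for the SNP quality-control chain."""

    min_call_rate: float = 0.9
    min_maf_exclusive: float = 0.0  # markers with MAF <= this are removed
    hwe_alpha: float = 0.05
    hwe_permutations: int = 1000
    seed: int | None = None
    drop_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if self.hwe_permutations < 1:
            raise ValueError("hwe_permutations must be >= 1")


@dataclass
class QCReport:
    """Per-marker and per-probe QC records plus removal tallies.

    ``snp_records``: DataFrame indexed by marker_id with columns call_rate,
    maf, hwe_p_raw, hwe_p_adjusted, removal_reasons (comma-joined string,
    empty = survivor). ``probe_records``: indexed by probe_id with column
    removal_reasons. ``counts``: removals per reason.
    """

    snp_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    probe_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: dict[str, int] = field(default_factory=dict)

    def surviving(self, table: str = "snp") -> list[str]:
        rec = self.snp_records if table == "snp" else self.probe_records
        if rec.empty:
            return []
        return rec.index[rec["removal_reasons"] == ""].tolist()

    @staticmethod
    def _tally(records: pd.DataFrame, reasons: tuple[str, ...]) -> dict[str, int]:
        out = {}
        for r in reasons:
            out[r] = int(records["removal_reasons"].str.contains(r).sum()) if not records.empty else 0
        return out


def call_rate(calls: np.ndarray) -> float:
    """Fraction of non-missing calls in a per-marker call-code vector."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("empty call vector")
    return float(np.count_nonzero(calls != _MISS) / calls.size)


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) among non-missing calls."""
    calls = np.asarray(calls)
    return (
        int(np.count_nonzero(calls == CALL_TO_CODE["AA"])),
        int(np.count_nonzero(calls == CALL_TO_CODE["AB"])),
        int(np.count_nonzero(calls == CALL_TO_CODE["BB"])),
    )


def minor_allele_frequency(calls: np.ndarray) -> float:
    """MAF among non-missing calls: min(f_B, 1 - f_B) with
    f_B = (2 n_BB + n_AB) / (2 n_non_missing)."""
    n_aa, n_ab, n_bb = genotype_counts(calls)
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all calls missing; MAF undefined")
    f_b = (2 * n_bb + n_ab) / (2 * n)
    return float(min(f_b, 1.0 - f_b))


def expected_het_count(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact expectation of the heterozygote count under random pairing of
    the 2N alleles: n_A * n_B / (2N - 1)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = n_ab + 2 * n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    if 2 * n - 1 <= 0:
        return 0.0
    return n_a * n_b / (2 * n - 1)


def hwe_permutation_test(
    n_aa: int,
    n_ab: int,
    n_bb: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation p-value for Hardy-Weinberg equilibrium.

    The allele pool (2N alleles with the observed allele counts) is shuffled
    ``n_perm`` times; consecutive alleles are paired into genotypes and the
    heterozygote count recomputed. The two-sided statistic is the absolute
    deviation of the heterozygote count from its exact expectation
    ``n_A n_B / (2N - 1)``, and

        p = (1 + #{|het* - E| >= |het_obs - E|}) / (1 + n_perm)

    so p is never zero. Monomorphic tables return 1.0 (degenerate statistic).
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_a = 2 * n_aa + n_ab
    n_b = n_ab + 2 * n_bb
    if n_a == 0 or n_b == 0:
        return 1.0
    e_het = expected_het_count(n_aa, n_ab, n_bb)
    obs_dev = abs(n_ab - e_het)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.zeros(2 * n, dtype=np.int8)
    pool[:n_a] = 1
    mat = np.tile(pool, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    het = np.count_nonzero(mat[:, 0::2] != mat[:, 1::2], axis=1)
    n_extreme = int(np.count_nonzero(np.abs(het - e_het) >= obs_dev - 1e-12))
    return (1 + n_extreme) / (1 + n_perm)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def filter_snps(
    g: GenotypeMatrix,
    labels: PopulationLabels | None,
    cfg: SNPQCConfig,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP QC chain on the pooled samples of ``g``.

    ``labels`` is accepted for interface symmetry (QC is run on the sample
    subset of the current population combination); the statistical rules pool
    all samples present in ``g``. Returns the filtered matrix (original
    marker order preserved) and a :class:`QCReport`.
    """
    n_markers = g.n_markers
    rng = np.random.default_rng(cfg.seed)
    rates = np.empty(n_markers)
    mafs = np.full(n_markers, np.nan)
    p_raw = np.ones(n_markers)
    reasons: list[set[str]] = [set() for _ in range(n_markers)]

    for j in range(n_markers):
        col = g.calls[:, j]
        rates[j] = call_rate(col)
        if rates[j] < cfg.min_call_rate:
            reasons[j].add("CALL_RATE")
        n_aa, n_ab, n_bb = genotype_counts(col)
        if n_aa + n_ab + n_bb == 0:
            reasons[j].add("MAF_ZERO")
            p_raw[j] = 1.0
            continue
        mafs[j] = minor_allele_frequency(col)
        if mafs[j] <= cfg.min_maf_exclusive:
            reasons[j].add("MAF_ZERO")
        p_raw[j] = hwe_permutation_test(
            n_aa, n_ab, n_bb, n_perm=cfg.hwe_permutations, seed=rng
        )

    p_adj = fdr_adjust(p_raw) if n_markers else np.array([])
    for j in range(n_markers):
        if p_adj[j] < cfg.hwe_alpha:
            reasons[j].add("HWE")
        if cfg.drop_sex_chromosomes and str(g.chrom[j]) in SEX_CHROMOSOMES:
            reasons[j].add("SEX_CHROM")

    records = pd.DataFrame(
        {
            "call_rate": rates,
            "maf": mafs,
            "hwe_p_raw": p_raw,
            "hwe_p_adjusted": p_adj,
            "removal_reasons": [",".join(sorted(r)) for r in reasons],
        },
        index=pd.Index(g.marker_ids, name="marker_id"),
    )
    report = QCReport(snp_records=records)
    report.counts = QCReport._tally(records, SNP_REASONS)
    keep = [m for m, r in zip(g.marker_ids, reasons) if not r]
    return g.subset_markers(keep), report


def filter_probes(e: ExpressionMatrix) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the expression-probe QC chain using the attached annotation."""
    if e.probe_annotation is None:
        raise ValueError("probe_annotation must be attached before probe QC")
    ann = e.probe_annotation.reindex(e.probe_ids)
    reasons: list[set[str]] = []
    for pid in e.probe_ids:
        row = ann.loc[pid]
        r: set[str] = set()
        if row.isna().all():
            warnings.warn(f"probe {pid} lacks an annotation record", stacklevel=2)
            r.add("NO_GENE_INFO")
            reasons.append(r)
            continue
        source = str(row.get("source", "") or "")
        chrom = str(row.get("chrom", "") or "")
        gene = str(row.get("gene_symbol", "") or "")
        if source != "RefSeq":
            r.add("NON_REFSEQ")
        if chrom in SEX_CHROMOSOMES:
            r.add("SEX_CHROM")
        if gene.strip() == "" or gene.lower() == "nan":
            r.add("NO_GENE_INFO")
        reasons.append(r)

    records = pd.DataFrame(
        {"removal_reasons": [",".join(sorted(r)) for r in reasons]},
        index=pd.Index(e.probe_ids, name="probe_id"),
    )
    report = QCReport(probe_records=records)
    report.counts = QCReport._tally(records, PROBE_REASONS)
    keep = [p for p, r in zip(e.probe_ids, reasons) if not r]
    return e.subset_probes(keep), report
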