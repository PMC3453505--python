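"""Simulation of population-structured SNP + gene-expression datasets with
known ground truth.

Noise SNPs share one allele frequency across populations (drawn per marker
from a uniform range); informative SNPs get population-differentiated
frequencies, either from an explicit per-population table or from a
Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) draw. Genotypes are
Binomial(2, freq) per sample. Expression is Gaussian on a log-intensity
scale; informative probes shift their mean by ``ge_shift * ge_sd`` between
consecutive populations. Informative markers are always autosomal RefSeq so
QC never removes planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from aimsel.io_formats import (
    ExpressionMatrix,
    GenotypeMatrix,
    PopulationLabels,
    attach_probe_annotation,
    write_expression,
    write_genotypes_tabular,
    write_genotypes_vcf,
    write_labels,
    write_probe_annotation,
)

AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class SimulationConfig:
    populations: list[tuple[str, int]] = field(
        default_factory=lambda: [("POP1", 50), ("POP2", 50)]
    )
    n_noise_snps: int = 100
    n_info_snps: int = 1
    #: explicit per-population allele frequencies for informative SNPs,
    #: shape (n_info_snps, n_populations); overrides info_fst when given
    info_snp_freqs: np.ndarray | None = None
    #: Balding-Nichols differentiation for informative SNPs when no explicit
    #: frequency table is given
    info_fst: float = 0.3
    base_freq_range: tuple[float, float] = (0.2, 0.8)
    n_noise_ge: int = 50
    n_info_ge: int = 0
    ge_shift: float = 2.0
    ge_sd: float = 1.0
    missing_rate: float = 0.0
    sex_chrom_fraction: float = 0.0
    non_refseq_fraction: float = 0.0
    no_gene_info_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("missing_rate", "sex_chrom_fraction", "non_refseq_fraction",
                     "no_gene_info_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.info_snp_freqs is None and not 0.0 < self.info_fst < 1.0:
            raise ValueError("info_fst must be in (0, 1)")
        if any(n < 1 for _, n in self.populations):
            raise ValueError("every population needs at least one sample")
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")
        lo, hi = self.base_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("base_freq_range must satisfy 0 < lo <= hi < 1")
        if self.info_snp_freqs is not None:
            self.info_snp_freqs = np.asarray(self.info_snp_freqs, dtype=float)
            want = (self.n_info_snps, len(self.populations))
            if self.info_snp_freqs.shape != want:
                raise ValueError(f"info_snp_freqs must have shape {want}")


@dataclass
class GroundTruth:
    informative_snp_ids: list[str]
    informative_ge_ids: list[str]
    snp_frequencies: pd.DataFrame  # marker x population allele-B frequency
    ge_means: pd.DataFrame         # probe x population mean


def hapmap_like_config(
    seed: int | None = None,
    n_noise_snps: int = 5000,
    n_noise_ge: int = 2000,
    **overrides,
) -> SimulationConfig:
    """Four populations sized 60/60/45/45 at reduced marker counts."""
    kwargs = dict(
        populations=[("POPA", 60), ("POPB", 60), ("POPC", 45), ("POPD", 45)],
        n_noise_snps=n_noise_snps,
        n_info_snps=5,
        info_fst=0.3,
        n_noise_ge=n_noise_ge,
        n_info_ge=3,
        ge_shift=2.0,
        missing_rate=0.01,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def draw_population_frequencies(
    base_freq: float,
    fst: float,
    n_pops: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Balding-Nichols draw of per-population allele frequencies."""
    if not 0.0 < base_freq < 1.0:
        raise ValueError("base_freq must be in (0, 1)")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = base_freq * (1.0 - fst) / fst
    b = (1.0 - base_freq) * (1.0 - fst) / fst
    return rng.beta(a, b, size=n_pops)


def _draw_genotype_block(
    rng: np.random.Generator, freqs: np.ndarray, pop_sizes: list[int]
) -> np.ndarray:
    """Genotype codes for markers with per-population allele-B frequencies.

    ``freqs`` has shape (n_markers, n_pops); result is (n_samples, n_markers)
    with codes 0/1/2 (allele-B dosage = count of the B allele).
    """
    blocks = []
    for k, n in enumerate(pop_sizes):
        blocks.append(rng.binomial(2, freqs[:, k], size=(n, freqs.shape[0])))
    return np.concatenate(blocks, axis=0).astype(np.int8)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, ExpressionMatrix, PopulationLabels, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate genotypes, expression, labels, annotations, and truth.

    Returns (genotypes, expression, labels, snp_annotation, probe_annotation,
    ground_truth). Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pop_names = [p for p, _ in cfg.populations]
    pop_sizes = [n for _, n in cfg.populations]
    n_pops = len(pop_names)
    n_samples = sum(pop_sizes)
    sample_ids = [
        f"{pop}_{i:03d}" for pop, n in cfg.populations for i in range(1, n + 1)
    ]
    labels = PopulationLabels(
        sample_ids, [pop for pop, n in cfg.populations for _ in range(n)]
    )

    # --- SNPs -------------------------------------------------------------
    info_ids = [f"snp_info_{j + 1:04d}" for j in range(cfg.n_info_snps)]
    noise_ids = [f"snp_noise_{j + 1:05d}" for j in range(cfg.n_noise_snps)]
    lo, hi = cfg.base_freq_range
    if cfg.n_info_snps:
        if cfg.info_snp_freqs is not None:
            info_freqs = np.asarray(cfg.info_snp_freqs, dtype=float)
        else:
            bases = rng.uniform(lo, hi, size=cfg.n_info_snps)
            info_freqs = np.stack(
                [draw_population_frequencies(b, cfg.info_fst, n_pops, rng) for b in bases]
            )
    else:
        info_freqs = np.empty((0, n_pops))
    noise_base = rng.uniform(lo, hi, size=cfg.n_noise_snps)
    noise_freqs = np.repeat(noise_base[:, None], n_pops, axis=1)

    marker_ids = info_ids + noise_ids
    freqs = np.concatenate([info_freqs, noise_freqs], axis=0)
    calls = _draw_genotype_block(rng, freqs, pop_sizes)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = -1

    chrom = np.asarray(
        [AUTOSOMES[j % len(AUTOSOMES)] for j in range(len(marker_ids))], dtype=object
    )
    if cfg.sex_chrom_fraction > 0 and cfg.n_noise_snps:
        n_sex = int(round(cfg.sex_chrom_fraction * cfg.n_noise_snps))
        sex_idx = len(info_ids) + rng.choice(cfg.n_noise_snps, size=n_sex, replace=False)
        chrom[sex_idx] = "X"
    genotypes = GenotypeMatrix(sample_ids, marker_ids, calls, chrom)
    snp_annotation = pd.DataFrame(
        {"chrom": chrom, "informative": [m in set(info_ids) for m in marker_ids]},
        index=pd.Index(marker_ids, name="marker_id"),
    )

    # --- expression -------------------------------------------------------
    info_ge = [f"ge_info_{j + 1:04d}" for j in range(cfg.n_info_ge)]
    noise_ge = [f"ge_noise_{j + 1:05d}" for j in range(cfg.n_noise_ge)]
    probe_ids = info_ge + noise_ge
    n_probes = len(probe_ids)
    baseline = rng.uniform(6.0, 10.0, size=n_probes)  # log-intensity-like level
    means = np.repeat(baseline[None, :], n_pops, axis=0)  # pop x probe
    for j in range(cfg.n_info_ge):
        means[:, j] = baseline[j] + np.arange(n_pops) * cfg.ge_shift * cfg.ge_sd
    values = np.empty((n_samples, n_probes))
    row = 0
    for k, n in enumerate(pop_sizes):
        values[row : row + n] = rng.normal(means[k], cfg.ge_sd, size=(n, n_probes))
        row += n

    source = np.asarray(["RefSeq"] * n_probes, dtype=object)
    probe_chrom = np.asarray(
        [AUTOSOMES[j % len(AUTOSOMES)] for j in range(n_probes)], dtype=object
    )
    gene_symbol = np.asarray([f"GENE{j + 1}" for j in range(n_probes)], dtype=object)
    if cfg.n_noise_ge:
        if cfg.non_refseq_fraction > 0:
            n_nr = int(round(cfg.non_refseq_fraction * cfg.n_noise_ge))
            idx = len(info_ge) + rng.choice(cfg.n_noise_ge, size=n_nr, replace=False)
            source[idx] = rng.choice(["UniGene", "Gnomon"], size=n_nr)
        if cfg.sex_chrom_fraction > 0:
            n_sex = int(round(cfg.sex_chrom_fraction * cfg.n_noise_ge))
            idx = len(info_ge) + rng.choice(cfg.n_noise_ge, size=n_sex, replace=False)
            probe_chrom[idx] = "Y"
        if cfg.no_gene_info_fraction > 0:
            n_ng = int(round(cfg.no_gene_info_fraction * cfg.n_noise_ge))
            idx = len(info_ge) + rng.choice(cfg.n_noise_ge, size=n_ng, replace=False)
            gene_symbol[idx] = ""
    probe_annotation = pd.DataFrame(
        {"source": source, "chrom": probe_chrom, "gene_symbol": gene_symbol},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    expression = attach_probe_annotation(
        ExpressionMatrix(sample_ids, probe_ids, values), probe_annotation
    )

    truth = GroundTruth(
        informative_snp_ids=info_ids,
        informative_ge_ids=info_ge,
        snp_frequencies=pd.DataFrame(
            freqs, index=pd.Index(marker_ids, name="marker_id"), columns=pop_names
        ),
        ge_means=pd.DataFrame(
            means.T, index=pd.Index(probe_ids, name="probe_id"), columns=pop_names
        ),
    )
    return genotypes, expression, labels, snp_annotation, probe_annotation, truth


def write_dataset(
    dataset: tuple,
    out_dir: str | Path,
    vcf: bool = False,
) -> dict[str, Path]:
    """Write a simulated dataset to ``out_dir`` as plain-text tables."""
    genotypes, expression, labels, snp_ann, probe_ann, truth = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "snp_annotation": out / "snp_annotation.tsv",
        "probe_annotation": out / "probe_annotation.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_genotypes_tabular(genotypes, paths["genotypes"])
    write_expression(expression, paths["expression"])
    write_labels(labels, paths["labels"])
    write_probe_annotation(snp_ann, paths["snp_annotation"], id_name="marker_id")
    write_probe_annotation(probe_ann, paths["probe_annotation"])
    gt_rows = [
        {"marker_id": m, "type": "snp"} for m in truth.informative_snp_ids
    ] + [{"marker_id": p, "type": "ge"} for p in truth.informative_ge_ids]
    pd.DataFrame(gt_rows, columns=["marker_id", "type"]).to_csv(
        paths["ground_truth"], sep="\t", index=False
    )
    if vcf:
        paths["vcf"] = out / "genotypes.vcf"
        write_genotypes_vcf(genotypes, paths["vcf"])
    return paths
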