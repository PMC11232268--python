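"""Synthetic soybean panels and neutral-coalescent alignments.

The panel generator emulates the statistical structure the downstream
analysis assumes: three population classes (wild / landrace / cultivar)
sampled along a latitude gradient, a two-group haplotype (HapA / HapB) at
each flowering-time gene whose HapA probability rises with latitude, and a
beginning-bloom-date phenotype that is additive in the number of HapA
copies plus Gaussian noise.  Background SNPs carry mild population-class
structure and no latitude signal.

A single global seed feeds named substreams (one per generator concern) so
that enlarging one part of the panel does not perturb draws elsewhere.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (AccessionMeta, ConfigurationError, DomainError,
                         GeneModel, GenotypeMatrix, read_gene_models,
                         read_metadata, read_vcf, write_gene_models,
                         write_metadata, write_vcf)
from .popgen import Alignment

GENE_NAMES = ("E1", "E3", "FT2a", "J", "Tof11", "Tof16", "Tof18",
              "E2", "E4", "FT5a", "Tof4", "Tof5", "Tof8", "Tof12")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: stable under addition of other streams."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated 2,898-accession panel
    at the effect sizes and noise level the validation world states."""

    n_wild: int = 103
    n_landrace: int = 1048
    n_cultivar: int = 1747
    n_genes: int = 7
    snps_per_gene: int = 6
    n_diagnostic: int = 3
    n_background_snps: int = 500
    hapA_effect_days: float = -6.0
    bbd_intercept_days: float = 85.0
    bbd_noise_sd: float = 3.0
    latitude_range: tuple = (20.0, 50.0)
    latitude_hapA_slope: float = 0.25
    missing_rate: float = 0.02
    envs: tuple = ("BJ13",)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_wild", "n_landrace", "n_cultivar", "n_genes",
                     "snps_per_gene", "n_diagnostic", "n_background_snps"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_genes > 0 and self.n_diagnostic < 2:
            raise ConfigurationError("n_diagnostic must be >= 2")
        if self.n_genes > 0 and self.snps_per_gene < self.n_diagnostic:
            raise ConfigurationError(
                "snps_per_gene must be >= n_diagnostic")
        if self.bbd_noise_sd < 0:
            raise ConfigurationError("bbd_noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not self.latitude_range[0] < self.latitude_range[1]:
            raise ConfigurationError("latitude_range must satisfy min < max")

    @property
    def n_total(self) -> int:
        return self.n_wild + self.n_landrace + self.n_cultivar


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    groups: pd.DataFrame       # accession x gene, entries "HapA"/"HapB"
    hapA_count: pd.Series      # per accession, = #genes carrying HapA
    effect_days: float
    config: SimConfig = None

    def __post_init__(self) -> None:
        recount = (self.groups == "HapA").sum(axis=1)
        if not (recount == self.hapA_count).all():
            raise ValueError("hapA_count inconsistent with per-gene groups")


def _gene_models(config: SimConfig) -> list:
    genes = []
    for g in range(config.n_genes):
        name = GENE_NAMES[g] if g < len(GENE_NAMES) else f"G{g + 1}"
        chrom = f"Gm{g + 1:02d}"
        start = 1_000_000
        end = start + 3_000
        # two exons; CDS trimmed so the total length is a codon multiple
        exons = [(start, start + 1_200), (start + 1_800, end)]
        cds = [(start + 99, start + 1_200), (start + 1_800, end - 300)]
        total = sum(b - a for a, b in cds)
        trim = total % 3
        if trim:
            cds[-1] = (cds[-1][0], cds[-1][1] - trim)
        genes.append(GeneModel(name, chrom, "+" if g % 2 == 0 else "-",
                               start, end, exons, cds))
    return genes


def simulate_panel(config: SimConfig):
    """Generate ``(GenotypeMatrix, AccessionMeta, [GeneModel], SimTruth)``.

    Latitudes are uniform over ``latitude_range``; at each gene the HapA
    probability is logistic in latitude (slope ``latitude_hapA_slope``,
    centred mid-range); HapA/HapB map to distinct fully linked allele
    strings over the gene's diagnostic SNPs; BBD is additive in HapA count.
    Deterministic for a fixed seed.
    """
    config.validate()
    n = config.n_total
    seed = config.seed

    ids = [f"ACC{i:05d}" for i in range(n)]
    pop_class = (["wild"] * config.n_wild + ["landrace"] * config.n_landrace
                 + ["cultivar"] * config.n_cultivar)

    lat_lo, lat_hi = config.latitude_range
    lats = _stream(seed, "latitude").uniform(lat_lo, lat_hi, size=n)
    lons = _stream(seed, "longitude").uniform(100.0, 130.0, size=n)
    mid = 0.5 * (lat_lo + lat_hi)

    genes = _gene_models(config)
    variant_rows = []
    dosage_cols = []
    groups = {}
    for g, gene in enumerate(genes):
        rng = _stream(seed, f"gene:{g}")
        p_hapA = 1.0 / (1.0 + np.exp(-config.latitude_hapA_slope
                                     * (lats - mid)))
        is_A = rng.random(n) < p_hapA
        groups[gene.gene_id] = np.where(is_A, "HapA", "HapB")
        positions = np.sort(rng.choice(np.arange(gene.start, gene.end),
                                       size=config.snps_per_gene,
                                       replace=False))
        diag = set(rng.choice(config.snps_per_gene,
                              size=config.n_diagnostic, replace=False))
        for s, pos in enumerate(positions):
            if s in diag:
                # fully linked diagnostic sites: HapA homozygous alt
                dos = np.where(is_A, 2, 0).astype(np.int8)
            else:
                freq = rng.uniform(0.1, 0.9)
                dos = (2 * (rng.random(n) < freq)).astype(np.int8)
            variant_rows.append((gene.chrom, int(pos),
                                 f"{gene.gene_id}_s{s}", "A", "T"))
            dosage_cols.append(dos)

    # background SNPs: class-structured (Balding-Nichols), latitude-free
    rng_bg = _stream(seed, "background")
    f_st = 0.05
    class_idx = pd.Categorical(pop_class, categories=["wild", "landrace",
                                                      "cultivar"]).codes
    bg_chrom = "Gm20"
    bg_pos = np.sort(rng_bg.choice(np.arange(1, 50_000_000),
                                   size=config.n_background_snps,
                                   replace=False))
    for s in range(config.n_background_snps):
        p_anc = rng_bg.uniform(0.05, 0.95)
        ab = p_anc * (1 - f_st) / f_st, (1 - p_anc) * (1 - f_st) / f_st
        p_pop = rng_bg.beta(ab[0], ab[1], size=3)
        p = p_pop[class_idx]
        dos = (2 * (rng_bg.random(n) < p)).astype(np.int8)
        # rare residual heterozygosity in a selfing species
        het = rng_bg.random(n) < 0.01
        dos[het] = 1
        variant_rows.append((bg_chrom, int(bg_pos[s]), f"bg_s{s}", "A", "T"))
        dosage_cols.append(dos)

    variants = pd.DataFrame(variant_rows,
                            columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (np.stack(dosage_cols, axis=1) if dosage_cols
               else np.zeros((n, 0), dtype=np.int8))

    if config.missing_rate > 0 and dosages.size:
        mask = _stream(seed, "missing").random(dosages.shape) \
            < config.missing_rate
        dosages = np.where(mask, np.int8(-1), dosages)

    gm = GenotypeMatrix(ids, variants, dosages)

    group_df = pd.DataFrame(groups, index=ids)
    hapA_count = (group_df == "HapA").sum(axis=1)

    rng_ph = _stream(seed, "phenotype")
    pheno_rows = []
    for env in config.envs:
        noise = rng_ph.normal(0.0, config.bbd_noise_sd, size=n)
        bbd = (config.bbd_intercept_days
               + config.hapA_effect_days * hapA_count.to_numpy() + noise)
        fbd = bbd + 10.0 + rng_ph.normal(0.0, 1.0, size=n)
        md = bbd + 60.0 + rng_ph.normal(0.0, 2.0, size=n)
        for i, acc in enumerate(ids):
            pheno_rows.append((acc, env, bbd[i], fbd[i], md[i]))
    pheno = pd.DataFrame(pheno_rows, columns=["id", "env", "BBD", "FBD", "MD"])

    info = pd.DataFrame({"pop_class": pop_class, "country": "China",
                         "latitude": lats, "longitude": lons},
                        index=pd.Index(ids, name="id"))
    meta = AccessionMeta(info, pheno)
    truth = SimTruth(group_df, hapA_count, config.hapA_effect_days, config)
    return gm, meta, genes, truth


# ---------------------------------------------------------------------------
# Neutral coalescent
# ---------------------------------------------------------------------------

def simulate_neutral_coalescent(n_samples: int, theta: float,
                                seed=None, rng=None) -> Alignment:
    """Standard neutral coalescent without recombination, infinite sites.

    Coalescence times are exponential with rate k(k-1)/2 for k active
    lineages; mutations fall on branches as Poisson(theta * length / 2),
    each creating one new segregating column carried by the leaves beneath.
    """
    if n_samples < 2:
        raise DomainError("n_samples must be >= 2")
    if theta <= 0:
        raise DomainError("theta must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    # active lineages as frozen leaf sets with their start times
    active = [(frozenset([i]), 0.0) for i in range(n_samples)]
    t = 0.0
    branches = []  # (leafset, length)
    k = n_samples
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        (la, ta), (lb, tb) = active[i], active[j]
        branches.append((la, t - ta))
        branches.append((lb, t - tb))
        merged = la | lb
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append((merged, t))
        k -= 1
    cols = []
    for leafset, length in branches:
        m = rng.poisson(theta * length / 2.0)
        for _ in range(m):
            col = np.zeros(n_samples, dtype=np.int8)
            col[list(leafset)] = 1
            cols.append(col)
    matrix = (np.stack(cols, axis=1) if cols
              else np.zeros((n_samples, 0), dtype=np.int8))
    return Alignment(matrix)


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------

def write_fixture(panel, directory) -> dict:
    """Write a simulated panel as VCF + TSVs readable by io_formats.

    ``panel`` is the (gm, meta, genes, truth) tuple from
    :func:`simulate_panel` (truth may be omitted).  Returns the file paths.
    """
    gm, meta, genes = panel[0], panel[1], panel[2]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "panel.vcf",
        "meta": directory / "meta.tsv",
        "pheno": directory / "pheno.tsv",
        "genes": directory / "genes.tsv",
    }
    write_vcf(gm, paths["vcf"])
    write_metadata(meta, paths["meta"], paths["pheno"])
    write_gene_models(genes, paths["genes"])
    return paths


def read_fixture(directory):
    """Inverse of :func:`write_fixture`: ``(gm, meta, genes)``."""
    directory = Path(directory)
    gm = read_vcf(directory / "panel.vcf")
    meta = read_metadata(directory / "meta.tsv", directory / "pheno.tsv")
    genes = read_gene_models(directory / "genes.tsv")
    return gm, meta, genes
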