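"""Standard-format I/O, variant filtering and gene-region extraction.

All coordinates are 0-based half-open in memory; 1-based inclusive
coordinates appear only at file boundaries (VCF ``POS``, gene-model TSV).

The central container is :class:`GenotypeMatrix`: an accessions x variants
allele-dosage table with ``-1`` marking missing calls.  Heterozygous
biallelic genotypes map to dosage 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
POP_CLASSES = ("wild", "landrace", "cultivar")
TRAITS = ("BBD", "FBD", "MD")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class VCFParseError(ValueError):
    """Malformed VCF input; carries the offending line number when known."""


class ConfigurationError(ValueError):
    """An invalid parameter value; the message names the field."""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vid: str = ""

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos + 1}")

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def vtype(self) -> str:
        return "indel" if self.indel_len > 0 else "SNP"

    @property
    def pos1(self) -> int:
        """1-based position as printed in VCF."""
        return self.pos + 1


@dataclass
class GenotypeMatrix:
    """Accessions x variants dosage matrix.

    Attributes
    ----------
    samples : list of accession ids (rows).
    variants : DataFrame with columns chrom, pos (0-based), id, ref, alt.
    dosages : int8 array, shape (n_samples, n_variants); entries in
        {0, 1, 2, -1} with -1 = missing.
    """

    samples: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def record(self, j: int) -> VariantRecord:
        row = self.variants.iloc[j]
        return VariantRecord(row["chrom"], int(row["pos"]), row["ref"],
                             row["alt"], str(row.get("id", "")))

    def records(self) -> Iterable[VariantRecord]:
        return (self.record(j) for j in range(self.n_variants))

    # -- per-variant summaries (vectorised) --------------------------------
    def called_mask(self) -> np.ndarray:
        return self.dosages >= 0

    def n_called(self) -> np.ndarray:
        return self.called_mask().sum(axis=0)

    def missing_fraction(self) -> np.ndarray:
        n = self.n_samples
        if n == 0:
            return np.zeros(self.n_variants)
        return 1.0 - self.n_called() / n

    def alt_frequency(self) -> np.ndarray:
        called = self.called_mask()
        nc = called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nc > 0, alt / (2.0 * nc), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def het_fraction(self) -> np.ndarray:
        nc = self.n_called()
        het = (self.dosages == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nc > 0, het / nc, np.nan)

    def indel_lengths(self) -> np.ndarray:
        ref = self.variants["ref"].str.len().to_numpy()
        alt = self.variants["alt"].str.len().to_numpy()
        return np.abs(alt - ref)

    # -- subsetting --------------------------------------------------------
    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(list(self.samples),
                              self.variants.iloc[idx].reset_index(drop=True),
                              self.dosages[:, idx])

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.samples[i] for i in idx],
                              self.variants.copy(), self.dosages[idx, :])

    def sample_index(self, ids: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[i] for i in ids], dtype=int)


@dataclass
class GeneModel:
    """A gene with exon/CDS structure; intervals 0-based half-open, sorted."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty gene span for {self.gene_id}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for (a, b) in ivs:
                if not a < b:
                    raise ValueError(f"empty {name} interval in {self.gene_id}")
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"overlapping {name}s in {self.gene_id}")
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"CDS outside exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_exon(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.cds)

    @property
    def tss(self) -> int:
        """Transcription start (0-based coordinate of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AccessionMeta:
    """Per-accession metadata plus long-format phenotypes.

    ``info``: DataFrame indexed by accession id with columns pop_class,
    country, latitude, longitude.  ``phenotypes``: long DataFrame with
    columns id, env, BBD, FBD, MD.
    """

    info: pd.DataFrame
    phenotypes: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.phenotypes is None:
            self.phenotypes = pd.DataFrame(
                columns=["id", "env", "BBD", "FBD", "MD"])
        bad = set(self.info["pop_class"]) - set(POP_CLASSES)
        if bad:
            raise ValueError(f"unknown pop_class values: {sorted(bad)}")
        lat = self.info["latitude"].astype(float)
        if (lat.abs() > 90).any():
            raise ValueError("latitude outside [-90, 90]")

    @property
    def ids(self) -> list:
        return list(self.info.index)

    def latitudes(self, ids: Sequence | None = None) -> pd.Series:
        lat = self.info["latitude"].astype(float)
        return lat if ids is None else lat.reindex(ids)

    def trait(self, env: str, trait: str = "BBD") -> pd.Series:
        """Phenotype values for one environment, indexed by accession id."""
        if trait not in TRAITS:
            raise KeyError(f"unknown trait {trait!r}")
        sub = self.phenotypes[self.phenotypes["env"] == env]
        return sub.set_index("id")[trait].astype(float)

    def envs(self) -> list:
        return sorted(self.phenotypes["env"].unique())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_header(path: Path) -> None:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VCFParseError(f"{path}: line 1: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if cols[:8] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO"]:
                    raise VCFParseError(
                        f"{path}: line {lineno}: malformed #CHROM line")
                return
            raise VCFParseError(
                f"{path}: line {lineno}: expected #CHROM header line")
    raise VCFParseError(f"{path}: no #CHROM header line found")


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCFv4.2 file of biallelic records into a GenotypeMatrix.

    Multi-allelic records are skipped with a logged count.  ``./.`` becomes
    a missing entry; ``0/1`` becomes dosage 1.
    """
    from cyvcf2 import VCF  # deferred: htslib import is not free

    path = Path(path)
    _validate_vcf_header(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosage_cols, skipped = [], [], 0
    for v in vcf:
        if v.ALT is None or len(v.ALT) != 1:
            skipped += 1
            continue
        rows.append((v.CHROM, v.POS - 1, v.ID or "", v.REF, v.ALT[0]))
        if samples:
            # gts012: 0/1/2 = dosage, 3 = unknown
            d = v.gt_types.astype(np.int8)
            d[d == 3] = MISSING
            dosage_cols.append(d)
    if skipped:
        log.warning("read_vcf: skipped %d multi-allelic record(s)", skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if dosage_cols:
        dosages = np.stack(dosage_cols, axis=1)
    else:
        dosages = np.zeros((len(samples), len(variants)), dtype=np.int8)
    return GenotypeMatrix(samples, variants, dosages)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> Path:
    """Write a GenotypeMatrix as an uncompressed VCFv4.2 file."""
    path = Path(path)
    chrom_max: dict = {}
    for _, row in gm.variants.iterrows():
        end = int(row["pos"]) + max(len(row["ref"]), len(row["alt"]))
        chrom_max[row["chrom"]] = max(chrom_max.get(row["chrom"], 0), end)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=latisoy\n")
        for chrom in sorted(chrom_max):
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + [str(s) for s in gm.samples]
        fh.write("\t".join(cols) + "\n")
        for j in range(gm.n_variants):
            row = gm.variants.iloc[j]
            gts = [_GT[int(d)] for d in gm.dosages[:, j]]
            fields = [row["chrom"], str(int(row["pos"]) + 1),
                      str(row["id"]) or ".", row["ref"], row["alt"],
                      ".", "PASS", ".", "GT"] + gts
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# TSVs
# ---------------------------------------------------------------------------

def read_metadata(meta_path, pheno_path=None) -> AccessionMeta:
    info = pd.read_csv(meta_path, sep="\t", dtype={"id": str}).set_index("id")
    pheno = None
    if pheno_path is not None:
        pheno = pd.read_csv(pheno_path, sep="\t", dtype={"id": str})
    return AccessionMeta(info, pheno)


def write_metadata(meta: AccessionMeta, meta_path, pheno_path=None) -> None:
    meta.info.reset_index().rename(columns={"index": "id"}).to_csv(
        meta_path, sep="\t", index=False)
    if pheno_path is not None:
        meta.phenotypes.to_csv(pheno_path, sep="\t", index=False)


def _ints(cell: str) -> list:
    cell = str(cell).strip()
    return [int(x) for x in cell.split(",") if x != ""] if cell else []


def read_gene_models(path) -> list:
    """Read the gene-model TSV (1-based inclusive columns) into GeneModels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for _, r in df.iterrows():
        ex = list(zip([s - 1 for s in _ints(r["exon_starts"])],
                      _ints(r["exon_ends"])))
        cds = list(zip([s - 1 for s in _ints(r["cds_starts"])],
                       _ints(r["cds_ends"])))
        genes.append(GeneModel(r["gene"], r["chrom"], r["strand"],
                               int(r["start"]) - 1, int(r["end"]), ex, cds))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start + 1, "end": g.end,
            "exon_starts": ",".join(str(a + 1) for a, _ in g.exons),
            "exon_ends": ",".join(str(b) for _, b in g.exons),
            "cds_starts": ",".join(str(a + 1) for a, _ in g.cds),
            "cds_ends": ",".join(str(b) for _, b in g.cds),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering / imputation / region extraction
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    dropped_maf: int
    dropped_missing: int
    dropped_het: int
    dropped_indel: int


def filter_variants(gm: GenotypeMatrix, maf_min: float = 0.05,
                    miss_max: float = 0.10, het_max: float = 0.10,
                    indel_max_len: int = 10):
    """Apply the panel QC filters with strict inequalities.

    Keeps variants with MAF > ``maf_min`` (on non-missing calls), missing
    fraction < ``miss_max``, heterozygote fraction < ``het_max``, and, for
    indels, length <= ``indel_max_len``.  Returns ``(kept_gm, FilterReport)``;
    a variant failing several rules is counted under each.
    """
    for name, v in (("maf_min", maf_min), ("miss_max", miss_max),
                    ("het_max", het_max)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
    if indel_max_len < 0:
        raise ConfigurationError("indel_max_len must be >= 0")
    if gm.n_variants == 0:
        return gm, FilterReport(0, 0, 0, 0, 0, 0)
    with np.errstate(invalid="ignore"):
        pass_maf = gm.maf() > maf_min
        pass_miss = gm.missing_fraction() < miss_max
        pass_het = gm.het_fraction() < het_max
    pass_maf = np.where(np.isnan(gm.maf()), False, pass_maf)
    pass_het = np.where(np.isnan(gm.het_fraction()), False, pass_het)
    pass_indel = gm.indel_lengths() <= indel_max_len
    keep = pass_maf & pass_miss & pass_het & pass_indel
    report = FilterReport(
        n_input=gm.n_variants, n_kept=int(keep.sum()),
        dropped_maf=int((~pass_maf).sum()),
        dropped_missing=int((~pass_miss).sum()),
        dropped_het=int((~pass_het).sum()),
        dropped_indel=int((~pass_indel).sum()))
    return gm.take_variants(np.flatnonzero(keep)), report


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing entry by the variant's modal dosage.

    Ties break toward the lower dosage; all-missing variants are dropped
    with a logged warning.
    """
    d = gm.dosages.copy()
    counts = np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)], axis=0)
    mode = counts.argmax(axis=0)  # first max -> ties break to lower dosage
    any_called = counts.sum(axis=0) > 0
    if not any_called.all():
        log.warning("impute_mode: dropping %d all-missing variant(s)",
                    int((~any_called).sum()))
    miss = d == MISSING
    d = np.where(miss, mode[np.newaxis, :].astype(np.int8), d)
    out = GenotypeMatrix(list(gm.samples), gm.variants.copy(), d)
    return out.take_variants(np.flatnonzero(any_called))


def extract_gene_region(gm: GenotypeMatrix, gene: GeneModel,
                        flank: int = 2000):
    """Sub-matrix of variants within ``gene`` span +/- ``flank`` bp.

    Strand-agnostic; returns ``(sub_gm, variant_indices)``.
    """
    if flank < 0:
        raise ConfigurationError("flank must be >= 0")
    pos = gm.variants["pos"].to_numpy()
    on_chrom = (gm.variants["chrom"] == gene.chrom).to_numpy()
    keep = on_chrom & (pos >= gene.start - flank) & (pos < gene.end + flank)
    idx = np.flatnonzero(keep)
    return gm.take_variants(idx), idx
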