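"""Variant classification against gene models.

Region labels follow the usual genome-annotation convention: exon > intron >
upstream > downstream > intergenic, with upstream/downstream windows of 2 kb
around the transcription start/termination sites, strand-aware (upstream of
a minus-strand gene lies at higher coordinates).  Coding SNPs are classified
by translating the reference and mutated codons; coding indels by whether
their length is a codon multiple.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import DomainError, GeneModel, VariantRecord

REGIONS = ("exon", "intron", "upstream", "downstream", "intergenic")
_PRECEDENCE = {r: i for i, r in enumerate(REGIONS)}
_BASES = set("ACGT")


@dataclass(frozen=True)
class Annotation:
    variant: VariantRecord
    region: str
    coding_effect: str = "none"

    def __post_init__(self) -> None:
        if self.coding_effect != "none" and self.region != "exon":
            raise ValueError("coding_effect requires region == exon")


def _region_for_gene(pos: int, gene: GeneModel, flank: int):
    """(label, distance-to-gene-span) for one gene, or None if out of reach."""
    if gene.in_exon(pos):
        return "exon", 0
    if gene.contains(pos):
        return "intron", 0
    if pos < gene.start:
        dist = gene.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - (gene.end - 1)
        side = "downstream" if gene.strand == "+" else "upstream"
    if dist <= flank:
        return side, dist
    return None


def classify_region(variant: VariantRecord, genes: Sequence[GeneModel],
                    flank: int = 2000) -> str:
    """Region label for a variant against a set of gene models.

    Precedence exon > intron > upstream > downstream; the nearest gene wins
    ties between genes; intergenic is the fallback.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    best = None
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        hit = _region_for_gene(variant.pos, gene, flank)
        if hit is None:
            continue
        key = (_PRECEDENCE[hit[0]], hit[1])
        if best is None or key < best:
            best = key
    return "intergenic" if best is None else REGIONS[best[0]]


def _spliced_cds(gene: GeneModel, genome_seq: Mapping[str, str]) -> str:
    chrom_seq = genome_seq[gene.chrom]
    cds = "".join(chrom_seq[a:b] for a, b in gene.cds)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds.upper()


def _cds_index(gene: GeneModel, pos: int) -> int:
    """Index of a genomic position within the spliced CDS (coding order)."""
    offset = 0
    idx = None
    for a, b in gene.cds:
        if a <= pos < b:
            idx = offset + (pos - a)
        offset += b - a
    if idx is None:
        raise DomainError(f"position {pos + 1} not in CDS of {gene.gene_id}")
    return idx if gene.strand == "+" else offset - 1 - idx


def classify_coding_snp(snp: VariantRecord, gene: GeneModel,
                        genome_seq: Mapping[str, str]) -> str:
    """'synonymous' or 'nonsynonymous' for a SNP inside the CDS.

    Builds the affected codon in CDS frame (reverse-complemented for minus
    strand) and compares translated amino acids under the standard code.
    """
    if snp.indel_len != 0:
        raise DomainError("classify_coding_snp expects a SNP")
    if snp.ref.upper() not in _BASES or snp.alt.upper() not in _BASES:
        raise DomainError(f"ambiguous base in {snp.ref}>{snp.alt}")
    cds = _spliced_cds(gene, genome_seq)
    i = _cds_index(gene, snp.pos)
    ref_base, alt_base = snp.ref.upper(), snp.alt.upper()
    if gene.strand == "-":
        ref_base = str(Seq(ref_base).reverse_complement())
        alt_base = str(Seq(alt_base).reverse_complement())
    if cds[i] != ref_base:
        raise DomainError(
            f"reference mismatch at {snp.chrom}:{snp.pos1} "
            f"(CDS has {cds[i]}, variant ref {ref_base})")
    codon_start = (i // 3) * 3
    codon = cds[codon_start:codon_start + 3]
    if len(codon) < 3 or not set(codon) <= _BASES:
        raise DomainError("incomplete or ambiguous codon")
    mutated = codon[:i - codon_start] + alt_base + codon[i - codon_start + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_indel(indel: VariantRecord, gene: GeneModel) -> str:
    """'frameshift' / 'inframe' for CDS-overlapping indels, else 'none'."""
    if indel.indel_len == 0:
        return "none"
    span_len = max(len(indel.ref), 1)
    lo, hi = indel.pos, indel.pos + span_len
    overlaps = any(a < hi and lo < b for a, b in gene.cds)
    if not overlaps:
        return "none"
    return "frameshift" if indel.indel_len % 3 != 0 else "inframe"


def annotate_variants(variants: Sequence[VariantRecord],
                      genes: Sequence[GeneModel],
                      genome_seq: Mapping[str, str] = None,
                      flank: int = 2000) -> pd.DataFrame:
    """Annotation table (variant id, region, coding_effect) for a variant set.

    Coding effects are filled only for exonic variants overlapping a CDS and,
    for SNPs, only when a reference sequence is supplied.
    """
    rows = []
    for v in variants:
        region = classify_region(v, genes, flank)
        effect = "none"
        if region == "exon":
            for gene in genes:
                if gene.chrom != v.chrom or not gene.in_cds(v.pos):
                    continue
                if v.indel_len > 0:
                    effect = classify_indel(v, gene)
                elif genome_seq is not None:
                    effect = classify_coding_snp(v, gene, genome_seq)
                break
        rows.append({"chrom": v.chrom, "pos": v.pos1, "id": v.vid,
                     "region": region, "coding_effect": effect})
    return pd.DataFrame(rows)
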