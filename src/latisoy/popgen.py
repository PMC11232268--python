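"""Diversity, neutrality, differentiation and LD statistics.

Computed from first principles on binary haplotype alignments
(:class:`Alignment`) or dosage matrices (:class:`~latisoy.io_formats.GenotypeMatrix`).

Conventions
-----------
* Watterson's theta per sequence is ``S / a1`` with ``a1 = sum_{i<n} 1/i``;
  per-site values divide by the alignment length.
* pi is the mean pairwise Hamming distance; per-site divides by length.
* Neutrality statistics are undefined (returned as NaN) when ``S == 0``.
* Fu & Li's starred statistics are outgroup-free: singletons are sites where
  the minor allele appears in exactly one sequence.
* Reports may scale per-site diversities by 1e3; the core returns raw values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DomainError, GenotypeMatrix


@dataclass
class Alignment:
    """n haplotypes x L binary sites (ancestral state unknown), no missing."""

    matrix: np.ndarray
    positions: np.ndarray = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if self.positions is None:
            self.positions = np.arange(self.matrix.shape[1])
        self.positions = np.asarray(self.positions)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def minor_counts(self) -> np.ndarray:
        k = self.derived_counts()
        return np.minimum(k, self.n - k)


def alignment_from_genotypes(gm: GenotypeMatrix):
    """Collapse a dosage matrix to one haplotype per accession.

    Homozygous dosages map directly (0 -> 0, 2 -> 1); heterozygous calls are
    resolved to the variant's major allele (soybean selfs, hets are rare).
    Sites with any missing call are dropped.  Returns
    ``(Alignment, n_sites_dropped, n_hets_resolved)``.
    """
    d = gm.dosages
    complete = (d >= 0).all(axis=0)
    dropped = int((~complete).sum())
    d = d[:, complete]
    pos = gm.variants["pos"].to_numpy()[complete]
    freq = d.sum(axis=0) / np.maximum(2.0 * d.shape[0], 1.0)
    major_is_alt = freq > 0.5
    hets = int((d == 1).sum())
    hap = (d == 2).astype(np.int8)
    het_mask = d == 1
    hap = np.where(het_mask, major_is_alt[np.newaxis, :].astype(np.int8), hap)
    return Alignment(hap, pos), dropped, hets


# ---------------------------------------------------------------------------
# Diversity and neutrality
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    """One Table-1-style row: diversity and neutrality for one alignment."""

    n: int
    L: int
    S: int
    eta: int
    eta_s: int
    theta_seq: float
    theta_site: float
    pi_total: float
    pi_site: float
    tajima_d: float
    fuli_dstar: float
    fuli_fstar: float

    @property
    def defined(self) -> bool:
        return self.S > 0

    def scaled(self, factor: float = 1e3) -> dict:
        """Per-site diversities on a report scale (default x1e3)."""
        return {"theta_site": self.theta_site * factor,
                "pi_site": self.pi_site * factor}


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def segregating_sites(aln: Alignment) -> int:
    k = aln.derived_counts()
    return int(((k > 0) & (k < aln.n)).sum())


def pi_total(aln: Alignment) -> float:
    """Mean pairwise Hamming distance over all C(n,2) haplotype pairs."""
    n = aln.n
    if n < 2:
        raise DomainError("pi requires n >= 2 sequences")
    k = aln.derived_counts().astype(float)
    return float((k * (n - k)).sum() / (n * (n - 1) / 2.0))


def diversity(aln: Alignment) -> DiversityStats:
    """S, eta, singletons, Watterson theta and pi, plus the neutrality tests."""
    n, L = aln.n, aln.L
    if n < 2:
        raise DomainError("diversity requires n >= 2 sequences")
    if L < 1:
        return DiversityStats(n, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0,
                              np.nan, np.nan, np.nan)
    S = segregating_sites(aln)
    eta = S  # infinite-sites, biallelic: one mutation per segregating site
    eta_s = int((aln.minor_counts() == 1).sum())
    a1 = _harmonic(n)
    theta_seq = S / a1
    pt = pi_total(aln)
    D = tajimas_d(aln)
    if n >= 4:
        Dstar, Fstar = fu_li_star(aln)
    else:
        Dstar = Fstar = float("nan")
    return DiversityStats(n, L, S, eta, eta_s, theta_seq, theta_seq / L,
                          pt, pt / L, D, Dstar, Fstar)


def tajimas_d(aln: Alignment) -> float:
    """Tajima's (1989) D; NaN when S = 0 or the variance is non-positive."""
    n = aln.n
    if n < 2:
        raise DomainError("Tajima's D requires n >= 2")
    S = segregating_sites(aln)
    if S == 0:
        return float("nan")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total(aln) - S / a1) / math.sqrt(var)


def _fu_li_coeffs(n: int):
    """Variance coefficients for D* and F* (corrected published forms)."""
    a = _harmonic(n)        # a_n
    b = _harmonic(n, 2)     # b_n
    a1 = a + 1.0 / n        # a_{n+1}
    cn = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / ((n - 1) ** 2)
          + (2.0 / (n - 1)) * (1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n))
    vD = (((n / (n - 1.0)) ** 2) * b + (a ** 2) * dn
          - 2.0 * (n * a * (a + 1)) / ((n - 1.0) ** 2)) / (a ** 2 + b)
    uD = (n / (n - 1.0)) * (a - n / (n - 1.0)) - vD
    vF = (dn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1.0))
          - (2.0 / (n - 1)) * (4 * b - 6 + 8.0 / n)) / (a ** 2 + b)
    uF = ((n / (n - 1.0)) + (n + 1) / (3.0 * (n - 1))
          - 4.0 / (n * (n - 1))
          + 2.0 * (n + 1) / ((n - 1.0) ** 2) * (a1 - 2.0 * n / (n + 1))) / a \
        - vF
    return uD, vD, uF, vF


def fu_li_star(aln: Alignment):
    """Fu & Li's (1993) outgroup-free D* and F*.

    Singletons are counted without ancestral-state information (minor allele
    present in exactly one sequence).  Returns ``(nan, nan)`` when S = 0.
    """
    n = aln.n
    if n < 4:
        raise DomainError("Fu & Li's starred statistics require n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        return float("nan"), float("nan")
    eta = float(S)
    eta_s = float((aln.minor_counts() == 1).sum())
    a = _harmonic(n)
    uD, vD, uF, vF = _fu_li_coeffs(n)
    varD = uD * eta + vD * eta ** 2
    varF = uF * eta + vF * eta ** 2
    Dstar = ((n / (n - 1.0)) * eta - a * eta_s) / math.sqrt(varD) \
        if varD > 0 else float("nan")
    Fstar = (pi_total(aln) - ((n - 1.0) / n) * eta_s) / math.sqrt(varF) \
        if varF > 0 else float("nan")
    return Dstar, Fstar


def shared_unique_mutations(aln_a: Alignment, aln_b: Alignment):
    """Counts of (shared, private_A, private_B) polymorphic sites.

    The alignments must cover the same site coordinates.
    """
    if aln_a.L != aln_b.L or not np.array_equal(aln_a.positions,
                                                aln_b.positions):
        raise DomainError("alignments must share site coordinates")
    ka, kb = aln_a.derived_counts(), aln_b.derived_counts()
    poly_a = (ka > 0) & (ka < aln_a.n)
    poly_b = (kb > 0) & (kb < aln_b.n)
    shared = int((poly_a & poly_b).sum())
    return shared, int((poly_a & ~poly_b).sum()), int((poly_b & ~poly_a).sum())


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    fst: float
    per_locus: np.ndarray
    p_value: float
    n_permutations: int
    above_threshold: bool = None


def _wc_components(alt1, called1, het1, alt2, called2, het2):
    """Per-locus Weir-Cockerham (1984) a, b, c for two populations.

    Inputs are per-locus arrays: alt-allele dosage sums, called individual
    counts and heterozygote counts for each population.
    """
    r = 2.0
    n1 = called1.astype(float)
    n2 = called2.astype(float)
    valid = (n1 >= 1) & (n2 >= 1)
    n1 = np.where(valid, n1, np.nan)
    n2 = np.where(valid, n2, np.nan)
    p1 = alt1 / (2.0 * n1)
    p2 = alt2 / (2.0 * n2)
    h1 = het1 / n1
    h2 = het2 / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                     - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2.0
    return a, b, c


def _pop_sums(dosages, mask_rows):
    """Alt sums, called counts and het counts per locus for selected rows."""
    sub = dosages[mask_rows]
    called = (sub >= 0).sum(axis=0).astype(float)
    alt = np.where(sub >= 0, sub, 0).sum(axis=0).astype(float)
    het = (sub == 1).sum(axis=0).astype(float)
    return alt, called, het


def weir_cockerham_fst(gm: GenotypeMatrix, labels: Sequence, n_perm: int = 1000,
                       seed: int = 0, top5_threshold: float = None) -> FstResult:
    """Multi-locus Weir-Cockerham Fst with a label-permutation test.

    The multi-locus estimate is the ratio of summed variance components
    ("ratio of averages"); negative estimates are reported as computed.
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` under random label shuffles.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise DomainError(f"exactly two populations required, got {len(uniq)}")
    mask1 = labels == uniq[0]
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise DomainError("each population needs n >= 2")

    d = gm.dosages

    def fst_for(mask):
        a, b, c = _wc_components(*_pop_sums(d, mask), *_pop_sums(d, ~mask))
        denom = np.nansum(a + b + c)
        num = np.nansum(a)
        with np.errstate(invalid="ignore", divide="ignore"):
            per = a / (a + b + c)
        return (num / denom if denom != 0 else float("nan")), per

    obs, per_locus = fst_for(mask1)

    rng = np.random.default_rng(seed)
    n1 = int(mask1.sum())
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(len(labels), dtype=bool)
        perm[rng.choice(len(labels), size=n1, replace=False)] = True
        f, _ = fst_for(perm)
        if not math.isnan(f) and f >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    above = None if top5_threshold is None else bool(obs >= top5_threshold)
    return FstResult(float(obs), per_locus, p, n_perm, above)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    pairs: pd.DataFrame  # columns i, j, chrom, dist_bp, r2
    n_skipped_monomorphic: int

    def windowed_mean(self, span_bp: int) -> float:
        """Mean r2 over pairs no farther apart than ``span_bp``."""
        sub = self.pairs[self.pairs["dist_bp"] <= span_bp]
        return float(sub["r2"].mean()) if len(sub) else float("nan")


def ld_r2(gm: GenotypeMatrix, window_kb: float = 1000,
          window_snps: int = 99999, r2_min: float = 0.0) -> LDResult:
    """Pairwise r2 (squared Pearson correlation of dosages) within windows.

    Pairs must lie on the same chromosome, within ``window_kb`` kb and within
    ``window_snps`` intervening SNPs.  Accessions missing at either SNP are
    excluded pairwise; monomorphic pairs are skipped and counted.
    """
    if gm.n_variants < 2:
        raise DomainError("ld_r2 requires >= 2 SNPs")
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    d = gm.dosages.astype(float)
    d[d < 0] = np.nan
    rows, skipped = [], 0
    max_bp = window_kb * 1000.0
    for i in range(gm.n_variants - 1):
        for j in range(i + 1, min(i + 1 + window_snps, gm.n_variants)):
            if chroms[j] != chroms[i]:
                continue
            dist = abs(pos[j] - pos[i])
            if dist > max_bp:
                continue
            x, y = d[:, i], d[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2:
                skipped += 1
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                skipped += 1
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            r2 = float(r * r)
            if r2 >= r2_min:
                rows.append((i, j, chroms[i], int(dist), r2))
    pairs = pd.DataFrame(rows, columns=["i", "j", "chrom", "dist_bp", "r2"])
    return LDResult(pairs, skipped)


# ---------------------------------------------------------------------------
# Report layer
# ---------------------------------------------------------------------------

def diversity_table(alignments: dict, scale: float = 1e3) -> pd.DataFrame:
    """Stack per-(gene, population) DiversityStats into a report table.

    ``alignments`` maps ``(gene, population)`` to an :class:`Alignment`.
    Per-site diversities are also given on the report scale (default x1e3).
    """
    rows = []
    for (gene, pop), aln in alignments.items():
        st = diversity(aln)
        rows.append({
            "gene": gene, "population": pop, "N": st.S,
            "theta_seq": st.theta_seq, "theta_site": st.theta_site,
            "pi_site": st.pi_site,
            "theta_site_scaled": st.theta_site * scale,
            "pi_site_scaled": st.pi_site * scale,
            "tajima_D": st.tajima_d, "fuli_Dstar": st.fuli_dstar,
            "fuli_Fstar": st.fuli_fstar,
        })
    return pd.DataFrame(rows)
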