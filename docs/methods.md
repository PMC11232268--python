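# Methods

This note documents the models, estimators, defaults and numerical choices
behind `latisoy`, and what the synthetic-data validation does and does not
establish.

## Data model and conventions

Genotypes live in a `GenotypeMatrix`: accessions × biallelic variants with
allele dosages {0, 1, 2} and −1 for missing. Coordinates are 0-based
half-open internally; 1-based inclusive coordinates appear only in files
(VCF `POS`, the gene-model TSV). Multi-allelic VCF records are skipped with
a logged count. Variant QC uses strict inequalities — keep when
MAF > 0.05, missing fraction < 0.10, heterozygote fraction < 0.10 — and
indels are kept up to 10 bp. The heterozygosity filter is per variant
(fraction of het calls among non-missing), the mixed-model-pipeline
convention; per-accession filtering is not applied. Missing genotypes are
imputed to the per-variant modal dosage (ties to the lower dosage):
deterministic and adequate at desk scale, in place of haplotype-phasing
imputers whose stochastic output would make every downstream number
seed-dependent on external software.

## Diversity and neutrality statistics

Statistics run on binary haplotype alignments. Soybean selfs, so an
accession's genotype is collapsed to one haplotype: homozygous dosages map
directly and the rare heterozygotes resolve to the variant's major allele
(count reported); sites with missing calls are dropped (count reported).

With n sequences, S segregating sites and a₁ = Σ_{i<n} 1/i:

- Watterson's θ per sequence = S/a₁, per site divided by L; π is the mean
  pairwise Hamming distance (per site divided by L). Reports also provide
  the ×10³ scale; the core returns raw values.
- Tajima's D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the 1989 constants
  computed from n. Undefined (NaN) when S = 0 or the variance is ≤ 0.
- Fu & Li's D\* and F\* are the outgroup-free forms: singletons ηₛ are
  sites whose minor allele occurs in exactly one sequence; variance
  coefficients follow the corrected published forms (including the
  Simonsen-corrected F\* terms) that mainstream software implements.
  These statistics carry a small negative bias under the neutral null at
  finite n, so the 3-SE-of-zero validation band over 2000 coalescent
  replicates is a genuine, not loose, check.

F<sub>ST</sub> is the Weir–Cockerham (1984) estimator; multi-locus values
are ratios of summed variance components, and negative estimates are
reported unclamped. The permutation test shuffles population labels and
uses p = (1 + #{F\* ≥ F_obs})/(1 + n_perm), default 1000 permutations.
LD r² is the squared Pearson correlation of dosage vectors over accessions
non-missing at both sites, within 1000-kb / 99 999-SNP windows by default.

## Haplotype networks and the HapA/HapB partition

The median-joining network follows Bandelt–Forster–Röhl: build the
ε-relaxed minimum spanning network under Hamming distance (an edge (u,v)
belongs iff d(u,v) ≤ bottleneck-MST-path(u,v) + ε; ε defaults to 0), then
repeatedly add the majority-consensus median of mutually connected triples
whenever it strictly lowers the network cost, then prune medians of degree
< 3. "Cost" is the spanning-tree weight over the node set (the Steiner
objective); the displayed network may carry equal-weight tie edges.
Candidate medians are evaluated in lexicographic order, making the result
independent of input order. Cost is integer and strictly decreasing across
additions, so termination is guaranteed.

The published grouping of haplotypes into HapA/HapB was an integrative,
not algorithmic, judgement. The reproducible proxy here: average-linkage
agglomerative clustering on pairwise Hamming distances cut at two
clusters; the cluster with the higher mean carrier latitude is HapA
("northward"), ties broken by earlier mean BBD. A gene is unusable when
the larger group exceeds 0.80 carrier share — such genes carry almost no
grouping information and are excluded from the dose model. The region used
is the gene span ± 2 kb (configurable); whether to restrict to coding SNPs
is left to the caller.

## The geographical evolution model

An accession's class is the number of usable genes at which it carries
HapA ("0A" … "GA" for G usable genes). Accessions unassigned at any usable
gene are excluded and counted. Class summaries cross-tabulate population
classes with percentages to two decimals; latitude bands default to
35°N/40°N because panel composition is conventionally quantified in
exactly those bands. Across-class latitude separation uses Duncan's
multiple range test at α = 0.05 (as the reference analyses do, despite its
known liberality) on `scipy.stats.studentized_range`, with protection of
non-significant ranges and a compact letter display; per-gene HapA-vs-HapB
comparisons use Welch's t and the Mann–Whitney rank-sum test (the
published "signed-rank" naming for unpaired groups is taken to mean
rank-sum). Planting-zone prediction maps a class to the latitude band of
its trained class-mean latitude, with nearest-class fallback for unseen
classes.

## Association machinery

**GWAS.** Single-variance-component mixed model with the EMMAX
approximation: kinship K from simple-matching coefficients
(K_ij = mean over SNPs of 1 − |d_i − d_j|/2; eigenvalue-clipped to PSD if
numerically indefinite — the similarity form is used because a distance
matrix is not PSD), eigendecomposed once; δ = σ²_e/σ²_g estimated by
bounded 1-D REML on the null model (intercept + 5 genotype PCs, computed
on the filtered SNP set); each SNP then tested by GLS with fixed
components (Wald t). With K = I the scan reduces exactly to per-SNP OLS.
Significance is Bonferroni α/m.

**Genomic selection.** rrBLUP: y = Xb + Zu + e with u ~ N(0, σ²_u I).
REML over λ = σ²_e/σ²_u via the eigendecomposition of ZZ'; marker effects
u = Z'(ZZ' + λI)⁻¹(y − Xb̂); predictions equal kernel ridge at that λ
(asserted against a closed-form oracle in tests). Markers are centred by
training means by default. Cross-validation is 20 repetitions × 5 folds,
folds balanced to within one accession, the same splits shared across all
SNP scenarios so scenario differences are not split noise.

**Genotype–environment association.** The latent factor mixed model is
implemented in its ridge/least-squares formulation rather than MCMC
(100 000 iterations with 50 000 burn-in are unnecessary at desk scale):
per run, K latent factors are the top left singular vectors of a random
80 % SNP subsample after projecting out the environmental variable; each
SNP's centred genotype is regressed on environment + factors, giving a
z-score; runs are combined by the median z (re-estimation with
resampling stands in for the published multi-run z-combination). λ =
median(z²)/0.4549 (the χ²₁ median convention), p-values are recalibrated
as χ²₁ tails of z²/λ — a monotone transform, so p ranks are unchanged —
and outliers are SNPs with BH q < 0.05. The published cross-entropy rank
selection is replaced by a masked-imputation analog: hold out 5 % of
entries, impute with rank-K truncated SVD, pick the K with the lowest
held-out error.

## Synthetic panels: the stated world

Defaults mirror the emulated panel: 103 wild / 1048 landrace / 1747
cultivar accessions, 7 FT genes. Latitudes are uniform on 20–50°N; the
per-gene HapA probability is logistic in latitude with slope 0.25/degree
centred mid-range, chosen so the carrier probability runs ~0.02 → ~0.98
across the range — the generative link is not published, only the
observed cline, so a logistic link is the minimal monotone choice. Each
gene has 3 fully linked diagnostic SNPs separating HapA/HapB (multi-SNP
strings make haplotype collapsing non-trivial) plus 3 group-independent
SNPs. BBD = 85 − 6 × dose + N(0, 3²) days: −6 d/copy and the 85-day
intercept match the observed ~85 → ~40 day span over eight classes, and
the 3-day noise is the validation world's stated level. Background SNPs
carry Balding–Nichols class structure (F = 0.05) and no latitude signal;
2 % of entries are masked as missing. A single global seed feeds named
substreams (one per concern), so enlarging one block does not perturb
draws elsewhere. The neutral-coalescent simulator (exponential
coalescence at rate k(k−1)/2, Poisson(θℓ/2) infinite-sites mutations per
branch) validates E[S] = θa₁, E[π] = θ and the null means of D, D\*, F\*.

What a green synthetic-data test establishes: the estimators and the
pipeline plumbing are correct, the dose model is recoverable when its
assumptions hold, and the GS/GEA machinery is calibrated under the null.
What it does not establish: real-panel effect sizes, LD decay, selection
or demographic history, genotype×environment interactions across
environments, or the published real-data accuracies — those require the
external panel and are out of scope.

## Known limitations

- Haplotype collapsing assumes near-homozygosity (selfing); highly
  heterozygous panels would need phasing, which is out of scope.
- The MJ implementation enumerates node triples; it is meant for the
  tens-of-haplotypes-per-gene regime, not thousands.
- Duncan's test is liberal by construction; the letters are for parity
  with field practice, not for strict error control.
- Permutation and CV defaults (1000 permutations, 20×5 CV) are the
  reference settings; validation tests scale some of them down and say so.
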