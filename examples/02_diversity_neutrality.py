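"""Per-gene nucleotide diversity and neutrality tests, plus a coalescent
sanity check.

theta (Watterson) and pi (mean pairwise difference) are reported per site
and on the x1e3 report scale; Tajima's D and Fu & Li's D*/F* contrast the
site-frequency spectrum against the neutral expectation (positive values
suggest balancing selection or structure, negative an excess of rare
variants).  Under the standard neutral coalescent all three statistics
average ~0.
"""
import numpy as np

from latisoy.io_formats import extract_gene_region, filter_variants, impute_mode
from latisoy.popgen import alignment_from_genotypes, diversity, diversity_table, tajimas_d
from latisoy.simdata import SimConfig, simulate_neutral_coalescent, simulate_panel

gm, meta, genes, _ = simulate_panel(SimConfig(
    n_wild=30, n_landrace=120, n_cultivar=150, n_background_snps=50, seed=3))
gm_i = impute_mode(filter_variants(gm)[0])

alignments = {}
for gene in genes[:3]:
    region, _ = extract_gene_region(gm_i, gene, flank=2000)
    for pop in ("wild", "landrace", "cultivar"):
        ids = [i for i in meta.info.index[meta.info["pop_class"] == pop]]
        sub = region.take_samples(region.sample_index(ids))
        aln, _, _ = alignment_from_genotypes(sub)
        if aln.L:
            alignments[(gene.gene_id, pop)] = aln

tbl = diversity_table(alignments)
print(tbl.round(3).to_string(index=False))
print("(theta/pi _scaled columns are per-bp diversity x1e3; D, D*, F* are "
      "the neutrality tests)")

rng = np.random.default_rng(0)
ds = [tajimas_d(simulate_neutral_coalescent(10, 5.0, rng=rng))
      for _ in range(500)]
ds = [d for d in ds if not np.isnan(d)]
print(f"\nneutral coalescent (n=10, theta=5): mean Tajima's D over "
      f"{len(ds)} replicates = {np.mean(ds):+.3f} (expected ~0)")
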