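"""The geographical evolution model: HapA-dose classes (0A..7A), their
latitude gradient, the BBD dose-response, and planting-zone prediction.

An accession's class counts the genes at which it carries the northward
haplotype; with a positive latitude cline, mean collection latitude rises
with the class and beginning bloom date falls roughly linearly with it.
"""
from latisoy import geomodel, hapnet
from latisoy.io_formats import extract_gene_region, filter_variants, impute_mode
from latisoy.simdata import SimConfig, simulate_panel

gm, meta, genes, truth = simulate_panel(SimConfig(
    n_wild=30, n_landrace=250, n_cultivar=250, n_background_snps=0, seed=9))
gm_i = impute_mode(filter_variants(gm)[0])

groupings, calls = {}, {}
for gene in genes:
    region, _ = extract_gene_region(gm_i, gene)
    haps, _ = hapnet.call_haplotypes(region, gene.gene_id, meta)
    calls[gene.gene_id] = haps
    groupings[gene.gene_id] = hapnet.partition_hapAB(haps, meta=meta)

asg = geomodel.assign_classes(groupings, calls)
summary = geomodel.class_frequency_table(asg, meta)
print("class composition (counts by population class, percent of panel):")
print(summary.table.to_string())

lat = geomodel.latitude_association(asg, meta)
print("\nmean latitude per class with Duncan multiple-range letters "
      "(classes sharing a letter are not separable at P<0.05):")
print(lat.per_class.round(2).to_string())

means, r = geomodel.bbd_dose_response(asg, meta, "BJ13")
print(f"\nBBD (days) per class:\n{means.round(1).to_string()}")
print(f"Pearson r of BBD on HapA dose: {r:+.2f} "
      "(negative: more northward haplotypes -> earlier flowering)")

pred = geomodel.predict_planting_zone(
    {"cultivarX": "7A", "cultivarY": "4A", "cultivarZ": "0A"}, summary)
print("\npredicted planting zones from the trained class latitudes:")
print(pred[["class", "predicted_latitude", "band"]].to_string())
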