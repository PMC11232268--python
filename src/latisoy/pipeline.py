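"""End-to-end pipeline: simulate/load -> filter -> per-gene analyses ->
geographical model -> association stages, with reproducible seeds and a
machine-readable run-metadata record.

Stage parameter defaults are the analysis's printed settings: 2 kb flanks,
MAF > 0.05, missing < 0.10, heterozygosity < 0.10, indels <= 10 bp, 1000
Fst permutations, 20x fivefold cross-validation, alpha 0.05, q < 0.05,
predominance cutoff 0.80, latitude bands at 35/40 degrees N.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import assoc, geomodel, hapnet, popgen
from .io_formats import (AccessionMeta, GenotypeMatrix, extract_gene_region,
                         filter_variants, impute_mode)
from .simdata import SimConfig, simulate_panel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the analysis's printed values."""

    sim: SimConfig = field(default_factory=SimConfig)
    flank: int = 2000
    maf_min: float = 0.05
    miss_max: float = 0.10
    het_max: float = 0.10
    indel_max_len: int = 10
    n_perm: int = 1000
    cv_reps: int = 20
    cv_folds: int = 5
    alpha: float = 0.05
    q_cut: float = 0.05
    predominance_max: float = 0.80
    band_breaks: tuple = (35.0, 40.0)
    gea_factors: int = 3
    n_pcs: int = 5
    env: str = "BJ13"
    seed: int = 0
    run_gwas: bool = True
    run_gs: bool = True
    run_gea: bool = True
    out_dir: str = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated panel.

    Returns a dict of in-memory results; when ``config.out_dir`` is set,
    also writes the TSV outputs plus ``run_metadata.json``.
    """
    t0 = time.time()
    config.sim.seed = config.seed
    gm, meta, genes, truth = simulate_panel(config.sim)

    gm_f, filter_report = filter_variants(
        gm, config.maf_min, config.miss_max, config.het_max,
        config.indel_max_len)
    gm_i = impute_mode(gm_f)

    # per-gene: region -> haplotypes -> network -> grouping -> diversity
    groupings, hap_calls, networks, stats_rows = {}, {}, {}, {}
    for gene in genes:
        region, _ = extract_gene_region(gm_i, gene, config.flank)
        haps, n_het = hapnet.call_haplotypes(region, gene.gene_id, meta)
        hap_calls[gene.gene_id] = haps
        networks[gene.gene_id] = hapnet.median_joining_network(haps)
        groupings[gene.gene_id] = hapnet.partition_hapAB(
            haps, networks[gene.gene_id], meta, config.env,
            config.predominance_max)
        aln, _, _ = popgen.alignment_from_genotypes(region)
        for pop in ("wild", "landrace", "cultivar"):
            ids = meta.info.index[meta.info["pop_class"] == pop]
            rows = region.sample_index([i for i in ids
                                        if i in set(region.samples)])
            if len(rows) >= 4:
                sub, _, _ = popgen.alignment_from_genotypes(
                    region.take_samples(rows))
                if sub.L:
                    stats_rows[(gene.gene_id, pop)] = sub
    diversity_tbl = popgen.diversity_table(stats_rows)

    assignments = geomodel.assign_classes(groupings, hap_calls)
    summary = geomodel.class_frequency_table(assignments, meta)
    lat_assoc = geomodel.latitude_association(assignments, meta)
    bbd_means, bbd_r = geomodel.bbd_dose_response(assignments, meta,
                                                 config.env)
    zones = geomodel.predict_planting_zone(assignments.labels, summary,
                                           config.band_breaks)

    results = {
        "filter_report": filter_report,
        "groupings": groupings,
        "networks": networks,
        "diversity": diversity_tbl,
        "assignments": assignments,
        "class_summary": summary,
        "latitude_association": lat_assoc,
        "bbd_class_means": bbd_means,
        "bbd_dose_r": bbd_r,
        "planting_zones": zones,
        "truth": truth,
    }

    y = meta.trait(config.env, "BBD").reindex(gm_i.samples).to_numpy()
    if config.run_gwas:
        K = assoc.kinship_simple_matching(gm_i)
        results["gwas"] = assoc.mlm_gwas(gm_i, y, K, config.n_pcs,
                                         config.alpha)
    if config.run_gs:
        gene_chroms = {g.chrom for g in genes}
        in_genes = gm_i.variants["chrom"].isin(gene_chroms).to_numpy()
        rng = np.random.default_rng(config.seed)
        n_sparse = min(10, gm_i.n_variants)
        scenarios = {
            "genomewide": np.arange(gm_i.n_variants),
            "ft_genes": np.flatnonzero(in_genes),
            "sparse_random": rng.choice(np.flatnonzero(~in_genes)
                                        if (~in_genes).any()
                                        else np.arange(gm_i.n_variants),
                                        size=n_sparse, replace=False),
        }
        results["gs"] = assoc.cross_validate_gs(
            gm_i, y, scenarios, config.cv_folds, config.cv_reps,
            config.seed, env=config.env)
    if config.run_gea:
        lat = meta.latitudes(gm_i.samples).to_numpy()
        results["gea"] = assoc.lfmm_gea(gm_i, lat, config.gea_factors,
                                        reps=10, seed=config.seed)

    results["runtime_s"] = time.time() - t0
    if config.out_dir is not None:
        _write_outputs(config, results)
    return results


def _write_outputs(config: RunConfig, results: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["diversity"].to_csv(out / "diversity.tsv", sep="\t", index=False)
    results["class_summary"].table.to_csv(out / "class_table.tsv", sep="\t")
    results["latitude_association"].per_class.to_csv(
        out / "class_latitude.tsv", sep="\t")
    results["planting_zones"].to_csv(out / "planting_zones.tsv", sep="\t")
    grouping_rows = [
        {"gene": g, "haplotype": h, "group": lab,
         "usable": grp.usable, "predominance": grp.predominance}
        for g, grp in results["groupings"].items()
        for h, lab in grp.assignment.items()]
    pd.DataFrame(grouping_rows).to_csv(out / "hap_grouping.tsv", sep="\t",
                                       index=False)
    if "gwas" in results:
        results["gwas"].table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    if "gs" in results:
        gs_rows = [{"scenario": r.scenario, "env": r.env, "fold": i,
                    "r": v} for r in results["gs"]
                   for i, v in enumerate(r.fold_r)]
        pd.DataFrame(gs_rows).to_csv(out / "gs.tsv", sep="\t", index=False)
    if "gea" in results:
        results["gea"].table.to_csv(out / "gea.tsv", sep="\t", index=False)
    meta_json = {
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("sim",)},
        "sim": asdict(config.sim),
        "bbd_dose_r": results["bbd_dose_r"],
        "runtime_s": results["runtime_s"],
    }
    if "gea" in results:
        meta_json["lambda_gc"] = results["gea"].lambda_gc
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta_json, fh, indent=2, default=str)
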