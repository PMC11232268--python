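"""Haplotype collapsing, median-joining networks and HapA/HapB grouping.

A gene region's genotypes are collapsed to allele strings over the region's
filtered variants ('0' = ref, '1' = alt; heterozygotes resolve to the major
allele, with the count reported).  The median-joining algorithm of Bandelt,
Forster & Roehl builds a network over observed haplotypes plus inferred
median (Steiner) vectors; the two-group partition is a reproducible proxy
for the integrative grouping used in practice: average-linkage clustering
on Hamming distances cut at two clusters, with the higher-latitude cluster
labelled HapA ("northward").
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import AccessionMeta, DomainError, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class Haplotype:
    """One collapsed allele string with its carriers."""

    gene_id: str
    alleles: str
    carriers: list
    frequency: float
    pop_counts: dict = field(default_factory=dict)


def call_haplotypes(region_gm: GenotypeMatrix, gene_id: str = "",
                    meta: AccessionMeta = None):
    """Collapse an (imputed) gene-region matrix into haplotypes.

    Dosage 0 -> '0', 2 -> '1'; dosage 1 resolves to the variant's major
    allele (het count logged).  Returns ``(haplotypes, n_hets_resolved)``
    with haplotypes sorted by decreasing frequency then allele string.
    """
    n = region_gm.n_samples
    if region_gm.n_variants == 0:
        log.warning("call_haplotypes(%s): no variants in region", gene_id)
        hap = Haplotype(gene_id, "", list(region_gm.samples), 1.0)
        _fill_pop_counts([hap], meta)
        return [hap], 0
    d = region_gm.dosages
    if (d < 0).any():
        raise DomainError("region must be imputed before haplotype calling")
    freq = d.sum(axis=0) / (2.0 * max(n, 1))
    major_is_alt = freq > 0.5
    n_het = int((d == 1).sum())
    alleles = (d == 2).astype(np.int8)
    alleles = np.where(d == 1, major_is_alt[np.newaxis, :].astype(np.int8),
                       alleles)
    strings = ["".join("1" if a else "0" for a in row) for row in alleles]
    carriers: dict = {}
    for acc, s in zip(region_gm.samples, strings):
        carriers.setdefault(s, []).append(acc)
    haps = [Haplotype(gene_id, s, accs, len(accs) / n)
            for s, accs in carriers.items()]
    haps.sort(key=lambda h: (-h.frequency, h.alleles))
    _fill_pop_counts(haps, meta)
    return haps, n_het


def _fill_pop_counts(haps, meta):
    if meta is None:
        return
    pc = meta.info["pop_class"]
    for h in haps:
        h.pop_counts = pc.reindex(h.carriers).value_counts().to_dict()


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

@dataclass
class HapNetwork:
    graph: nx.Graph          # nodes = allele strings; attr is_median
    epsilon: int
    total_cost: int          # spanning-tree weight over the node set

    @property
    def medians(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes, eps: int):
    """Epsilon-relaxed minimum spanning network over Hamming distance.

    A pair (u, v) is an edge iff d(u, v) <= sigma(u, v) + eps, where
    sigma(u, v) is the bottleneck (minimax) distance: the largest edge
    weight on the path between u and v in any minimum spanning tree.  With
    eps = 0 this is the classical minimum spanning network (the union of
    all MSTs).
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        return []
    complete = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        complete.add_edge(u, v, weight=_hamming(u, v))
    mst = nx.minimum_spanning_tree(complete)
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        path = nx.shortest_path(mst, u, v)
        sigma = max(mst[a][b]["weight"] for a, b in zip(path, path[1:]))
        d = complete[u][v]["weight"]
        if d <= sigma + eps:
            edges.append((u, v, d))
    return edges


def _network_cost(nodes, eps: int) -> int:
    """Total cost = minimum-spanning-tree weight over the node set.

    This is the Steiner-style objective the median-addition step minimises;
    the displayed network (MSN) may carry additional equal-weight tie edges.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        return 0
    g = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=_hamming(u, v))
    return sum(d["weight"] for _, _, d in
               nx.minimum_spanning_tree(g).edges(data=True))


def median_joining_network(haps, epsilon: int = 0) -> HapNetwork:
    """Bandelt-Forster-Roehl median-joining network over haplotypes.

    Iteratively adds the majority-consensus median of mutually connected
    node triples whenever it strictly reduces the total network cost, then
    prunes median vectors of degree < 3.  Deterministic: candidate medians
    are considered in lexicographic order of their allele strings.
    """
    if not haps:
        raise DomainError("median_joining_network requires >= 1 haplotype")
    observed = [h.alleles for h in haps]
    if len(set(observed)) != len(observed):
        raise DomainError("duplicate haplotype strings; merge carriers first")
    L = len(observed[0])
    if any(len(s) != L for s in observed):
        raise DomainError("haplotype strings differ in length")

    nodes = list(observed)
    if len(nodes) == 1 or L == 0:
        g = nx.Graph()
        g.add_nodes_from(nodes, is_median=False)
        return HapNetwork(g, epsilon, 0)

    cost = _network_cost(nodes, epsilon)
    while True:
        edges = _msn_edges(nodes, epsilon)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(edges)
        candidates = set()
        for u, v, w in itertools.combinations(nodes, 3):
            if g.has_edge(u, v) and g.has_edge(u, w) and g.has_edge(v, w):
                med = "".join(
                    "1" if (a + b + c) >= 2 else "0"
                    for a, b, c in ((int(x), int(y), int(z))
                                    for x, y, z in zip(u, v, w)))
                if med not in nodes:
                    candidates.add(med)
        best = None
        for med in sorted(candidates):
            new_cost = _network_cost(nodes + [med], epsilon)
            if new_cost < cost and (best is None or new_cost < best[1]):
                best = (med, new_cost)
        if best is None:
            break
        nodes.append(best[0])
        cost = best[1]

    # prune medians that are not junctions (degree < 3)
    observed_set = set(observed)
    while True:
        edges = _msn_edges(nodes, epsilon)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(edges)
        removable = [nd for nd in nodes if nd not in observed_set
                     and g.degree(nd) < 3]
        if not removable:
            break
        nodes = [nd for nd in nodes if nd not in removable]
    cost = _network_cost(nodes, epsilon)
    final = nx.Graph()
    for nd in nodes:
        final.add_node(nd, is_median=nd not in observed_set)
    final.add_weighted_edges_from(_msn_edges(nodes, epsilon))
    return HapNetwork(final, epsilon, cost)


# ---------------------------------------------------------------------------
# HapA / HapB partition
# ---------------------------------------------------------------------------

@dataclass
class HapGrouping:
    gene_id: str
    assignment: dict          # haplotype allele string -> "HapA" | "HapB"
    predominance: float       # carrier share of the larger group
    usable: bool

    def group_of(self, allele_string: str) -> str:
        return self.assignment.get(allele_string, "unassigned")


def partition_hapAB(haps, network: HapNetwork = None,
                    meta: AccessionMeta = None, env: str = None,
                    predominance_max: float = 0.80) -> HapGrouping:
    """Two-group haplotype partition with latitude-based labelling.

    Average-linkage agglomerative clustering on pairwise Hamming distances,
    cut at two clusters.  The cluster whose carriers have the higher mean
    collection latitude is HapA (northward); ties break toward the cluster
    with the earlier mean BBD.  ``usable`` is False when the larger group
    carries more than ``predominance_max`` of accessions.
    """
    gene_id = haps[0].gene_id if haps else ""
    if len(haps) < 2:
        return HapGrouping(gene_id, {h.alleles: "HapA" for h in haps},
                           1.0, False)
    strings = [h.alleles for h in haps]
    mat = np.array([[int(c) for c in s] for s in strings], dtype=float)
    condensed = pdist(mat, metric="hamming") * mat.shape[1]
    labels = fcluster(linkage(condensed, method="average"), t=2,
                      criterion="maxclust")
    clusters = {1: [], 2: []}
    for h, lab in zip(haps, labels):
        clusters[int(lab)].append(h)
    if not clusters[1] or not clusters[2]:  # degenerate cut
        return HapGrouping(gene_id, {s: "HapA" for s in strings}, 1.0, False)

    def carriers(cluster):
        out = []
        for h in cluster:
            out.extend(h.carriers)
        return out

    def mean_lat(cluster):
        if meta is None:
            return float("nan")
        return float(meta.latitudes(carriers(cluster)).mean())

    lat1, lat2 = mean_lat(clusters[1]), mean_lat(clusters[2])
    if np.isnan(lat1) or np.isnan(lat2) or lat1 == lat2:
        if meta is not None and env is not None:
            bbd = meta.trait(env, "BBD")
            b1 = bbd.reindex(carriers(clusters[1])).mean()
            b2 = bbd.reindex(carriers(clusters[2])).mean()
            hapA_key = 1 if b1 <= b2 else 2
        else:
            hapA_key = 1
    else:
        hapA_key = 1 if lat1 > lat2 else 2
    assignment = {}
    for key, group in clusters.items():
        label = "HapA" if key == hapA_key else "HapB"
        for h in group:
            assignment[h.alleles] = label
    nA = len(carriers(clusters[hapA_key]))
    nB = len(carriers(clusters[1 if hapA_key == 2 else 2]))
    total = nA + nB
    predominance = max(nA, nB) / total if total else 1.0
    usable = predominance <= predominance_max
    return HapGrouping(gene_id, assignment, predominance, usable)


def haplotype_table(haps) -> pd.DataFrame:
    rows = [{"gene": h.gene_id, "alleles": h.alleles,
             "n_carriers": len(h.carriers), "frequency": h.frequency,
             **{f"n_{k}": v for k, v in sorted(h.pop_counts.items())}}
            for h in haps]
    return pd.DataFrame(rows)
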