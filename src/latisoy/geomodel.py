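"""The geographical evolution model: HapA dose classes and their geography.

Each accession is scored by the number of usable flowering-time genes at
which it carries the northward haplotype group (HapA); with G usable genes
the classes run "0A" .. "GA".  Class composition, latitude and
beginning-bloom-date summaries, multiple-range comparisons across classes,
and a latitude-band planting-zone predictor mirror how such models are used
to place cultivars.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AccessionMeta, DomainError
from .hapnet import HapGrouping

log = logging.getLogger(__name__)

DEFAULT_BAND_BREAKS = (35.0, 40.0)
DEFAULT_BAND_NAMES = ("southern (<35N)", "Huang-Huai-Hai (35-40N)",
                      "northern (>40N)")


@dataclass
class ClassAssignment:
    """Per-accession HapA dose over the usable genes."""

    table: pd.DataFrame   # index accession; per-gene group columns + hapA_count + class_label
    usable_genes: list
    n_excluded: int = 0

    @property
    def G(self) -> int:
        return len(self.usable_genes)

    @property
    def counts(self) -> pd.Series:
        return self.table["hapA_count"]

    @property
    def labels(self) -> pd.Series:
        return self.table["class_label"]


def assign_classes(groupings, hap_calls) -> ClassAssignment:
    """Count HapA genes per accession over the usable groupings.

    ``groupings``: mapping gene -> HapGrouping; ``hap_calls``: mapping
    gene -> list of Haplotype (carriers of each allele string).  Genes with
    ``usable=False`` are excluded from the count and from G; accessions
    unassigned at any usable gene are excluded (count reported).
    """
    usable = [g for g, grp in groupings.items() if grp.usable]
    if not usable:
        raise DomainError("no usable gene groupings (all predominance-failed)")
    per_gene = {}
    for gene in usable:
        grp = groupings[gene]
        col = {}
        for hap in hap_calls[gene]:
            label = grp.group_of(hap.alleles)
            for acc in hap.carriers:
                col[acc] = label
        per_gene[gene] = col
    df = pd.DataFrame(per_gene)
    complete = df.notna().all(axis=1) & (df != "unassigned").all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        log.info("assign_classes: excluded %d accession(s) with unassigned "
                 "genes", n_excluded)
    df = df[complete]
    count = (df == "HapA").sum(axis=1)
    df = df.assign(hapA_count=count,
                   class_label=[f"{c}A" for c in count])
    return ClassAssignment(df, usable, n_excluded)


@dataclass
class ClassSummary:
    """Class x population-class composition with latitude/BBD means."""

    table: pd.DataFrame        # index class; wild/landrace/cultivar/total/percent
    mean_latitude: pd.Series   # per class
    mean_bbd: pd.DataFrame     # class x env
    n_classified: int

    def percent(self, classes) -> float:
        """Combined percentage of one or more classes (2-dp convention)."""
        if isinstance(classes, str):
            classes = [classes]
        total = self.table.loc[list(classes), "total"].sum()
        return round(100.0 * total / self.n_classified, 2)


def class_frequency_table(assignments: ClassAssignment,
                          meta: AccessionMeta) -> ClassSummary:
    """Cross-tabulate classes by population class, with percentages.

    Percentages are class total / classified total x 100, reported to two
    decimals; per-class mean latitude and mean BBD per environment ride
    along when available.
    """
    df = assignments.table
    if df.empty:
        raise DomainError("no classified accessions")
    G = assignments.G
    order = [f"{k}A" for k in range(G + 1)]
    pc = meta.info["pop_class"].reindex(df.index)
    tab = pd.crosstab(df["class_label"], pc).reindex(order, fill_value=0)
    for col in ("wild", "landrace", "cultivar"):
        if col not in tab:
            tab[col] = 0
    tab = tab[["wild", "landrace", "cultivar"]]
    tab["total"] = tab.sum(axis=1)
    n = int(tab["total"].sum())
    tab["percent"] = (100.0 * tab["total"] / n).round(2)
    lat = meta.latitudes(df.index)
    mean_lat = lat.groupby(df["class_label"]).mean().reindex(order)
    envs = meta.envs()
    bbd_cols = {}
    for env in envs:
        bbd = meta.trait(env, "BBD").reindex(df.index)
        bbd_cols[env] = bbd.groupby(df["class_label"]).mean().reindex(order)
    mean_bbd = pd.DataFrame(bbd_cols)
    return ClassSummary(tab, mean_lat, mean_bbd, n)


def latitude_band_composition(assignments: ClassAssignment,
                              meta: AccessionMeta,
                              breaks=DEFAULT_BAND_BREAKS) -> pd.DataFrame:
    """Class composition within latitude bands (default <35, 35-40, >40)."""
    df = assignments.table
    lat = meta.latitudes(df.index)
    edges = [-np.inf, *breaks, np.inf]
    band = pd.cut(lat, edges, labels=DEFAULT_BAND_NAMES[:len(edges) - 1])
    return pd.crosstab(band, df["class_label"])


# ---------------------------------------------------------------------------
# Association with latitude and BBD
# ---------------------------------------------------------------------------

def _duncan_letters(groups: dict, alpha: float = 0.05) -> dict:
    """Duncan's multiple range test with a compact letter display.

    ``groups`` maps label -> 1-D array of observations.  Returns
    label -> letters; groups sharing a letter are not significantly
    different at the (per-span-adjusted) level alpha.
    """
    labels = [k for k, v in groups.items() if len(v) >= 2]
    if len(labels) < 2:
        return {k: "a" for k in groups}
    means = {k: float(np.mean(groups[k])) for k in labels}
    ns = {k: len(groups[k]) for k in labels}
    N = sum(ns.values())
    k = len(labels)
    sse = sum(float(np.sum((np.asarray(groups[g]) - means[g]) ** 2))
              for g in labels)
    df_err = N - k
    mse = sse / df_err if df_err > 0 else 0.0
    order = sorted(labels, key=lambda g: means[g], reverse=True)
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    # spans largest-first so protected (non-significant) ranges absorb
    # their sub-ranges, the classical stepwise rule
    for span in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err) \
            if df_err > 0 else np.inf
        for i in range(0, k - span + 1):
            j = i + span - 1
            gi, gj = order[i], order[j]
            nh = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            lsr = q * np.sqrt(mse / nh)
            if nonsig[i, j]:
                continue
            if abs(means[gi] - means[gj]) <= lsr:
                nonsig[i:j + 1, i:j + 1] = True
    # compact letters from maximal non-significant rank intervals
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i:j + 2, i:j + 2].all():
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    letters = {g: "" for g in labels}
    for letter_idx, (a, b) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for g in order[a:b + 1]:
            letters[g] += ch
    for g in groups:
        letters.setdefault(g, "")
    return letters


@dataclass
class LatitudeAssociation:
    per_class: pd.DataFrame      # class: n, mean, sd latitude, duncan letters
    per_gene_tests: pd.DataFrame  # gene: t p, rank-sum p for HapA vs HapB


def latitude_association(assignments: ClassAssignment, meta: AccessionMeta,
                         alpha: float = 0.05) -> LatitudeAssociation:
    """Latitude by class (Duncan letters) and per-gene HapA-vs-HapB tests.

    Per gene, carrier latitudes of the two haplotype groups are compared by
    a two-tailed Welch t-test and a Wilcoxon rank-sum (Mann-Whitney) test.
    Classes with n < 2 are excluded from the range test.
    """
    df = assignments.table
    lat = meta.latitudes(df.index)
    groups = {lab: lat[df["class_label"] == lab].dropna().to_numpy()
              for lab in sorted(df["class_label"].unique(),
                                key=lambda s: int(s[:-1]))}
    eligible = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(eligible) < 2:
        raise DomainError("need >= 2 classes with >= 2 members")
    letters = _duncan_letters(eligible, alpha)
    rows = []
    for lab, vals in groups.items():
        rows.append({"class": lab, "n": len(vals),
                     "mean_latitude": float(np.mean(vals)) if len(vals) else np.nan,
                     "sd_latitude": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                     "duncan": letters.get(lab, "")})
    per_class = pd.DataFrame(rows).set_index("class")

    gene_rows = []
    for gene in assignments.usable_genes:
        a = lat[df[gene] == "HapA"].dropna()
        b = lat[df[gene] == "HapB"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            t_p = stats.ttest_ind(a, b, equal_var=False).pvalue
            w_p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            t_p = w_p = np.nan
        gene_rows.append({"gene": gene, "mean_lat_HapA": a.mean(),
                          "mean_lat_HapB": b.mean(),
                          "welch_t_p": t_p, "ranksum_p": w_p})
    return LatitudeAssociation(per_class, pd.DataFrame(gene_rows))


def bbd_dose_response(assignments: ClassAssignment, meta: AccessionMeta,
                      env: str):
    """Per-class mean BBD and the Pearson r of BBD on HapA count.

    Returns ``(per_class_means: Series, r: float)``; raises when fewer than
    three accessions carry a phenotype in the environment.
    """
    df = assignments.table
    bbd = meta.trait(env, "BBD").reindex(df.index)
    ok = bbd.notna()
    if int(ok.sum()) < 3:
        raise DomainError(f"fewer than 3 accessions phenotyped in {env}")
    count = df.loc[ok, "hapA_count"].astype(float)
    means = bbd.groupby(df["class_label"]).mean()
    order = sorted(means.index, key=lambda s: int(s[:-1]))
    r = float(stats.pearsonr(count, bbd[ok])[0])
    return means.reindex(order), r


# ---------------------------------------------------------------------------
# Planting-zone prediction
# ---------------------------------------------------------------------------

def predict_planting_zone(class_labels, summary: ClassSummary,
                          breaks=DEFAULT_BAND_BREAKS,
                          names=DEFAULT_BAND_NAMES) -> pd.DataFrame:
    """Map accessions to the latitude band of their class's trained mean.

    ``class_labels``: mapping or Series accession -> class label ("4A").
    Unseen classes fall back to the nearest trained class (warned).
    """
    labels = pd.Series(class_labels)
    trained = summary.mean_latitude.dropna()
    if trained.empty:
        raise DomainError("trained summary has no class latitude means")
    trained_dose = {int(k[:-1]): v for k, v in trained.items()}
    edges = [-np.inf, *breaks, np.inf]

    def band_of(latitude: float) -> str:
        idx = int(np.searchsorted(breaks, latitude, side="right"))
        return names[idx]

    rows = []
    for acc, lab in labels.items():
        dose = int(str(lab)[:-1])
        if dose in trained_dose:
            lat = trained_dose[dose]
            fallback = False
        else:
            nearest = min(trained_dose, key=lambda d: abs(d - dose))
            log.warning("predict_planting_zone: unseen class %s, using "
                        "nearest trained class %dA", lab, nearest)
            lat = trained_dose[nearest]
            fallback = True
        rows.append({"id": acc, "class": lab, "predicted_latitude": lat,
                     "band": band_of(lat), "nearest_class_fallback": fallback})
    return pd.DataFrame(rows).set_index("id")
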