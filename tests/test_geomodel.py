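import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latisoy.geomodel import (ClassAssignment, assign_classes,
                              bbd_dose_response, class_frequency_table,
                              latitude_association, latitude_band_composition,
                              predict_planting_zone)
from latisoy.hapnet import HapGrouping, Haplotype
from latisoy.io_formats import AccessionMeta, DomainError


def _grouping(gene, usable=True):
    return HapGrouping(gene, {"0": "HapB", "1": "HapA"}, 0.5, usable)


def _calls(gene, hapA_accs, hapB_accs):
    n = len(hapA_accs) + len(hapB_accs)
    return [Haplotype(gene, "1", list(hapA_accs), len(hapA_accs) / n),
            Haplotype(gene, "0", list(hapB_accs), len(hapB_accs) / n)]


def _meta(lats, pop_class="landrace", bbd=None, env="BJ13"):
    info = pd.DataFrame({"pop_class": pop_class, "country": "x",
                         "latitude": pd.Series(lats), "longitude": 110.0})
    info.index.name = "id"
    pheno = None
    if bbd is not None:
        pheno = pd.DataFrame({"id": list(bbd), "env": env,
                              "BBD": list(bbd.values()),
                              "FBD": np.nan, "MD": np.nan})
    return AccessionMeta(info, pheno)


class TestAssignClasses:
    def make(self, n_genes=7, hapA_genes=None, unusable=()):
        """One accession 'x' plus a backdrop accession 'y' (all HapB)."""
        hapA_genes = set(hapA_genes or [])
        groupings, calls = {}, {}
        for g in range(n_genes):
            gene = f"G{g}"
            groupings[gene] = _grouping(gene, usable=gene not in unusable)
            a = ["x"] if gene in hapA_genes else []
            b = (["y"] if gene in hapA_genes else ["x", "y"])
            calls[gene] = _calls(gene, a + (["y"] if False else []),
                                 b)
        return groupings, calls

    def test_all_seven_hapA_is_7A(self):
        groupings, calls = self.make(hapA_genes=[f"G{g}" for g in range(7)])
        asg = assign_classes(groupings, calls)
        assert asg.labels["x"] == "7A" and asg.labels["y"] == "0A"

    def test_three_of_seven_is_3A(self):
        groupings, calls = self.make(hapA_genes=["G0", "G2", "G5"])
        asg = assign_classes(groupings, calls)
        assert asg.labels["x"] == "3A"

    def test_unusable_gene_excluded_from_G(self):
        groupings, calls = self.make(n_genes=8,
                                     hapA_genes=[f"G{g}" for g in range(8)],
                                     unusable={"G7"})
        asg = assign_classes(groupings, calls)
        assert asg.G == 7
        assert asg.labels["x"] == "7A"  # classes run 0A..7A

    def test_no_usable_genes_errors(self):
        groupings, calls = self.make(n_genes=2, unusable={"G0", "G1"})
        with pytest.raises(DomainError):
            assign_classes(groupings, calls)


def assignment_from_counts(counts_by_class, pop_breakdown=None):
    """Build a ClassAssignment table holding stated class totals."""
    rows, ids = [], []
    i = 0
    for cls, total in counts_by_class.items():
        for _ in range(total):
            ids.append(f"a{i}")
            rows.append({"hapA_count": int(cls[:-1]), "class_label": cls})
            i += 1
    table = pd.DataFrame(rows, index=ids)
    G = max(int(c[:-1]) for c in counts_by_class)
    return ClassAssignment(table, [f"G{k}" for k in range(G)], 0)


class TestClassFrequencyTable:
    def test_percentages_and_partition(self):
        counts = {"0A": 10, "1A": 30, "2A": 60}
        asg = assignment_from_counts(counts)
        meta = _meta({f"a{i}": 30.0 for i in range(100)})
        s = class_frequency_table(asg, meta)
        assert s.n_classified == 100
        assert s.table["total"].sum() == 100
        assert s.percent("2A") == 60.0
        assert s.table["percent"].sum() == pytest.approx(100, abs=0.01)

    def test_single_class_is_100_percent(self):
        asg = assignment_from_counts({"2A": 7})
        meta = _meta({f"a{i}": 30.0 for i in range(7)})
        s = class_frequency_table(asg, meta)
        assert s.table.loc["2A", "percent"] == 100.0


class TestLatitudeAssociation:
    def test_disjoint_ranges_tiny_p(self):
        lats = {f"a{i}": 25.0 + 0.01 * i for i in range(40)}
        lats.update({f"b{i}": 45.0 + 0.01 * i for i in range(40)})
        table = pd.DataFrame(
            {"G0": ["HapB"] * 40 + ["HapA"] * 40,
             "hapA_count": [0] * 40 + [1] * 40,
             "class_label": ["0A"] * 40 + ["1A"] * 40},
            index=list(lats))
        asg = ClassAssignment(table, ["G0"], 0)
        res = latitude_association(asg, _meta(lats))
        assert res.per_gene_tests["welch_t_p"].iloc[0] < 1e-6
        assert res.per_gene_tests["ranksum_p"].iloc[0] < 1e-6
        letters = res.per_class["duncan"]
        assert set(letters["0A"]).isdisjoint(set(letters["1A"]))

    def test_null_test_size(self):
        """Identical latitude distributions: p > 0.05 in >= 94% of sims."""
        rng = np.random.default_rng(17)
        ok = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.normal(35, 5, size=12)
            b = rng.normal(35, 5, size=12)
            ok += stats.ttest_ind(a, b, equal_var=False).pvalue > 0.05
        assert ok / n_sims >= 0.94

    def test_small_class_excluded(self):
        lats = {"a0": 30.0, "a1": 31.0, "a2": 45.0, "a3": 46.0, "only": 50.0}
        table = pd.DataFrame(
            {"G0": ["HapB", "HapB", "HapA", "HapA", "HapA"],
             "hapA_count": [0, 0, 1, 1, 1],
             "class_label": ["0A", "0A", "1A", "1A", "2A"]},
            index=list(lats))
        asg = ClassAssignment(table, ["G0"], 0)
        res = latitude_association(asg, _meta(lats))
        assert res.per_class.loc["2A", "duncan"] == ""


class TestBBDDoseResponse:
    def _panel_assignment(self, big_panel):
        gm, meta, genes, truth = big_panel
        table = pd.DataFrame({"hapA_count": truth.hapA_count,
                              "class_label": [f"{c}A"
                                              for c in truth.hapA_count]})
        return ClassAssignment(table, list(truth.groups.columns), 0), meta

    def test_zero_effect_zero_correlation(self):
        rng = np.random.default_rng(3)
        n = 2000
        counts = rng.integers(0, 8, size=n)
        ids = [f"a{i}" for i in range(n)]
        bbd = dict(zip(ids, rng.normal(60, 5, size=n)))
        table = pd.DataFrame({"hapA_count": counts,
                              "class_label": [f"{c}A" for c in counts]},
                             index=ids)
        asg = ClassAssignment(table, [f"G{k}" for k in range(7)], 0)
        meta = _meta({i: 30.0 for i in ids}, bbd=bbd)
        _, r = bbd_dose_response(asg, meta, "BJ13")
        assert abs(r) < 0.05

    def test_noiseless_perfect_correlation(self):
        counts = np.repeat(np.arange(8), 5)
        ids = [f"a{i}" for i in range(len(counts))]
        bbd = dict(zip(ids, 85.0 - 6.0 * counts))
        table = pd.DataFrame({"hapA_count": counts,
                              "class_label": [f"{c}A" for c in counts]},
                             index=ids)
        asg = ClassAssignment(table, [f"G{k}" for k in range(7)], 0)
        meta = _meta({i: 30.0 for i in ids}, bbd=bbd)
        means, r = bbd_dose_response(asg, meta, "BJ13")
        assert r == pytest.approx(-1.0)
        assert means.is_monotonic_decreasing

    def test_recovers_analytic_r(self, big_panel):
        """Measured r matches beta*SD(dose)/SD(BBD) from the generator."""
        asg, meta = self._panel_assignment(big_panel)
        means, r = bbd_dose_response(asg, meta, "BJ13")
        counts = asg.counts.to_numpy(dtype=float)
        beta, sigma = -6.0, 3.0
        target = beta * counts.std() / np.sqrt(
            beta ** 2 * counts.var() + sigma ** 2)
        assert r == pytest.approx(target, abs=0.05)
        assert means.is_monotonic_decreasing

    def test_too_few_phenotyped(self):
        table = pd.DataFrame({"hapA_count": [1, 2],
                              "class_label": ["1A", "2A"]}, index=["a", "b"])
        asg = ClassAssignment(table, ["G0"], 0)
        meta = _meta({"a": 30.0, "b": 31.0}, bbd={"a": 50.0, "b": 60.0})
        with pytest.raises(DomainError):
            bbd_dose_response(asg, meta, "BJ13")


class TestPlantingZone:
    @pytest.fixture
    def trained_summary(self):
        counts = {f"{k}A": 20 for k in range(8)}
        asg = assignment_from_counts(counts)
        lats = {}
        i = 0
        for k in range(8):
            for _ in range(20):
                lats[f"a{i}"] = 28.0 + 2.5 * k  # 0A ~28N ... 7A ~45.5N
                i += 1
        return class_frequency_table(asg, _meta(lats))

    def test_band_mapping(self, trained_summary):
        pred = predict_planting_zone({"c7": "7A", "c0": "0A", "c4": "4A"},
                                     trained_summary)
        assert pred.loc["c7", "band"].startswith("northern")
        assert pred.loc["c0", "band"].startswith("southern")
        assert pred.loc["c4", "band"].startswith("Huang")

    def test_unseen_class_falls_back(self, trained_summary):
        counts = {f"{k}A": 10 for k in range(3)}   # trained on 0A-2A only
        asg = assignment_from_counts(counts)
        lats = {f"a{i}": 25.0 + i * 0.1 for i in range(30)}
        small = class_frequency_table(asg, _meta(lats))
        pred = predict_planting_zone({"c": "7A"}, small)
        assert bool(pred.loc["c", "nearest_class_fallback"])


def test_latitude_band_composition(big_panel):
    gm, meta, genes, truth = big_panel
    table = pd.DataFrame({"hapA_count": truth.hapA_count,
                          "class_label": [f"{c}A" for c in truth.hapA_count]})
    asg = ClassAssignment(table, list(truth.groups.columns), 0)
    bands = latitude_band_composition(asg, meta)
    assert bands.to_numpy().sum() == len(table)
    # northern band is enriched for high doses relative to the southern band
    north = bands.iloc[-1]
    south = bands.iloc[0]
    hi = [c for c in bands.columns if int(c[:-1]) >= 6]
    lo = [c for c in bands.columns if int(c[:-1]) <= 1]
    assert north[hi].sum() / north.sum() > south[hi].sum() / south.sum()
    assert south[lo].sum() / south.sum() > north[lo].sum() / north.sum()
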