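import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latisoy.io_formats import DomainError
from latisoy.popgen import (Alignment, alignment_from_genotypes, diversity,
                            fu_li_star, ld_r2, pi_total, segregating_sites,
                            shared_unique_mutations, tajimas_d,
                            weir_cockerham_fst)
from .conftest import make_gm


def aln_from_strings(seqs, one="T"):
    return Alignment(np.array([[1 if c == one else 0 for c in s]
                               for s in seqs]))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (enumeration + fresh constant evaluation)
# ---------------------------------------------------------------------------

def oracle_pi_total(m):
    n = m.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    return sum(int((m[i] != m[j]).sum()) for i, j in pairs) / len(pairs)


def oracle_tajima(m):
    n, S = m.shape[0], oracle_S(m)
    if S == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    var = (c1 / a1) * S + (c2 / (a1 ** 2 + a2)) * S * (S - 1)
    return (oracle_pi_total(m) - S / a1) / math.sqrt(var)


def oracle_S(m):
    n = m.shape[0]
    return sum(1 for j in range(m.shape[1]) if 0 < m[:, j].sum() < n)


def oracle_fu_li(m):
    n = m.shape[0]
    eta = oracle_S(m)
    if eta == 0:
        return float("nan"), float("nan")
    eta_s = sum(1 for j in range(m.shape[1])
                if min(m[:, j].sum(), n - m[:, j].sum()) == 1)
    a = sum(1 / i for i in range(1, n))
    b = sum(1 / i ** 2 for i in range(1, n))
    an1 = a + 1 / n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    vD = ((n / (n - 1)) ** 2 * b + a ** 2 * dn
          - 2 * n * a * (a + 1) / (n - 1) ** 2) / (a ** 2 + b)
    uD = n / (n - 1) * (a - n / (n - 1)) - vD
    vF = (dn + 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
          - 2 / (n - 1) * (4 * b - 6 + 8 / n)) / (a ** 2 + b)
    uF = (n / (n - 1) + (n + 1) / (3 * (n - 1)) - 4 / (n * (n - 1))
          + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))) / a - vF
    D = (n / (n - 1) * eta - a * eta_s) / math.sqrt(uD * eta + vD * eta ** 2)
    F = (oracle_pi_total(m) - (n - 1) / n * eta_s) / math.sqrt(
        uF * eta + vF * eta ** 2)
    return D, F


def oracle_wc_fst(geno1, geno2):
    """Textbook Weir-Cockerham (1984) a,b,c for one locus, two pops."""
    def summarize(g):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h
    (n1, p1, h1), (n2, p2, h2) = summarize(geno1), summarize(geno2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar)
                                            - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# Diversity & neutrality
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_four_sequence_worked_example(self):
        aln = aln_from_strings(["AAAA", "AAAT", "AATT", "ATTT"])
        st_ = diversity(aln)
        assert st_.S == 3
        assert st_.theta_seq == pytest.approx(1.6364, abs=1e-4)
        assert st_.pi_total == pytest.approx(10 / 6, abs=1e-9)
        assert st_.pi_site == pytest.approx(0.4167, abs=1e-4)
        assert st_.tajima_d == pytest.approx(0.17, abs=0.005)

    def test_identical_sequences(self):
        aln = aln_from_strings(["AAAA"] * 5)
        st_ = diversity(aln)
        assert st_.S == 0 and st_.theta_site == 0 and st_.pi_site == 0
        assert math.isnan(st_.tajima_d)
        assert not st_.defined

    def test_two_sequences_one_diff(self):
        m = np.zeros((2, 100), dtype=int)
        m[1, 0] = 1
        st_ = diversity(Alignment(m))
        assert st_.theta_site == pytest.approx(0.01)
        assert st_.pi_site == pytest.approx(0.01)

    def test_n_below_two_rejected(self):
        with pytest.raises(DomainError):
            diversity(Alignment(np.zeros((1, 5))))

    def test_singleton_excess_drives_dstar_negative(self):
        m = np.zeros((8, 6), dtype=int)
        for j in range(6):            # every segregating site a singleton
            m[j % 8, j] = 1
        d, f = fu_li_star(Alignment(m))
        assert d < 0

    def test_brute_force_agreement(self):
        """All statistics match enumeration oracles to 1e-9 (n<=6, L<=10)."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 7))
            L = int(rng.integers(1, 11))
            m = (rng.random((n, L)) < rng.uniform(0.1, 0.9)).astype(np.int8)
            if oracle_S(m) == 0:
                continue
            aln = Alignment(m)
            st_ = diversity(aln)
            assert st_.S == oracle_S(m)
            assert st_.pi_total == pytest.approx(oracle_pi_total(m), abs=1e-9)
            assert st_.theta_seq == pytest.approx(
                oracle_S(m) / sum(1 / i for i in range(1, n)), abs=1e-9)
            assert tajimas_d(aln) == pytest.approx(oracle_tajima(m), abs=1e-9)
            oD, oF = oracle_fu_li(m)
            gD, gF = fu_li_star(aln)
            assert gD == pytest.approx(oD, abs=1e-9)
            assert gF == pytest.approx(oF, abs=1e-9)
            checked += 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((6, 8)) < 0.4).astype(np.int8)
        perm = rng.permutation(6)
        a, b = diversity(Alignment(m)), diversity(Alignment(m[perm]))
        assert a.theta_site == b.theta_site and a.pi_site == b.pi_site

    def test_tajima_sign_matches_pi_minus_theta(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = (rng.random((8, 10)) < 0.3).astype(np.int8)
            aln = Alignment(m)
            d = tajimas_d(aln)
            if math.isnan(d):
                continue
            a1 = sum(1 / i for i in range(1, 8))
            diff = pi_total(aln) - segregating_sites(aln) / a1
            assert math.copysign(1, d) == math.copysign(1, diff) or diff == 0


class TestSharedUnique:
    def test_classification(self):
        a = aln_from_strings(["TAAA", "AAAA", "AAAA", "ATAA"])
        b = aln_from_strings(["TAAA", "AAAA", "AATA", "AAAA"])
        shared, pa, pb = shared_unique_mutations(a, b)
        assert (shared, pa, pb) == (1, 1, 1)

    def test_disjoint_sets(self):
        m_a = np.zeros((4, 5), dtype=int)
        m_a[0, [0, 1, 2]] = 1
        m_b = np.zeros((4, 5), dtype=int)
        m_b[0, [3, 4]] = 1
        assert shared_unique_mutations(Alignment(m_a),
                                       Alignment(m_b)) == (0, 3, 2)

    def test_coordinate_mismatch(self):
        with pytest.raises(DomainError):
            shared_unique_mutations(Alignment(np.zeros((2, 3))),
                                    Alignment(np.zeros((2, 4))))


class TestFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[0]] * 5 + [[2]] * 5)
        res = weir_cockerham_fst(gm, ["a"] * 5 + ["b"] * 5, n_perm=19, seed=0)
        assert res.fst == pytest.approx(1.0)

    def test_toy_counts_match_component_oracle(self):
        g1, g2 = [0, 0, 0, 1, 1], [1, 1, 2, 2, 2]
        gm = make_gm(np.array(g1 + g2).reshape(-1, 1))
        res = weir_cockerham_fst(gm, ["a"] * 5 + ["b"] * 5, n_perm=19, seed=0)
        a, b, c = oracle_wc_fst(g1, g2)
        assert res.fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_multilocus_ratio_of_sums(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0, 1, 2], size=(12, 6)).astype(np.int8)
        labels = ["a"] * 6 + ["b"] * 6
        res = weir_cockerham_fst(make_gm(d), labels, n_perm=9, seed=0)
        num = den = 0.0
        for j in range(6):
            a, b, c = oracle_wc_fst(d[:6, j], d[6:, j])
            num += a
            den += a + b + c
        assert res.fst == pytest.approx(num / den, abs=1e-12)

    def test_equal_frequencies_near_zero_unclamped(self):
        d = np.tile([0, 2], 30).reshape(-1, 1).astype(np.int8)
        res = weir_cockerham_fst(make_gm(d), ["a"] * 30 + ["b"] * 30,
                                 n_perm=9, seed=0)
        assert res.fst < 0.05  # may legitimately be slightly negative

    def test_small_population_rejected(self):
        gm = make_gm([[0], [2], [2]])
        with pytest.raises(DomainError):
            weir_cockerham_fst(gm, ["a", "b", "b"], n_perm=9, seed=0)


class TestLD:
    def test_duplicated_column_r2_one(self):
        d = np.array([[0, 0], [2, 2], [0, 0], [2, 2], [1, 1]], dtype=np.int8)
        res = ld_r2(make_gm(d))
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_window_excludes_distant_pair(self):
        d = np.array([[0, 0], [2, 2], [0, 2], [2, 0]], dtype=np.int8)
        gm = make_gm(d, positions=[0, 1_200_000])
        res = ld_r2(gm, window_kb=1000)
        assert len(res.pairs) == 0

    def test_independent_snps_low_mean_r2(self):
        rng = np.random.default_rng(5)
        d = (2 * (rng.random((1000, 30)) < 0.5)).astype(np.int8)
        res = ld_r2(make_gm(d))
        assert res.pairs["r2"].mean() < 0.01

    def test_monomorphic_pair_skipped(self):
        d = np.array([[0, 0], [0, 2], [0, 0], [0, 2]], dtype=np.int8)
        res = ld_r2(make_gm(d))
        assert len(res.pairs) == 0 and res.n_skipped_monomorphic == 1


def test_alignment_from_genotypes_major_allele_het():
    # het at an alt-major site resolves to alt; missing site dropped
    d = np.array([[2, -1], [2, 0], [1, 0], [0, 2]], dtype=np.int8)
    aln, dropped, hets = alignment_from_genotypes(make_gm(d))
    assert dropped == 1 and hets == 1
    np.testing.assert_array_equal(aln.matrix[:, 0], [1, 1, 1, 0])
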