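"""Nucleotide diversity, ROD and Weir-Cockerham FST against independent
oracles (pairwise Hamming distances; rational-arithmetic WC84)."""
from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sweepscan.data import Window, make_windows
from sweepscan.diversity import (rod, wc_fst_components, wc_fst_site,
                                 window_pi, windowed_fst)

from conftest import make_gset, make_hapset


def pairwise_pi_oracle(hap_matrix: np.ndarray, length: int) -> float:
    """Mean per-bp Hamming distance over all haplotype pairs."""
    n = hap_matrix.shape[1]
    pairs = list(combinations(range(n), 2))
    total = sum(int(np.sum(hap_matrix[:, i] != hap_matrix[:, j]))
                for i, j in pairs)
    return total / len(pairs) / length


class TestWindowPi:
    def test_hand_example_two_sites(self):
        # 4 haplotypes, alt counts 1 and 2 in a 1000-bp window
        h = np.array([[1, 0, 0, 0], [1, 1, 0, 0]], dtype=np.uint8)
        g = make_hapset(h, positions=[10, 20]).to_genotype_set()
        track = window_pi(g, "P", [Window("chr1", 0, 1000)])
        assert track.frame["pi"].iloc[0] == pytest.approx((0.5 + 2 / 3) / 1000)
        assert track.frame["pi"].iloc[0] == pytest.approx(
            pairwise_pi_oracle(h, 1000))

    def test_monomorphic_window_zero(self):
        g = make_gset(np.zeros((3, 4), dtype=np.int8))
        track = window_pi(g, "P", [Window("chr1", 0, 1000)])
        assert track.frame["pi"].iloc[0] == 0.0

    def test_single_het_site_term(self):
        # p = 0.5 with n = 4 haplotypes: per-site term (4/3) * 0.5
        h = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        g = make_hapset(h, positions=[0]).to_genotype_set()
        track = window_pi(g, "P", [Window("chr1", 0, 1)])
        assert track.frame["pi"].iloc[0] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_pairwise_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n_hap = int(rng.integers(2, 11)) * 2  # even: two haps per sample
        n_sites = int(rng.integers(1, 21))
        h = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.uint8)
        length = int(rng.integers(n_sites * 10, 5000))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        g = make_hapset(h, positions=pos).to_genotype_set()
        track = window_pi(g, "P", [Window("chr1", 0, length)])
        assert track.frame["pi"].iloc[0] == pytest.approx(
            pairwise_pi_oracle(h, length), rel=1e-12)

    def test_sites_with_low_call_count_skipped(self):
        d = np.array([[1, -1], [1, 0]], dtype=np.int8)  # site 0: 1 sample
        g = make_gset(d)
        track = window_pi(g, "P", [Window("chr1", 0, 1000)])
        assert track.frame["n_skipped"].iloc[0] == 0  # 2 haplotypes still >= 2
        d2 = np.array([[-1, -1]], dtype=np.int8)
        g2 = make_gset(d2)
        track2 = window_pi(g2, "P", [Window("chr1", 0, 1000)])
        assert track2.frame["n_skipped"].iloc[0] == 1


def _track(values, n_snps=20):
    rows = [{"chrom": "chr1", "start": i * 1000, "end": (i + 1) * 1000,
             "pi": v, "n_snps": n_snps, "n_skipped": 0}
            for i, v in enumerate(values)]
    from sweepscan.diversity import DiversityTrack
    return DiversityTrack(pd.DataFrame(rows), "P")


class TestRod:
    def test_equal_diversity_gives_zero(self):
        out = rod(_track([1e-3]), _track([1e-3]))
        assert out["rod"].iloc[0] == 0.0

    def test_test_pi_zero_gives_one(self):
        out = rod(_track([1e-3]), _track([0.0]))
        assert out["rod"].iloc[0] == 1.0

    def test_ref_pi_zero_flagged_invalid(self):
        out = rod(_track([0.0]), _track([1e-3]))
        assert not out["valid"].iloc[0]
        assert np.isnan(out["rod"].iloc[0])

    def test_low_snp_windows_excluded(self):
        out = rod(_track([1e-3], n_snps=3), _track([1e-3], n_snps=3),
                  min_snps=10)
        assert not out["valid"].iloc[0]

    def test_mismatched_windows_error(self):
        t2 = _track([1e-3, 1e-3])
        with pytest.raises(ValueError):
            rod(_track([1e-3]), t2)


def wc84_fraction_oracle(n1, a1, het1, n2, a2, het2):
    """Literal transcription of the two-population WC84 variance
    components with exact rational arithmetic.  Inputs are diploid counts,
    alt-allele counts and heterozygote counts per population."""
    r = 2
    n = [Fraction(n1), Fraction(n2)]
    p = [Fraction(a1, 2 * n1), Fraction(a2, 2 * n2)]
    h = [Fraction(het1, n1), Fraction(het2, n2)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - Fraction(1, 1) / (nbar - 1)
                       * (pbar * (1 - pbar) - Fraction(r - 1, r) * s2
                          - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - Fraction(r - 1, r) * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    tot = a + b + c
    theta = a / tot if tot != 0 else None
    return a, b, c, theta


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        n = np.array([[10, 10]])
        p = np.array([[0.0, 1.0]])
        h = np.array([[0.0, 0.0]])
        a, b, c, theta, defined = wc_fst_components(n, p, h)
        assert b[0] == pytest.approx(0.0)
        assert c[0] == 0.0
        assert a[0] > 0
        assert theta[0] == pytest.approx(1.0)

    def test_both_monomorphic_identical_undefined(self):
        n = np.array([[10, 10]])
        p = np.array([[0.0, 0.0]])
        h = np.array([[0.0, 0.0]])
        *_, theta, defined = wc_fst_components(n, p, h)
        assert not defined[0]

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        n = rng.integers(2, 20, size=(50, 2)).astype(float)
        p = rng.random((50, 2))
        h = np.minimum(rng.random((50, 2)), 2 * p * (1 - p) + 0.2)
        a1, b1, c1, t1, d1 = wc_fst_components(n, p, h)
        a2, b2, c2, t2, d2 = wc_fst_components(n[:, ::-1], p[:, ::-1], h[:, ::-1])
        np.testing.assert_allclose(a1, a2)
        np.testing.assert_allclose(t1[d1], t2[d2])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rational_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n1, n2 = rng.integers(2, 16, size=2)
        # genotype counts: (hom_ref, het, hom_alt) per population
        g1 = rng.multinomial(n1, [1 / 3] * 3)
        g2 = rng.multinomial(n2, [1 / 3] * 3)
        a1 = g1[1] + 2 * g1[2]
        a2 = g2[1] + 2 * g2[2]
        oa, ob, oc, otheta = wc84_fraction_oracle(n1, a1, g1[1], n2, a2, g2[1])
        n = np.array([[n1, n2]], dtype=float)
        p = np.array([[a1 / (2 * n1), a2 / (2 * n2)]])
        h = np.array([[g1[1] / n1, g2[1] / n2]])
        a, b, c, theta, defined = wc_fst_components(n, p, h)
        assert a[0] == pytest.approx(float(oa), abs=1e-12)
        assert b[0] == pytest.approx(float(ob), abs=1e-12)
        assert c[0] == pytest.approx(float(oc), abs=1e-12)
        if otheta is None:
            assert not defined[0]
        else:
            assert theta[0] == pytest.approx(float(otheta), abs=1e-12)

    def test_wc_fst_site_from_genotypes(self):
        # pop A: all het; pop B: fixed ref -> components defined, theta < 1
        d = np.array([[1, 1, 0, 0]], dtype=np.int8)
        g = make_gset(d, pops=["A", "A", "B", "B"])
        comp = wc_fst_site(g, "A", "B")
        oa, ob, oc, otheta = wc84_fraction_oracle(2, 2, 2, 2, 0, 0)
        assert comp["a"].iloc[0] == pytest.approx(float(oa), abs=1e-12)
        assert comp["theta"].iloc[0] == pytest.approx(float(otheta), abs=1e-12)


class TestWindowedFst:
    def _frame(self, comps):
        return pd.DataFrame([
            {"chrom": "chr1", "pos": 10 * (i + 1), "a": a, "b": b, "c": c,
             "theta": (a / (a + b + c)) if (a + b + c) else np.nan,
             "defined": bool(a + b + c)}
            for i, (a, b, c) in enumerate(comps)])

    def test_single_site_window_equals_theta(self):
        f = self._frame([(1.0, 1.0, 0.0)])
        out = windowed_fst(f, [Window("chr1", 0, 100)], min_snps=1)
        assert out["fst"].iloc[0] == pytest.approx(0.5)

    def test_ratio_of_averages_not_mean_of_ratios(self):
        # sites (1,0,0) and (0,3,1): ratio = 1/5 = 0.2, mean of thetas = 0.5
        f = self._frame([(1.0, 0.0, 0.0), (0.0, 3.0, 1.0)])
        out = windowed_fst(f, [Window("chr1", 0, 100)], min_snps=1)
        assert out["fst"].iloc[0] == pytest.approx(0.2)
        assert f["theta"].mean() == pytest.approx(0.5)

    def test_all_undefined_window_flagged(self):
        f = self._frame([(0.0, 0.0, 0.0)])
        out = windowed_fst(f, [Window("chr1", 0, 100)], min_snps=1)
        assert not out["valid"].iloc[0]
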