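"""EHH partition refinement, iHH integration, iHS and XP-EHH scans."""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.data import GeneticMap
from sweepscan.ehh import EhhProfile, ehh, ihh, ihs_scan, xpehh_scan

from conftest import make_hapset


def ehh_substring_oracle(H, core, carriers, x, direction):
    """Group carrier haplotypes by their exact allele string over
    [core..x] and count identical pairs."""
    lo, hi = (core, x) if direction == "right" else (x, core)
    strings = {}
    for c in carriers:
        key = tuple(H[lo:hi + 1, c])
        strings.setdefault(key, 0)
        strings[key] += 1
    n = len(carriers)
    pairs = sum(k * (k - 1) // 2 for k in strings.values())
    return pairs / (n * (n - 1) // 2)


class TestEhh:
    def test_core_is_one(self):
        H = np.array([[1, 1, 0, 0], [0, 1, 0, 1]], dtype=np.uint8)
        hs = make_hapset(H)
        prof = ehh(hs, 0, np.arange(4), "right")
        assert prof.ehh[0] == 1.0

    def test_identical_carriers_stay_one(self):
        H = np.tile(np.array([[1], [0], [1]], dtype=np.uint8), (1, 4))
        hs = make_hapset(H)
        prof = ehh(hs, 0, np.arange(4), "right", stop_ehh=-1.0)
        assert np.all(prof.ehh == 1.0)
        assert prof.reached_end  # never decayed

    def test_two_two_split_gives_third(self):
        H = np.array([[1, 1, 1, 1], [0, 0, 1, 1]], dtype=np.uint8)
        hs = make_hapset(H)
        prof = ehh(hs, 0, np.arange(4), "right")
        assert prof.ehh[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_invalid(self):
        H = np.zeros((2, 4), dtype=np.uint8)
        hs = make_hapset(H)
        assert not ehh(hs, 0, np.array([0]), "right").valid

    def test_profiles_non_increasing(self):
        rng = np.random.default_rng(8)
        H = rng.integers(0, 2, size=(15, 12)).astype(np.uint8)
        hs = make_hapset(H)
        for direction in ("left", "right"):
            prof = ehh(hs, 7, np.arange(12), direction, stop_ehh=-1.0)
            assert np.all(np.diff(prof.ehh) <= 1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_substring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_hap = int(rng.integers(1, 7)) * 2
        n_sites = int(rng.integers(2, 16))
        H = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.uint8)
        hs = make_hapset(H)
        core = int(rng.integers(0, n_sites))
        carriers = np.arange(n_hap)
        for direction in ("left", "right"):
            prof = ehh(hs, core, carriers, direction, stop_ehh=-1.0)
            step = 1 if direction == "right" else -1
            for k in range(1, len(prof.positions)):
                x = core + step * k
                assert prof.ehh[k] == pytest.approx(
                    ehh_substring_oracle(H, core, carriers, x, direction))


class TestIhh:
    def test_hand_trapezoids(self):
        prof = EhhProfile(positions=np.array([0, 100, 200]),
                          cm=np.array([0.0, 0.01, 0.02]),
                          ehh=np.array([1.0, 0.5, 0.04]))
        val, ok = ihh(prof, ehh_cutoff=0.05)
        assert ok
        assert val == pytest.approx(0.0075 + 0.0027)

    def test_never_decaying_profile_invalid(self):
        prof = EhhProfile(positions=np.array([0, 100]),
                          cm=np.array([0.0, 0.01]),
                          ehh=np.array([1.0, 1.0]), reached_end=True)
        _, ok = ihh(prof)
        assert not ok

    def test_single_point_profile_zero(self):
        prof = EhhProfile(positions=np.array([0]), cm=np.array([0.0]),
                          ehh=np.array([1.0]))
        val, ok = ihh(prof)
        assert val == 0.0

    def test_insertion_invariance_at_same_genetic_position(self):
        # a non-differing site co-located in genetic distance adds a
        # zero-width trapezoid; a non-differing site strictly between two
        # sites can only increase the integral (trapezoid geometry)
        H = np.array([[1, 1, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.uint8)
        hs = make_hapset(H, positions=[100, 200, 300])
        base, _ = ihh(ehh(hs, 0, np.arange(4), "right", stop_ehh=-1.0), 0.0)
        H2 = np.insert(H, 1, np.ones(4, dtype=np.uint8), axis=0)
        hs2 = make_hapset(H2, positions=[100, 101, 200, 300])
        with_site, _ = ihh(ehh(hs2, 0, np.arange(4), "right", stop_ehh=-1.0), 0.0)
        assert with_site >= base - 1e-15
        # co-located in cM: custom flat map makes the insertion free
        flat = GeneticMap({"chr1": (np.array([100, 101, 200, 300]),
                                    np.array([0.0, 0.0, 1.0, 2.0]))})
        a, _ = ihh(ehh(hs2, 0, np.arange(4), "right", gmap=flat, stop_ehh=-1.0), 0.0)
        ref_map = GeneticMap({"chr1": (np.array([100, 200, 300]),
                                       np.array([0.0, 1.0, 2.0]))})
        b, _ = ihh(ehh(hs, 0, np.arange(4), "right", gmap=ref_map, stop_ehh=-1.0), 0.0)
        assert a == pytest.approx(b)


def _mirror_hapset():
    """Derived and ancestral carrier groups with mirror-image structure
    around the core, so iHH_ancestral = iHH_derived exactly."""
    rng = np.random.default_rng(4)
    block = rng.integers(0, 2, size=(12, 4)).astype(np.uint8)
    n_sites = 25
    core = 12
    H = np.zeros((n_sites, 8), dtype=np.uint8)
    H[core, :4] = 1                      # derived carriers: haplotypes 0-3
    H[:core, :4] = block
    H[core + 1:, :4] = block
    H[:core, 4:] = block                 # ancestral carriers mirror them
    H[core + 1:, 4:] = block
    return make_hapset(H)


class TestIhsScan:
    def test_symmetric_data_unstandardized_zero(self):
        hs = _mirror_hapset()
        track = ihs_scan(hs, "P", maf_min=0.0, n_bins=1, min_bin_count=1)
        core_row = track[track["pos"] == hs.positions[12]]
        assert len(core_row) == 1
        assert core_row["ihh_a"].iloc[0] == pytest.approx(core_row["ihh_d"].iloc[0])
        assert core_row["unstd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_maf_filter_applies_to_cores(self):
        rng = np.random.default_rng(6)
        H = rng.integers(0, 2, size=(30, 20)).astype(np.uint8)
        H[5] = 0
        H[5, 0] = 1  # frequency 0.05 < default maf_min? 1/20 = 0.05 -> kept
        hs = make_hapset(H)
        track = ihs_scan(hs, "P", maf_min=0.2)
        freqs = track["freq"].to_numpy()
        assert np.all((freqs >= 0.2) & (freqs <= 0.8))

    def test_standardized_bins_are_centered(self):
        rng = np.random.default_rng(12)
        H = rng.integers(0, 2, size=(400, 24)).astype(np.uint8)
        hs = make_hapset(H, positions=np.arange(400) * 37 + 11)
        track = ihs_scan(hs, "P", n_bins=5, min_bin_count=10)
        ok = track[track["valid"]]
        if len(ok) >= 20:
            for _, grp in ok.groupby("bin"):
                if len(grp) >= 2:
                    assert abs(grp["std"].mean()) < 1e-9
                    assert abs(grp["std"].std(ddof=1) - 1) < 1e-9


class TestXpehhScan:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(13)
        block = rng.integers(0, 2, size=(60, 8)).astype(np.uint8)
        H = np.hstack([block, block])  # pop B haplotypes == pop A
        hs = make_hapset(H, pops=["A"] * 4 + ["B"] * 4)
        track = xpehh_scan(hs, "A", "B")
        assert np.allclose(track["unstd"].dropna(), 0.0, atol=1e-12)

    def test_population_swap_negates_exactly(self):
        rng = np.random.default_rng(14)
        H = rng.integers(0, 2, size=(80, 16)).astype(np.uint8)
        hs = make_hapset(H, pops=["A"] * 4 + ["B"] * 4)
        t1 = xpehh_scan(hs, "A", "B")
        t2 = xpehh_scan(hs, "B", "A")
        u1 = t1["unstd"].to_numpy()
        u2 = t2["unstd"].to_numpy()
        mask = np.isfinite(u1) & np.isfinite(u2)
        assert mask.any()
        np.testing.assert_array_equal(u1[mask], -u2[mask])

    def test_missing_population_errors(self):
        H = np.zeros((3, 4), dtype=np.uint8)
        hs = make_hapset(H)
        with pytest.raises(KeyError):
            xpehh_scan(hs, "P", "nope")
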