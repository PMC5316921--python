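"""Extended haplotype homozygosity (EHH), its genetic-distance integral
(iHH), and the standardized iHS and XP-EHH scan statistics.

EHH at extension x is the probability that two randomly drawn carrier
haplotypes are identical over every site from the core out to x:
sum_g C(n_g, 2) / C(n, 2) over the groups g of haplotypes sharing the same
allele string.  It is computed by partition refinement, one site at a time,
moving outwards from the core.

iHS follows the classic recipe: ln(iHH_ancestral / iHH_derived) per core
SNP, standardized to zero mean / unit variance within derived-allele-
frequency bins.  XP-EHH integrates EHH over *all* haplotypes of each
population and standardizes ln(iHH_A / iHH_B) genome-wide, so swapping the
populations negates every score exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneticMap, HaplotypeSet


@dataclass
class EhhProfile:
    """EHH decay from a core site in one direction.

    ``reached_end`` is True when the profile stopped at the chromosome end
    (or the maximum extension) instead of decaying through the stop
    threshold; iHH built from such a profile is flagged invalid.
    """

    positions: np.ndarray          # bp, profile order: core outwards
    cm: np.ndarray                 # genetic positions, same order
    ehh: np.ndarray
    valid: bool = True
    reached_end: bool = False


def ehh(
    hapset: HaplotypeSet,
    core_index: int,
    carriers: np.ndarray,
    direction: str,
    gmap: GeneticMap | None = None,
    max_extension_bp: int = 1_000_000,
    stop_ehh: float = 0.0,
) -> EhhProfile:
    """EHH profile from ``core_index`` over the given carrier haplotypes.

    ``carriers`` are haplotype column indices (the carriers of one core
    allele for iHS, or every haplotype of one population for XP-EHH);
    ``direction`` is "left" or "right".  The profile stops once EHH <=
    ``stop_ehh`` (that point included), at ``max_extension_bp`` from the
    core, or at the chromosome end — whichever comes first.
    """
    if gmap is None:
        gmap = GeneticMap.uniform()
    carriers = np.asarray(carriers, dtype=np.intp)
    n = carriers.size
    chrom = hapset.sites["chrom"].iloc[core_index]
    pos_all = hapset.positions
    core_pos = int(pos_all[core_index])
    if n < 2:
        return EhhProfile(np.array([core_pos]), gmap.cm(chrom, [core_pos]),
                          np.array([1.0]), valid=False)

    chrom_arr = hapset.sites["chrom"].to_numpy()
    if direction == "right":
        step = 1
        limit = len(pos_all)
    elif direction == "left":
        step = -1
        limit = -1
    else:
        raise ValueError("direction must be 'left' or 'right'")

    H = hapset.haplotypes
    denom = n * (n - 1) / 2.0
    # haplotypes must be identical over [core..x]: the core site's alleles
    # seed the partition (EHH at the core itself is 1 by convention)
    gid = H[core_index, carriers].astype(np.int64)
    positions = [core_pos]
    values = [1.0]
    reached_end = True
    i = core_index + step
    while i != limit and chrom_arr[i] == chrom:
        if abs(int(pos_all[i]) - core_pos) > max_extension_bp:
            break
        alleles = H[i, carriers]
        _, gid = np.unique(gid * 2 + alleles, return_inverse=True)
        counts = np.bincount(gid)
        e = float((counts * (counts - 1)).sum()) / 2.0 / denom
        positions.append(int(pos_all[i]))
        values.append(e)
        if e <= stop_ehh:
            reached_end = False
            break
        i += step
    positions = np.array(positions)
    return EhhProfile(positions, np.asarray(gmap.cm(chrom, positions)),
                      np.array(values), valid=True, reached_end=reached_end)


def ihh(profile: EhhProfile, ehh_cutoff: float = 0.05) -> tuple[float, bool]:
    """Trapezoidal integral of an EHH profile over genetic distance (cM).

    Integration stops at the first point where EHH < ``ehh_cutoff`` (that
    final trapezoid included).  Returns (value, valid): invalid when the
    profile itself is invalid or EHH never fell below the cutoff before the
    profile ended at a boundary.
    """
    if not profile.valid:
        return 0.0, False
    total = 0.0
    fell = False
    for k in range(1, len(profile.ehh)):
        d = abs(profile.cm[k] - profile.cm[k - 1])
        total += 0.5 * (profile.ehh[k] + profile.ehh[k - 1]) * d
        if profile.ehh[k] < ehh_cutoff:
            fell = True
            break
    if not fell and profile.reached_end:
        return total, False
    return total, True


class _ScanArrays:
    """Pre-extracted numpy views used by the scan loops (the public
    :func:`ehh` rebuilds them per call, which is fine for single profiles
    but too slow for genome scans)."""

    def __init__(self, hapset: HaplotypeSet, gmap: GeneticMap):
        self.H = hapset.haplotypes
        self.pos = hapset.positions
        chrom = hapset.sites["chrom"].to_numpy()
        n = len(chrom)
        starts = np.concatenate([[0], np.flatnonzero(chrom[1:] != chrom[:-1]) + 1, [n]])
        self.lo = np.empty(n, dtype=np.intp)
        self.hi = np.empty(n, dtype=np.intp)
        self.cm = np.empty(n, dtype=float)
        for a, b in zip(starts[:-1], starts[1:]):
            self.lo[a:b] = a
            self.hi[a:b] = b
            self.cm[a:b] = gmap.cm(chrom[a], self.pos[a:b])


def _one_direction_py(H, carriers, pos, cm, core, step, limit, cutoff, max_ext):
    n = carriers.size
    denom = n * (n - 1) / 2.0
    core_pos = int(pos[core])
    gid = H[core, carriers].astype(np.int64)  # core alleles seed the partition
    total, e_prev, cm_prev = 0.0, 1.0, cm[core]
    i = core + step
    while i != limit:
        if abs(int(pos[i]) - core_pos) > max_ext:
            break
        gid = gid * 2 + H[i, carriers]
        _, gid, counts = np.unique(gid, return_inverse=True, return_counts=True)
        e = float((counts * (counts - 1)).sum()) / 2.0 / denom
        total += 0.5 * (e + e_prev) * abs(cm[i] - cm_prev)
        if e <= cutoff:
            return total, True
        e_prev, cm_prev = e, cm[i]
        i += step
    return total, False


try:  # compiled kernel; the numpy path above is the fallback
    from numba import njit

    @njit(cache=False)
    def _one_direction_nb(H, carriers, pos, cm, core, step, limit, cutoff, max_ext):  # pragma: no cover
        n = carriers.shape[0]
        denom = n * (n - 1) * 0.5
        core_pos = pos[core]
        gid = np.empty(n, dtype=np.int64)
        for j in range(n):  # core alleles seed the partition
            gid[j] = H[core, carriers[j]]
        keys = np.empty(n, dtype=np.int64)
        total = 0.0
        e_prev = 1.0
        cm_prev = cm[core]
        i = core + step
        while i != limit:
            d = pos[i] - core_pos
            if d < 0:
                d = -d
            if d > max_ext:
                break
            for j in range(n):
                keys[j] = gid[j] * 2 + H[i, carriers[j]]
            order = np.argsort(keys)
            pairs = 0.0
            label = -1
            prev_key = np.int64(-1)
            run = 0
            for k in range(n):
                j = order[k]
                if keys[j] != prev_key:
                    if run > 1:
                        pairs += run * (run - 1) * 0.5
                    label += 1
                    run = 1
                    prev_key = keys[j]
                else:
                    run += 1
                gid[j] = label
            if run > 1:
                pairs += run * (run - 1) * 0.5
            e = pairs / denom
            dcm = cm[i] - cm_prev
            if dcm < 0:
                dcm = -dcm
            total += 0.5 * (e + e_prev) * dcm
            if e <= cutoff:
                return total, True
            e_prev = e
            cm_prev = cm[i]
            i += step
        return total, False

    _one_direction = _one_direction_nb
except ImportError:  # pragma: no cover
    _one_direction = _one_direction_py


def _ihh_fast(arr: _ScanArrays, core: int, carriers: np.ndarray,
              ehh_cutoff: float, max_extension_bp: int) -> tuple[float, bool]:
    """iHH summed over both directions, integrating trapezoids on the fly.

    Semantics match ehh() + ihh(): integration stops at the first site
    where EHH <= cutoff (that trapezoid included); hitting the chromosome
    end or the extension cap first makes the core invalid.
    """
    n = carriers.size
    if n < 2:
        return 0.0, False
    total = 0.0
    for step, limit in ((1, int(arr.hi[core])), (-1, int(arr.lo[core]) - 1)):
        v, fell = _one_direction(arr.H, carriers, arr.pos, arr.cm, core,
                                 step, limit, ehh_cutoff, max_extension_bp)
        total += v
        if not fell:
            return total, False
    return total, True


def _ihh_both(hapset, core, carriers, gmap, ehh_cutoff, max_extension_bp):
    total, ok = 0.0, True
    for direction in ("left", "right"):
        prof = ehh(hapset, core, carriers, direction, gmap=gmap,
                   max_extension_bp=max_extension_bp, stop_ehh=ehh_cutoff)
        v, valid = ihh(prof, ehh_cutoff)
        total += v
        ok &= valid
    return total, ok


# ---------------------------------------------------------------------------
# standardization helpers
# ---------------------------------------------------------------------------

def _merge_small_bins(bin_idx: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Relabel frequency bins so every occupied label has >= min_count
    members, merging undersized bins into their right neighbour (the last
    bin merges leftwards).  Returns the merged label per score."""
    labels = bin_idx.copy()
    order = sorted(set(labels.tolist()))
    counts = {b: int((labels == b).sum()) for b in order}
    groups: list[list[int]] = []
    carry: list[int] = []
    for b in order:
        carry.append(b)
        if sum(counts[g] for g in carry) >= min_count:
            groups.append(carry)
            carry = []
    if carry:  # trailing undersized group merges leftwards
        if groups:
            groups[-1].extend(carry)
        else:
            groups.append(carry)
    merged = {g: grp[-1] for grp in groups for g in grp}
    return np.array([merged[b] for b in labels])


def _standardize(scores: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-sd within each bin label (sample sd, ddof=1)."""
    out = np.full(scores.shape, np.nan)
    for b in np.unique(bins):
        sel = bins == b
        vals = scores[sel]
        if vals.size < 2:
            continue
        sd = vals.std(ddof=1)
        if sd > 0:
            out[sel] = (vals - vals.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def ihs_scan(
    hapset: HaplotypeSet,
    population: str,
    ancestral_policy: str = "ref_is_ancestral",
    ancestral_alleles: dict | None = None,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    max_extension_bp: int = 1_000_000,
    gmap: GeneticMap | None = None,
    n_bins: int = 50,
    min_bin_count: int = 20,
) -> pd.DataFrame:
    """iHS per core SNP of one population.

    ``ancestral_policy`` is "ref_is_ancestral" (default) or
    "annotation_file", in which case ``ancestral_alleles`` maps (chrom, pos)
    to the ancestral base; cores whose ancestral base matches neither allele
    are skipped.  Scores are ln(iHH_ancestral / iHH_derived), standardized
    within ``n_bins`` equal-width derived-allele-frequency bins (bins with
    fewer than ``min_bin_count`` scores merged with neighbours).
    """
    if ancestral_policy not in ("ref_is_ancestral", "annotation_file"):
        raise ValueError(f"unknown ancestral_policy {ancestral_policy!r}")
    if ancestral_policy == "annotation_file" and ancestral_alleles is None:
        raise ValueError("annotation_file policy needs ancestral_alleles")
    if gmap is None:
        gmap = GeneticMap.uniform()
    hap_idx = hapset.hap_indices(population)
    H = hapset.haplotypes
    arr = _ScanArrays(hapset, gmap)
    chrom_arr = hapset.sites["chrom"].to_numpy()
    pos_arr = hapset.positions
    ref_arr = hapset.sites["ref"].to_numpy()
    alt_arr = hapset.sites["alt"].to_numpy()

    rows = []
    for core in range(len(pos_arr)):
        derived_code = 1
        if ancestral_policy == "annotation_file":
            anc = ancestral_alleles.get((chrom_arr[core], int(pos_arr[core])))
            if anc == alt_arr[core]:
                derived_code = 0
            elif anc != ref_arr[core]:
                continue
        alleles = H[core, hap_idx]
        p_derived = float((alleles == derived_code).mean())
        if min(p_derived, 1 - p_derived) < maf_min:
            continue
        der = hap_idx[alleles == derived_code]
        anc_c = hap_idx[alleles != derived_code]
        ihh_d, ok_d = _ihh_fast(arr, core, der, ehh_cutoff, max_extension_bp)
        ihh_a, ok_a = _ihh_fast(arr, core, anc_c, ehh_cutoff, max_extension_bp)
        valid = ok_d and ok_a and ihh_d > 0 and ihh_a > 0
        unstd = np.log(ihh_a) - np.log(ihh_d) if valid else np.nan
        rows.append({
            "chrom": chrom_arr[core], "pos": int(pos_arr[core]),
            "freq": p_derived, "ihh_a": ihh_a, "ihh_d": ihh_d,
            "unstd": unstd, "valid": valid,
        })
    track = pd.DataFrame(rows, columns=["chrom", "pos", "freq", "ihh_a",
                                        "ihh_d", "unstd", "valid"])
    track["std"] = np.nan
    ok = track["valid"].to_numpy(dtype=bool) if len(track) else np.array([], bool)
    if ok.any():
        freqs = track.loc[ok, "freq"].to_numpy()
        bin_idx = np.minimum((freqs * n_bins).astype(int), n_bins - 1)
        bins = _merge_small_bins(bin_idx, n_bins, min_bin_count)
        track.loc[ok, "std"] = _standardize(track.loc[ok, "unstd"].to_numpy(), bins)
        track["bin"] = -1
        track.loc[ok, "bin"] = bins
    else:
        track["bin"] = -1
    track.loc[track["std"].isna(), "valid"] = False
    return track


def xpehh_scan(
    hapset: HaplotypeSet,
    pop_a: str,
    pop_b: str,
    ehh_cutoff: float = 0.05,
    maf_min: float = 0.05,
    max_extension_bp: int = 1_000_000,
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """XP-EHH per core SNP: genome-wide standardized ln(iHH_A / iHH_B).

    EHH is computed over every haplotype of each population (no allele
    partition); ``maf_min`` filters cores on pooled (both-population) minor
    allele frequency.
    """
    if gmap is None:
        gmap = GeneticMap.uniform()
    idx_a = hapset.hap_indices(pop_a)
    idx_b = hapset.hap_indices(pop_b)
    both = np.concatenate([idx_a, idx_b])
    H = hapset.haplotypes
    arr = _ScanArrays(hapset, gmap)
    chrom_arr = hapset.sites["chrom"].to_numpy()
    pos_arr = hapset.positions

    rows = []
    for core in range(len(pos_arr)):
        p = float(H[core, both].mean())
        if min(p, 1 - p) < maf_min:
            continue
        ihh_1, ok_1 = _ihh_fast(arr, core, idx_a, ehh_cutoff, max_extension_bp)
        ihh_2, ok_2 = _ihh_fast(arr, core, idx_b, ehh_cutoff, max_extension_bp)
        valid = ok_1 and ok_2 and ihh_1 > 0 and ihh_2 > 0
        # log difference (not log of the ratio) so a population swap
        # negates every score bit-exactly
        unstd = np.log(ihh_1) - np.log(ihh_2) if valid else np.nan
        rows.append({
            "chrom": chrom_arr[core], "pos": int(pos_arr[core]),
            "ihh_pop1": ihh_1, "ihh_pop2": ihh_2, "unstd": unstd, "valid": valid,
        })
    track = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_pop1", "ihh_pop2",
                                        "unstd", "valid"])
    track["std"] = np.nan
    ok = track["valid"].to_numpy(dtype=bool) if len(track) else np.array([], bool)
    if ok.sum() >= 2:
        vals = track.loc[ok, "unstd"].to_numpy()
        sd = vals.std(ddof=1)
        if sd > 0:
            track.loc[ok, "std"] = (vals - vals.mean()) / sd
    track.loc[track["std"].isna(), "valid"] = False
    return track
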