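"""Windowed nucleotide diversity (pi), reduction of diversity (ROD) and the
Weir–Cockerham (1984) two-population FST estimator.

pi uses the unbiased per-site estimator n/(n-1) * 2p(1-p) summed over variant
sites and divided by window length, which equals the mean pairwise Hamming
distance between sampled haplotypes per bp.  Window FST is the ratio of
averages sum(a)/sum(a+b+c) over sites, the standard multi-locus combination
(not the mean of per-site ratios).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeSet, Window


@dataclass
class DiversityTrack:
    """Per-window diversity: columns chrom, start, end, pi, n_snps."""

    frame: pd.DataFrame
    population: str

    def __len__(self) -> int:
        return len(self.frame)


def _window_site_index(sites: pd.DataFrame, windows: list[Window]) -> list[np.ndarray]:
    """Row indices of sites falling in each window (0-based half-open)."""
    out = []
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    by_chrom: dict[str, np.ndarray] = {}
    for c in pd.unique(chrom):
        by_chrom[c] = np.flatnonzero(chrom == c)
    for w in windows:
        idx = by_chrom.get(w.chrom, np.empty(0, dtype=np.intp))
        if idx.size:
            p = pos[idx]
            sel = idx[(p >= w.start) & (p < w.end)]
        else:
            sel = idx
        out.append(sel)
    return out


def window_pi(gset: GenotypeSet, population: str, windows: list[Window]) -> DiversityTrack:
    """Nucleotide diversity per bp in each window for one population.

    Sites with fewer than two called haplotypes in the population are skipped
    (and counted in the ``n_skipped`` column).  Monomorphic windows give
    pi = 0.
    """
    alt, called = gset.allele_counts(population)
    usable = called >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(usable, alt / np.maximum(called, 1), 0.0)
        terms = np.where(
            usable,
            called / np.maximum(called - 1, 1) * 2.0 * p * (1.0 - p),
            0.0,
        )
    rows = []
    for w, idx in zip(windows, _window_site_index(gset.sites, windows)):
        ok = idx[usable[idx]]
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "pi": float(terms[ok].sum()) / w.length,
            "n_snps": int(ok.size),
            "n_skipped": int(idx.size - ok.size),
        })
    return DiversityTrack(pd.DataFrame(rows), population)


def rod(track_ref: DiversityTrack, track_test: DiversityTrack,
        min_snps: int = 10) -> pd.DataFrame:
    """Reduction of diversity 1 - pi_test/pi_ref per window.

    Windows where pi_ref = 0, or where either track has fewer than
    ``min_snps`` SNPs, are flagged invalid and excluded from outlier ranking
    downstream (the value column is NaN there).
    """
    a, b = track_ref.frame, track_test.frame
    if len(a) != len(b) or not (
        a[["chrom", "start", "end"]].equals(b[["chrom", "start", "end"]])
    ):
        raise ValueError("ROD requires tracks on identical windows")
    pi_ref = a["pi"].to_numpy()
    pi_test = b["pi"].to_numpy()
    valid = (pi_ref > 0) & (a["n_snps"].to_numpy() >= min_snps) \
        & (b["n_snps"].to_numpy() >= min_snps)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(valid, 1.0 - pi_test / np.where(pi_ref > 0, pi_ref, 1.0), np.nan)
    out = a[["chrom", "start", "end"]].copy()
    out["rod"] = val
    out["n_snps"] = np.minimum(a["n_snps"], b["n_snps"])
    out["valid"] = valid
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def wc_fst_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-site variance components (a, b, c) of the Weir–Cockerham
    estimator for r = 2 populations.

    Parameters are per-site arrays for the two populations: ``n`` diploid
    sample sizes (shape (sites, 2)), ``p`` alt-allele frequencies and ``h``
    observed heterozygote proportions.  Returns (a, b, c, theta, defined)
    where theta = a/(a+b+c) and ``defined`` is False when a+b+c == 0 (e.g.
    both populations monomorphic for the same allele).  Negative thetas are
    retained, as in the original estimator.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = 2.0
    nsum = n.sum(axis=1)
    nbar = nsum / r
    nc = (nsum - (n ** 2).sum(axis=1) / nsum) / (r - 1.0)
    pbar = (n * p).sum(axis=1) / nsum
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
    hbar = (n * h).sum(axis=1) / nsum

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (
                pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
            )
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
    c = hbar / 2.0
    tot = a + b + c
    defined = tot != 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(defined, a / np.where(defined, tot, 1.0), np.nan)
    return a, b, c, theta, defined


def wc_fst_site(gset: GenotypeSet, pop_ref: str, pop_test: str) -> pd.DataFrame:
    """Per-site WC components between two populations of a GenotypeSet."""
    cols = {}
    for k, pop in enumerate((pop_ref, pop_test)):
        d = gset.dosages[:, gset.sample_indices(pop)]
        miss = d == MISSING
        ncalled = (~miss).sum(axis=1)
        alt = np.where(miss, 0, d).sum(axis=1)
        het = np.where(miss, 0, d == 1).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[f"n{k}"] = ncalled
            cols[f"p{k}"] = np.where(ncalled > 0, alt / np.maximum(2 * ncalled, 1), np.nan)
            cols[f"h{k}"] = np.where(ncalled > 0, het / np.maximum(ncalled, 1), np.nan)
    n = np.stack([cols["n0"], cols["n1"]], axis=1)
    p = np.stack([cols["p0"], cols["p1"]], axis=1)
    h = np.stack([cols["h0"], cols["h1"]], axis=1)
    ok = (n >= 1).all(axis=1) & (n.sum(axis=1) > 2)  # nbar > 1 needed
    a, b, c, theta, defined = wc_fst_components(
        np.where(ok[:, None], n, 1), np.nan_to_num(p), np.nan_to_num(h))
    defined &= ok
    out = gset.sites[["chrom", "pos"]].copy()
    out["a"], out["b"], out["c"] = a, b, c
    out["theta"] = theta
    out["defined"] = defined
    return out


def windowed_fst(site_components: pd.DataFrame, windows: list[Window],
                 min_snps: int = 10) -> pd.DataFrame:
    """Ratio-of-averages window FST: sum(a) / sum(a+b+c) over defined sites.

    Windows whose component sum is <= 0, with no defined site, or with fewer
    than ``min_snps`` defined sites are flagged invalid.
    """
    rows = []
    for w, idx in zip(windows, _window_site_index(site_components, windows)):
        sub = site_components.iloc[idx]
        sub = sub[sub["defined"]]
        num = sub["a"].sum()
        den = (sub["a"] + sub["b"] + sub["c"]).sum()
        valid = len(sub) >= max(min_snps, 1) and den > 0
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "fst": num / den if (len(sub) and den > 0) else np.nan,
            "n_snps": int(len(sub)), "valid": bool(valid),
        })
    return pd.DataFrame(rows)
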