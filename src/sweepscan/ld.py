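"""Pairwise-r2 linkage disequilibrium decay and the half-decay distance.

Phased input uses the true haplotype r2 = D^2 / (pA qA pB qB); unphased
diploid input falls back to the squared Pearson correlation of dosages
(composite LD, the usual genotype-based approximation).  The decay curve is
the mean r2 per physical-distance bin; the half-decay distance is where the
binned curve first drops to half of its highest value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeSet, HaplotypeSet


@dataclass
class LdCurve:
    """Binned mean r2 against pairwise distance for one population."""

    frame: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    max_r2: float
    half_decay_bp: float  # NaN if the curve never reaches half of max


def hap_r2(h1: np.ndarray, h2: np.ndarray) -> float:
    """Haplotype r2 between two binary site vectors; NaN if either is
    monomorphic."""
    p1, p2 = h1.mean(), h2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return np.nan
    d = (h1 * h2).mean() - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def _pair_r2_matrixless(mat: np.ndarray, phased: bool, i: int, js: np.ndarray) -> np.ndarray:
    """r2 of site i against sites js; NaN marks skipped (monomorphic) pairs."""
    x = mat[i].astype(float)
    Y = mat[js].astype(float)
    if phased:
        p1 = x.mean()
        p2 = Y.mean(axis=1)
        d = (Y * x).mean(axis=1) - p1 * p2
        denom = p1 * (1 - p1) * p2 * (1 - p2)
    else:
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=1, keepdims=True)
        d = (Yc * xc).mean(axis=1)
        denom = (xc ** 2).mean() * (Yc ** 2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / np.where(denom > 0, denom, 1.0), np.nan)
    return r2


def ld_curve(dataset, population: str, max_dist_bp: int = 300_000,
             bin_width_bp: int = 5_000) -> LdCurve:
    """Mean r2 per distance bin for all SNP pairs within ``max_dist_bp``.

    Accepts a HaplotypeSet (haplotype r2) or GenotypeSet (dosage r2 with
    per-site mean imputation of missing calls).  Monomorphic pairs are
    skipped.
    """
    phased = isinstance(dataset, HaplotypeSet)
    if phased:
        mat = dataset.haplotypes[:, dataset.hap_indices(population)].astype(float)
    else:
        d = dataset.dosages[:, dataset.sample_indices(population)].astype(float)
        d[dataset.dosages[:, dataset.sample_indices(population)] == MISSING] = np.nan
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
        idx = np.where(np.isnan(d))
        d[idx] = np.take(np.nan_to_num(col_mean), idx[0])
        mat = d
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 sites for LD")

    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    sites = dataset.sites
    for chrom in pd.unique(sites["chrom"]):
        rows = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy()[rows]
        sub = mat[rows]
        for k in range(len(rows) - 1):
            hi = np.searchsorted(pos, pos[k] + max_dist_bp, side="right")
            js = np.arange(k + 1, hi)
            if js.size == 0:
                continue
            r2 = _pair_r2_matrixless(sub, phased, k, js)
            dist = pos[js] - pos[k]
            ok = ~np.isnan(r2)
            b = np.minimum(dist[ok] // bin_width_bp, n_bins - 1)
            np.add.at(sums, b, r2[ok])
            np.add.at(counts, b, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    frame = pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width_bp,
        "bin_end": np.arange(1, n_bins + 1) * bin_width_bp,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    max_r2 = float(np.nanmax(mean_r2)) if counts.sum() else np.nan
    return LdCurve(frame, max_r2, half_decay(frame, max_r2))


def half_decay(frame: pd.DataFrame, max_r2: float | None = None) -> float:
    """Midpoint of the first distance bin whose mean r2 has fallen to half
    of the curve's highest value; NaN if the curve never gets there."""
    vals = frame["mean_r2"].to_numpy()
    if max_r2 is None:
        max_r2 = np.nanmax(vals)
    if not np.isfinite(max_r2):
        return np.nan
    for i in range(len(frame)):
        v = vals[i]
        if np.isfinite(v) and v <= max_r2 / 2.0:
            return float((frame["bin_start"].iloc[i] + frame["bin_end"].iloc[i]) / 2.0)
    return np.nan
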