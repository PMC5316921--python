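"""Genotype PCA with allele-frequency standardisation.

Each site is centred by twice its alt-allele frequency and scaled by the
binomial standard deviation sqrt(2 p (1-p)) (the usual normalisation for
population-structure PCA); missing dosages are mean-imputed beforehand.
Coordinates are the left singular vectors of the standardised sample x site
matrix scaled by their singular values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeSet


@dataclass
class PcaResult:
    coords: np.ndarray            # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    samples: list[str]


def pca(gset: GenotypeSet, n_components: int = 2) -> PcaResult:
    if n_components > gset.n_samples:
        raise ValueError("more components requested than samples")
    X = gset.dosages.T.astype(float)          # samples x sites
    miss = gset.dosages.T == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean)        # all-missing columns -> 0
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0                          # drop monomorphic columns
    Z = (X[:, keep] - 2.0 * p[keep]) / scale[keep]

    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, S.size)
    coords = U[:, :k] * S[:k]
    ev = (S ** 2) / max(gset.n_samples - 1, 1)
    pad = n_components - k
    if pad:  # degenerate: fewer informative dimensions than asked
        coords = np.hstack([coords, np.zeros((gset.n_samples, pad))])
        ev = np.concatenate([ev, np.zeros(pad)])
    total = ev.sum()
    ratio = ev[:n_components] / total if total > 0 else np.zeros(n_components)
    return PcaResult(coords, ev[:n_components], ratio, list(gset.samples))
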