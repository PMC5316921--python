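"""Core containers shared by every scan: genotype/haplotype matrices, genomic
windows, gene models and genetic maps.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  VCF positions (1-based) are
converted on read and restored on write; GFF3 gene models keep their native
1-based inclusive coordinates because they are only ever intersected with
windows through helpers that know both conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing diploid dosage
MISSING = -1


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_lengths: Mapping[str, int],
    size: int = 100_000,
    step: int | None = None,
) -> list[Window]:
    """Tile each chromosome with windows of ``size`` bp every ``step`` bp.

    The final window is truncated at the chromosome end and kept whenever it
    covers at least one bp.  ``step`` defaults to ``size`` (non-overlapping).
    """
    if step is None:
        step = size
    if size < 1:
        raise ValueError("window size must be >= 1")
    if not (1 <= step <= size):
        raise ValueError("step must satisfy 1 <= step <= size")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom!r}")
        for start in range(0, length, step):
            windows.append(Window(chrom, start, min(start + size, length)))
    return windows


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene interval as read from GFF3 (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Physical-to-genetic distance interpolation.

    Either a uniform rate (cM/Mb) applied to every chromosome, or per-
    chromosome anchor lists of (bp, cM) pairs interpolated linearly.  Outside
    the anchored range the boundary segment's rate is extended so the map
    stays monotone.
    """

    def __init__(
        self,
        anchors: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
        rate_cM_per_Mb: float = 4.0,
    ) -> None:
        self.rate_cM_per_Mb = float(rate_cM_per_Mb)
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if anchors:
            for chrom, (pos, cm) in anchors.items():
                pos = np.asarray(pos, dtype=float)
                cm = np.asarray(cm, dtype=float)
                if pos.size != cm.size or pos.size < 2:
                    raise ValueError(f"{chrom}: need >= 2 anchors")
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"{chrom}: anchor positions not sorted")
                if np.any(np.diff(cm) < 0):
                    raise ValueError(f"{chrom}: anchor cM not non-decreasing")
                self.anchors[chrom] = (pos, cm)

    @classmethod
    def uniform(cls, rate_cM_per_Mb: float = 4.0) -> "GeneticMap":
        return cls(None, rate_cM_per_Mb)

    def cm(self, chrom: str, pos) -> np.ndarray:
        """Genetic position (cM) of physical position(s) ``pos`` (bp)."""
        pos = np.asarray(pos, dtype=float)
        if chrom not in self.anchors:
            return pos * (self.rate_cM_per_Mb / 1e6)
        xp, fp = self.anchors[chrom]
        out = np.interp(pos, xp, fp)
        # linear extrapolation beyond the anchored range
        lo = pos < xp[0]
        if np.any(lo):
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            out = np.where(lo, fp[0] + (pos - xp[0]) * slope, out)
        hi = pos > xp[-1]
        if np.any(hi):
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            out = np.where(hi, fp[-1] + (pos - xp[-1]) * slope, out)
        return out

    def morgans(self, chrom: str, pos) -> np.ndarray:
        return self.cm(chrom, pos) / 100.0


# ---------------------------------------------------------------------------
# site tables and genotype/haplotype sets
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "missing_count", "maf"]


def _check_sites(sites: pd.DataFrame) -> None:
    for chrom, grp in sites.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


def _annotate(sites: pd.DataFrame, dosages: np.ndarray) -> pd.DataFrame:
    """Fill missing_count and pooled MAF columns from a dosage matrix."""
    missing = (dosages == MISSING).sum(axis=1)
    called = 2 * (dosages.shape[1] - missing)
    alt = np.where(dosages == MISSING, 0, dosages).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    sites = sites.copy()
    sites["missing_count"] = missing.astype(np.int64)
    sites["maf"] = np.minimum(p, 1.0 - p)
    return sites


@dataclass
class GenotypeSet:
    """Diploid dosage matrix (sites x samples) with site metadata.

    Dosages count alt alleles (0, 1, 2); :data:`MISSING` marks an uncalled
    genotype.  Every sample maps to exactly one population.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]
    populations: dict[str, str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sites):
            raise ValueError("dosage matrix does not match site table")
        if self.dosages.shape[1] != len(self.samples):
            raise ValueError("dosage matrix does not match sample list")
        for s in self.samples:
            if s not in self.populations:
                raise ValueError(f"sample {s!r} has no population assignment")
        if "missing_count" not in self.sites.columns:
            self.sites = _annotate(self.sites, self.dosages)
        self.sites = self.sites.reset_index(drop=True)
        _check_sites(self.sites)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"population {population!r} not found")
        return idx

    # -- per-population allele summaries ------------------------------------
    def allele_counts(self, population: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt_count, called_haplotypes) per site, pooled or per population."""
        d = self.dosages if population is None else self.dosages[:, self.sample_indices(population)]
        miss = d == MISSING
        called = 2 * (d.shape[1] - miss.sum(axis=1))
        alt = np.where(miss, 0, d).sum(axis=1)
        return alt.astype(np.int64), called.astype(np.int64)

    def allele_freq(self, population: str | None = None) -> np.ndarray:
        alt, called = self.allele_counts(population)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(called > 0, alt / np.maximum(called, 1), np.nan)

    # -- subsetting ----------------------------------------------------------
    def take(self, index) -> "GenotypeSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeSet(
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosages=self.dosages[index],
            samples=list(self.samples),
            populations=dict(self.populations),
        )


@dataclass
class HaplotypeSet:
    """Phased binary allele matrix (sites x haplotypes), two haplotypes per
    sample in sample order; no missing values."""

    sites: pd.DataFrame
    haplotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != len(self.sites):
            raise ValueError("haplotype matrix does not match site table")
        if self.haplotypes.shape[1] != 2 * len(self.samples):
            raise ValueError("haplotype count must be 2 x sample count")
        if not np.all((self.haplotypes == 0) | (self.haplotypes == 1)):
            raise ValueError("haplotype alleles must be 0/1 (no missing)")
        for s in self.samples:
            if s not in self.populations:
                raise ValueError(f"sample {s!r} has no population assignment")
        if "missing_count" not in self.sites.columns:
            self.sites = _annotate(self.sites, self.to_dosages())
        self.sites = self.sites.reset_index(drop=True)
        _check_sites(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def hap_indices(self, population: str) -> np.ndarray:
        idx = []
        for i, s in enumerate(self.samples):
            if self.populations[s] == population:
                idx.extend((2 * i, 2 * i + 1))
        if not idx:
            raise KeyError(f"population {population!r} not found")
        return np.array(idx, dtype=np.intp)

    def to_dosages(self) -> np.ndarray:
        return (self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]).astype(np.int8)

    def to_genotype_set(self) -> GenotypeSet:
        return GenotypeSet(
            sites=self.sites[["chrom", "pos", "ref", "alt"]].copy(),
            dosages=self.to_dosages(),
            samples=list(self.samples),
            populations=dict(self.populations),
        )

    def take(self, index) -> "HaplotypeSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypeSet(
            sites=self.sites.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[index],
            samples=list(self.samples),
            populations=dict(self.populations),
        )


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_sites(dataset, max_missing: float = 0.0, min_maf: float = 0.05):
    """Drop sites by missingness and pooled minor-allele frequency.

    ``max_missing`` is the tolerated fraction of samples with a missing call
    (0 = a single missing genotype removes the site); sites are kept when
    ``maf >= min_maf`` (a site at exactly the threshold survives).  Works on
    both :class:`GenotypeSet` and :class:`HaplotypeSet`; order is preserved
    and the operation is idempotent.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    n_samples = len(dataset.samples)
    miss = dataset.sites["missing_count"].to_numpy()
    maf = dataset.sites["maf"].to_numpy()
    keep = (miss <= max_missing * n_samples) & (maf >= min_maf)
    return dataset.take(keep)
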