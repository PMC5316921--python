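"""Empirical outlier calling, outlier-to-gene mapping and the >= 2-metric
candidate-gene intersection.

Outliers are the empirical top quantile (default 2.5%) of each metric's
genome-wide distribution: exactly ceil(q * M) of the M valid records are
flagged, with ties broken deterministically in genomic order.  A candidate
selection gene is one hit by the outliers of at least ``min_support``
(default 2) of the five metrics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneModel

METRICS = ("ROD", "FST", "XPEHH", "IHS", "XPCLR")

#: default tail per metric: diversity loss / differentiation / long
#: haplotypes in the test population are all upper-tail signals; iHS is
#: conventionally two-sided on |score|.
DEFAULT_TAILS = {"ROD": "upper", "FST": "upper", "XPEHH": "upper",
                 "IHS": "two_sided_abs", "XPCLR": "upper"}


@dataclass
class ScanTrack:
    """One metric's records on a common (chrom, start, end, value, valid)
    schema; site-level metrics use end = start + 1."""

    metric: str
    unit: str                      # "window" or "site"
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.unit not in ("window", "site"):
            raise ValueError("unit must be 'window' or 'site'")
        required = {"chrom", "start", "end", "value", "valid"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"track frame needs columns {sorted(required)}")

    @classmethod
    def from_windows(cls, metric: str, frame: pd.DataFrame, value_col: str,
                     valid_col: str = "valid") -> "ScanTrack":
        f = frame[["chrom", "start", "end"]].copy()
        f["value"] = frame[value_col].to_numpy(dtype=float)
        f["valid"] = (frame[valid_col].to_numpy(dtype=bool)
                      if valid_col in frame else np.isfinite(f["value"]))
        f["valid"] &= np.isfinite(f["value"])
        return cls(metric, "window", f)

    @classmethod
    def from_sites(cls, metric: str, frame: pd.DataFrame, value_col: str,
                   valid_col: str = "valid") -> "ScanTrack":
        f = pd.DataFrame({
            "chrom": frame["chrom"], "start": frame["pos"].astype(np.int64),
            "end": frame["pos"].astype(np.int64) + 1,
            "value": frame[value_col].to_numpy(dtype=float),
        })
        f["valid"] = (frame[valid_col].to_numpy(dtype=bool)
                      if valid_col in frame else np.isfinite(f["value"]))
        f["valid"] &= np.isfinite(f["value"])
        return cls(metric, "site", f.reset_index(drop=True))


def call_outliers(track: ScanTrack, q: float = 0.025,
                  tail: str | None = None) -> ScanTrack:
    """Flag the empirical top ceil(q * M) of the M valid records.

    ``tail`` is "upper", "lower" or "two_sided_abs" (default: the metric's
    conventional tail).  Records are ranked by the tail-appropriate score,
    ties resolved by (chrom, start), so repeated runs flag an identical
    set.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    tail = tail or DEFAULT_TAILS[track.metric]
    if tail not in ("upper", "lower", "two_sided_abs"):
        raise ValueError(f"unknown tail {tail!r}")
    f = track.frame.copy().reset_index(drop=True)
    value = f["value"].to_numpy(dtype=float)
    if tail == "upper":
        score = value
    elif tail == "lower":
        score = -value
    else:
        score = np.abs(value)
    valid = f["valid"].to_numpy(dtype=bool) & np.isfinite(score)
    m = int(valid.sum())
    if m < 1:
        raise ValueError("no valid records to rank")
    n_out = math.ceil(q * m)
    idx = np.flatnonzero(valid)
    sub = pd.DataFrame({"score": score[idx], "chrom": f["chrom"].to_numpy()[idx],
                        "start": f["start"].to_numpy()[idx], "row": idx})
    sub = sub.sort_values(["score", "chrom", "start"],
                          ascending=[False, True, True], kind="mergesort")
    flagged = sub["row"].to_numpy()[:n_out]
    f["outlier"] = False
    f.loc[flagged, "outlier"] = True
    return ScanTrack(track.metric, track.unit, f)


def outliers_to_genes(track: ScanTrack, genes: list[GeneModel],
                      flank_bp: int = 0) -> set[str]:
    """Genes hit by the flagged records of a called track.

    Window metrics: a gene is included when its interval overlaps an
    outlier window by >= 1 bp after extending the window by ``flank_bp``.
    Site metrics: when an outlier site lies within
    [gene.start - flank_bp, gene.end + flank_bp].  Both reduce to interval
    overlap of the flank-extended record with the gene.
    """
    if "outlier" not in track.frame.columns:
        raise ValueError("track has no outlier flags; run call_outliers first")
    out = track.frame[track.frame["outlier"]]
    hits: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, grp in out.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy() - flank_bp
        ends = grp["end"].to_numpy() + flank_bp
        for g in by_chrom.get(chrom, ()):
            g0, g1 = g.start - 1, g.end  # to 0-based half-open
            if np.any((starts < g1) & (ends > g0)):
                hits.add(g.gene_id)
    return hits


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    metrics: frozenset
    support: int


def candidate_genes(gene_sets: dict[str, set], min_support: int = 2
                    ) -> list[CandidateGene]:
    """Genes present in at least ``min_support`` of the per-metric sets,
    each annotated with its supporting metrics.  Sorted by gene id."""
    if len(gene_sets) < 2:
        raise ValueError("need gene sets from at least two metrics")
    support: dict[str, set] = {}
    for metric, genes in gene_sets.items():
        for g in genes:
            support.setdefault(g, set()).add(metric)
    out = [CandidateGene(g, frozenset(m), len(m))
           for g, m in support.items() if len(m) >= min_support]
    return sorted(out, key=lambda c: c.gene_id)


def overlap_table(gene_sets: dict[str, set]) -> pd.DataFrame:
    """Venn-style counts: genes per exact combination of supporting
    metrics, plus per-metric totals."""
    support: dict[str, set] = {}
    for metric, genes in gene_sets.items():
        for g in genes:
            support.setdefault(g, set()).add(metric)
    combos: dict[str, int] = {}
    for g, m in support.items():
        key = "+".join(sorted(m))
        combos[key] = combos.get(key, 0) + 1
    rows = [{"combination": k, "n_genes": v}
            for k, v in sorted(combos.items())]
    for metric in sorted(gene_sets):
        rows.append({"combination": f"total:{metric}",
                     "n_genes": len(gene_sets[metric])})
    return pd.DataFrame(rows)


def flank_genes(genes: list[GeneModel], chrom: str, locus_pos: int,
                flank_bp: int = 600_000) -> list[GeneModel]:
    """Genes whose interval intersects [locus_pos - flank, locus_pos +
    flank] on ``chrom`` (1-based coordinates, like the gene models)."""
    lo, hi = locus_pos - flank_bp, locus_pos + flank_bp
    return [g for g in genes
            if g.chrom == chrom and g.end >= lo and g.start <= hi]
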