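"""End-to-end selection-scan pipeline: VCF -> five metric tracks ->
empirical outliers -> candidate genes, with deterministic text outputs.

Stage order: read inputs, filter sites (no missing calls, MAF >= 0.05 by
default), tile 100-kb windows, compute ROD / FST / iHS / XP-EHH / XP-CLR,
flag the empirical top 2.5% per metric, map outliers to genes and intersect
across metrics (>= 2 supporting metrics makes a candidate).  Any stage
failure aborts with the stage name and cause.  Given the same inputs and
seed the outputs are byte-identical.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GeneticMap, filter_sites, make_windows
from .diversity import rod, wc_fst_site, window_pi, windowed_fst
from .ehh import ihs_scan, xpehh_scan
from .io import read_gff, read_map, read_population_table, read_vcf, write_bed
from .outliers import (ScanTrack, call_outliers, candidate_genes,
                       outliers_to_genes, overlap_table)
from .xpclr import xpclr_scan, xpclr_windowed

ALL_METRICS = ("rod", "fst", "ihs", "xpehh", "xpclr")


@dataclass
class PipelineConfig:
    vcf: str
    pops: str
    gff: str
    ref_pop: str
    test_pop: str
    out_dir: str
    map: str | None = None
    window_size: int = 100_000
    step: int | None = None
    top_q: float = 0.025
    min_support: int = 2
    metrics: tuple = ALL_METRICS
    seed: int = 0
    min_snps: int = 10
    max_missing: float = 0.0
    min_maf: float = 0.05
    flank_bp: int = 0             # site-metric -> gene mapping flank
    rate_cM_per_Mb: float = 4.0
    chrom_lengths: dict | None = None
    xpclr_grid_bp: int = 10_000
    xpclr_window_cM: float = 0.5


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(name, e) from e
        return wrapped
    return deco


def _fmt_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested scans and write tracks, outlier BED, candidate
    gene TSV and a summary JSON into ``config.out_dir``.  Returns the
    summary dict."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = tuple(m.lower() for m in cfg.metrics)
    for m in metrics:
        if m not in ALL_METRICS:
            raise ValueError(f"unknown metric {m!r}")

    @_stage("read_inputs")
    def _read():
        pops = read_population_table(cfg.pops)
        data = read_vcf(cfg.vcf, pops)
        genes = read_gff(cfg.gff)
        gmap = read_map(cfg.map) if cfg.map else GeneticMap.uniform(cfg.rate_cM_per_Mb)
        return data, genes, gmap

    data, genes, gmap = _read()

    @_stage("filter_sites")
    def _filter():
        return filter_sites(data.genotypes, cfg.max_missing, cfg.min_maf)

    gset = _filter()
    # EHH-family scans keep the full phased site set: rare variants drive
    # the EHH decay, and the MAF threshold applies to core SNPs only
    # (inside the scans), as in standard practice.
    hapset = data.haplotypes
    needs_phase = {"ihs", "xpehh"} & set(metrics)
    if needs_phase and hapset is None:
        raise StageError("read_inputs", ValueError(
            f"metrics {sorted(needs_phase)} need fully phased genotypes"))

    @_stage("windows")
    def _windows():
        lengths = cfg.chrom_lengths or data.contig_lengths
        if not lengths:
            lengths = {c: int(grp["pos"].max()) + 1
                       for c, grp in gset.sites.groupby("chrom", sort=False)}
        return lengths, make_windows(lengths, cfg.window_size, cfg.step)

    lengths, windows = _windows()

    tracks: dict[str, ScanTrack] = {}

    if "rod" in metrics:
        @_stage("rod")
        def _rod():
            pi_ref = window_pi(gset, cfg.ref_pop, windows)
            pi_test = window_pi(gset, cfg.test_pop, windows)
            frame = rod(pi_ref, pi_test, min_snps=cfg.min_snps)
            return ScanTrack.from_windows("ROD", frame, "rod")
        tracks["ROD"] = _rod()

    if "fst" in metrics:
        @_stage("fst")
        def _fst():
            comp = wc_fst_site(gset, cfg.ref_pop, cfg.test_pop)
            frame = windowed_fst(comp, windows, min_snps=cfg.min_snps)
            return ScanTrack.from_windows("FST", frame, "fst")
        tracks["FST"] = _fst()

    if "ihs" in metrics:
        @_stage("ihs")
        def _ihs():
            frame = ihs_scan(hapset, cfg.test_pop, gmap=gmap)
            return ScanTrack.from_sites("IHS", frame, "std")
        tracks["IHS"] = _ihs()

    if "xpehh" in metrics:
        @_stage("xpehh")
        def _xpehh():
            frame = xpehh_scan(hapset, cfg.test_pop, cfg.ref_pop, gmap=gmap)
            return ScanTrack.from_sites("XPEHH", frame, "std")
        tracks["XPEHH"] = _xpehh()

    if "xpclr" in metrics:
        @_stage("xpclr")
        def _xpclr():
            grid = xpclr_scan(gset, cfg.ref_pop, cfg.test_pop, gmap=gmap,
                              grid_spacing_bp=cfg.xpclr_grid_bp,
                              window_cM=cfg.xpclr_window_cM,
                              chrom_lengths=lengths)
            frame = xpclr_windowed(grid, windows)
            return ScanTrack.from_windows("XPCLR", frame, "clr")
        tracks["XPCLR"] = _xpclr()

    @_stage("outliers")
    def _call():
        called = {}
        for name, track in tracks.items():
            called[name] = call_outliers(track, q=cfg.top_q)
        return called

    called = _call()

    @_stage("genes")
    def _genes():
        gene_sets = {}
        for name, track in called.items():
            flank = cfg.flank_bp if track.unit == "site" else 0
            gene_sets[name] = outliers_to_genes(track, genes, flank_bp=flank)
        cands = candidate_genes(gene_sets, cfg.min_support) \
            if len(gene_sets) >= 2 else []
        return gene_sets, cands

    gene_sets, cands = _genes()

    @_stage("write_outputs")
    def _write():
        bed_rows = []
        for name in sorted(called):
            track = called[name]
            _fmt_frame(track.frame, out / f"track_{name.lower()}.tsv")
            flagged = track.frame[track.frame["outlier"]]
            for _, row in flagged.iterrows():
                bed_rows.append((row["chrom"], int(row["start"]),
                                 int(row["end"]), name,
                                 f"{row['value']:.6g}"))
        bed_rows.sort(key=lambda r: (r[0], r[1], r[3]))
        write_bed(bed_rows, out / "outliers.bed")

        cand_frame = pd.DataFrame(
            [{"gene_id": c.gene_id, "support": c.support,
              "metrics": ",".join(sorted(c.metrics))} for c in cands],
            columns=["gene_id", "support", "metrics"])
        _fmt_frame(cand_frame, out / "candidate_genes.tsv")
        _fmt_frame(overlap_table(gene_sets), out / "metric_overlap.tsv")

        summary = {
            "seed": cfg.seed,
            "n_sites_input": int(data.genotypes.n_sites),
            "n_sites_filtered": int(gset.n_sites),
            "n_skipped_records": int(data.n_skipped),
            "n_windows": len(windows),
            "per_metric": {
                name: {
                    "n_valid": int(called[name].frame["valid"].sum()),
                    "n_outliers": int(called[name].frame["outlier"].sum()),
                    "n_genes": len(gene_sets[name]),
                } for name in sorted(called)
            },
            "candidate_count": len(cands),
            "min_support": cfg.min_support,
            "top_q": cfg.top_q,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary

    return _write()
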