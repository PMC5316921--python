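"""Readers and writers for the external formats the scans consume.

VCF 4.x is read with cyvcf2 (biallelic SNP records only; anything else is
skipped and counted), GFF3 with gffutils, and the small tabular side inputs
(population table, genetic map) with pandas.  The VCF writer emits the
supported subset — biallelic SNPs, GT only — so a read/write cycle preserves
genotypes, positions and sample order exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import gffutils

from .data import MISSING, GeneModel, GeneticMap, GenotypeSet, HaplotypeSet, _annotate

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class VcfData:
    """Result of :func:`read_vcf`: dosages always, haplotypes when phased."""

    genotypes: GenotypeSet
    haplotypes: HaplotypeSet | None
    n_skipped: int
    contig_lengths: dict[str, int]


def read_population_table(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"sample {dup!r} listed twice in population table")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path, population_table: Mapping[str, str]) -> VcfData:
    """Read a VCF 4.x into a :class:`GenotypeSet` (plus a
    :class:`HaplotypeSet` when every genotype is phased and called).

    Only biallelic SNP records are used; multiallelic or non-SNP records are
    skipped with a logged count, never split.  A sample named in
    ``population_table`` but absent from the VCF is an error, as is an allele
    index other than 0/1/missing (reported with the file line number).
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for s in population_table:
        if s not in samples:
            raise ValueError(f"sample {s!r} in population table absent from VCF")
    missing_pop = [s for s in samples if s not in population_table]
    if missing_pop:
        raise ValueError(f"VCF sample {missing_pop[0]!r} missing from population table")

    header_lines = 0  # from the file itself: cyvcf2 normalises its header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
    try:
        contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without contig lines
        contig_lengths = {}

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    all_phased = True
    any_missing = False

    for rec_idx, v in enumerate(vcf):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF.upper() not in _BASES or v.ALT[0].upper() not in _BASES:
            n_skipped += 1
            continue
        gts = v.genotype.array()  # (n_samples, ploidy+1): a0, a1, phased
        alleles = gts[:, :2]
        if np.any(alleles > 1):
            line = header_lines + rec_idx + 1
            raise ValueError(
                f"malformed GT at {v.CHROM}:{v.POS} (file line {line}): "
                f"allele index out of range for biallelic record")
        miss = alleles < 0
        if miss.any():
            any_missing = True
        row = np.where(miss, 0, alleles).sum(axis=1).astype(np.int8)
        row[miss.any(axis=1)] = MISSING
        if not np.all(gts[:, 2] == 1):
            all_phased = False
        chroms.append(v.CHROM)
        pos.append(v.POS - 1)  # to 0-based
        ref.append(v.REF.upper())
        alt.append(v.ALT[0].upper())
        dosage_rows.append(row)
        hap_rows.append(np.clip(alleles, 0, 1).astype(np.uint8).reshape(-1))

    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    sites = pd.DataFrame({
        "chrom": pd.Series(chroms, dtype=str),
        "pos": pd.Series(pos, dtype=np.int64),
        "ref": pd.Series(ref, dtype=str),
        "alt": pd.Series(alt, dtype=str),
    })
    n_samp = len(samples)
    dosages = (np.vstack(dosage_rows) if dosage_rows
               else np.empty((0, n_samp), dtype=np.int8))
    gset = GenotypeSet(sites, dosages, samples, dict(population_table))

    hapset = None
    if all_phased and not any_missing:
        haps = (np.vstack(hap_rows) if hap_rows
                else np.empty((0, 2 * n_samp), dtype=np.uint8))
        hapset = HaplotypeSet(sites.copy(), haps, samples, dict(population_table))
    return VcfData(gset, hapset, n_skipped, contig_lengths)


def write_vcf(dataset, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeSet or HaplotypeSet as a plain-text VCF 4.2.

    A HaplotypeSet is written phased ("|"); a GenotypeSet unphased ("/",
    heterozygotes as 0/1).  GT is the only FORMAT field.
    """
    phased = isinstance(dataset, HaplotypeSet)
    sep = "|" if phased else "/"
    lines = ["##fileformat=VCFv4.2", "##source=sweepscan"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples))
    sites = dataset.sites
    for i in range(len(sites)):
        row = sites.iloc[i]
        if phased:
            h = dataset.haplotypes[i]
            gts = [f"{h[2 * j]}{sep}{h[2 * j + 1]}" for j in range(len(dataset.samples))]
        else:
            d = dataset.dosages[i]
            lut = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: f".{sep}."}
            gts = [lut[int(x)] for x in d]
        lines.append("\t".join([
            str(row["chrom"]), str(int(row["pos"]) + 1), ".", str(row["ref"]),
            str(row["alt"]), ".", "PASS", ".", "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path) -> list[GeneModel]:
    """Gene features from a GFF3 file, native 1-based inclusive coordinates."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end,
                               feat.strand or "+"))
    return genes


def read_map(path) -> GeneticMap:
    """Three-column TSV (chrom, pos bp, cM) -> interpolating GeneticMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "cm"],
                     dtype={"chrom": str, "pos": np.int64, "cm": float},
                     comment="#")
    anchors = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        anchors[chrom] = (grp["pos"].to_numpy(), grp["cm"].to_numpy())
    return GeneticMap(anchors)


def uniform_map(rate_cM_per_Mb: float = 4.0) -> GeneticMap:
    return GeneticMap.uniform(rate_cM_per_Mb)


def write_bed(records, path) -> None:
    """Write (chrom, start, end, name, score) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
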