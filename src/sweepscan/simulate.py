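"""Two-population forward Wright-Fisher simulator with an optional
conditioned hard sweep, plus light-weight generators for drift-only
frequency pairs and synthetic tissue-expression matrices.

The full simulator emulates the divergence the scans assume: an ancestral
population (optionally seeded with standing variation from a 1/x neutral
site-frequency spectrum) drifts for ``T_burn`` generations, splits into a
reference (landrace-like) and a test (weedy-like) population of the same
size, and the daughters evolve independently for ``T_split`` generations.
A hard sweep can be planted in the test population: a single beneficial
copy with additive fitness (1, 1 + s/2, 1 + s), optionally conditioned on
fixation by re-running the test population's trajectory (never re-drawing
the seed) until the allele fixes.  Forward simulation keeps sweeps,
conditioning and LD exact by construction; a desk-scale guard
(N <= 1000, L <= 1 Mb) keeps runs fast.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GeneModel, GeneticMap, GenotypeSet, HaplotypeSet, make_windows
from .diversity import wc_fst_site, windowed_fst
from . import io as sio

_TISSUES = ["leaf", "root", "stem", "panicle", "anther", "pistil", "lemma",
            "palea", "ovary", "embryo", "endosperm"]


@dataclass
class SweepSpec:
    """A hard sweep planted in the test population."""

    position: int
    s: float = 0.5
    start_gen: int = 0            # generations after the split
    condition_on_fixation: bool = True


@dataclass
class SimConfig:
    N: int = 200                  # diploids per population
    L: int = 500_000              # bp
    mu: float = 2e-6              # per-site per-generation
    r: float = 4e-8               # per-adjacent-bp per-generation (4 cM/Mb)
    T_burn: int = 100
    T_split: int = 40
    sweep: SweepSpec | None = None
    n_sample: int = 20            # diploids sampled per population
    n_standing: int = 800         # standing-variation sites at burn-in start
    seed: int = 0
    chrom: str = "chr1"
    ref_name: str = "landrace"
    test_name: str = "weedy"

    def __post_init__(self) -> None:
        if self.N > 1000 or self.L > 1_000_000:
            raise ValueError("desk-scale guard: N <= 1000 and L <= 1 Mb")
        if min(self.N, self.L) < 1 or min(self.mu, self.r) < 0:
            raise ValueError("sizes must be positive and rates non-negative")
        if self.n_sample > 2 * self.N:
            raise ValueError("cannot sample more than 2N haplotypes")
        if self.sweep is not None and not (0 <= self.sweep.position < self.L):
            raise ValueError("sweep position outside [0, L)")


@dataclass
class SweepTruth:
    position: int | None
    s: float | None
    fixed: bool
    final_freq: float
    split_time: int
    realized_fst: float

    def to_dict(self) -> dict:
        return {
            "position": self.position, "s": self.s, "fixed": self.fixed,
            "final_freq": self.final_freq, "split_time": self.split_time,
            "realized_fst": self.realized_fst,
        }


@dataclass
class SimResult:
    haplotypes: HaplotypeSet
    genotypes: GenotypeSet
    truth: SweepTruth
    config: SimConfig
    files: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _next_generation(positions, H, L, mu, r, rng, s=0.0, sweep_pos=None):
    """One discrete Wright-Fisher generation for one population."""
    n_hap = H.shape[1]
    N = n_hap // 2
    prob = None
    if s and sweep_pos is not None and positions.size:
        k = np.searchsorted(positions, sweep_pos)
        if k < positions.size and positions[k] == sweep_pos:
            geno = H[k, 0::2].astype(float) + H[k, 1::2]
            w = 1.0 + (s / 2.0) * geno          # 1, 1+s/2, 1+s
            prob = w / w.sum()
    parents = rng.choice(N, size=n_hap, p=prob)

    if positions.size:
        A = H[:, 2 * parents]
        B = H[:, 2 * parents + 1]
        phase = np.empty((positions.size, n_hap), dtype=bool)
        n_cross = rng.poisson(r * L, size=n_hap)
        starts = rng.integers(0, 2, size=n_hap)
        for g in range(n_hap):
            if n_cross[g]:
                bps = np.sort(rng.integers(0, L, size=n_cross[g]))
                cnt = np.searchsorted(bps, positions, side="left")
                phase[:, g] = (cnt + starts[g]) % 2 == 1
            else:
                phase[:, g] = bool(starts[g])
        child = np.where(phase, B, A)
    else:
        child = H.copy()

    n_mut = rng.poisson(mu * L, size=n_hap)
    total = int(n_mut.sum())
    if total:
        existing = set(positions.tolist())
        new_pos = np.empty(total, dtype=np.int64)
        for j in range(total):  # repeat-hit positions are re-drawn
            while True:
                p = int(rng.integers(0, L))
                if p not in existing:
                    existing.add(p)
                    new_pos[j] = p
                    break
        gam = np.repeat(np.arange(n_hap), n_mut)
        rows = np.zeros((total, n_hap), dtype=np.uint8)
        rows[np.arange(total), gam] = 1
        positions = np.concatenate([positions, new_pos])
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        child = np.vstack([child, rows])[order]
    return positions, child


def _purge(positions, H, keep_fixed, sweep_pos=None):
    """Drop lost sites (and, pre-split, fixed ones); the sweep site stays."""
    if not positions.size:
        return positions, H
    totals = H.sum(axis=1, dtype=np.int64)
    keep = totals > 0
    if not keep_fixed:
        keep &= totals < H.shape[1]
    if sweep_pos is not None:
        k = np.searchsorted(positions, sweep_pos)
        if k < positions.size and positions[k] == sweep_pos:
            keep[k] = True
    return positions[keep], H[keep]


def _sweep_freq(positions, H, sweep_pos):
    k = np.searchsorted(positions, sweep_pos)
    if k < positions.size and positions[k] == sweep_pos:
        return float(H[k].mean())
    return 0.0


def _evolve_test_pop(positions, H, cfg, rng, sweep):
    """Post-split trajectory of the test population, with the optional
    sweep seeded at generation ``sweep.start_gen``."""
    sweep_pos = sweep.position if sweep else None
    for t in range(cfg.T_split):
        s_now = 0.0
        if sweep and t == sweep.start_gen:
            k = np.searchsorted(positions, sweep_pos)
            if not (k < positions.size and positions[k] == sweep_pos):
                positions = np.insert(positions, k, sweep_pos)
                H = np.insert(H, k, np.zeros(H.shape[1], dtype=np.uint8), axis=0)
            H[k] = 0  # the beneficial mutation is new: one copy
            H[k, rng.integers(0, H.shape[1])] = 1
        if sweep and t >= sweep.start_gen:
            s_now = sweep.s
        positions, H = _next_generation(positions, H, cfg.L, cfg.mu, cfg.r,
                                        rng, s=s_now, sweep_pos=sweep_pos)
        positions, H = _purge(positions, H, keep_fixed=True, sweep_pos=sweep_pos)
        if sweep and t >= sweep.start_gen and sweep.condition_on_fixation \
                and _sweep_freq(positions, H, sweep_pos) == 0.0:
            return positions, H, False  # lost: caller restarts
    if sweep and sweep.condition_on_fixation:
        return positions, H, _sweep_freq(positions, H, sweep_pos) == 1.0
    return positions, H, True


def simulate(config: SimConfig, out_dir=None) -> SimResult:
    """Run the two-population simulation and sample phased haplotypes.

    Returns the sampled HaplotypeSet/GenotypeSet and the ground truth; when
    ``out_dir`` is given, also writes ``sim.vcf`` (phased), ``map.tsv``
    (uniform map matching the recombination rate), ``genes.gff3`` (genes
    tiled every 20 kb, 5 kb long) and ``truth.json``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_burn, rng_ref, rng_test, rng_out = [np.random.default_rng(s)
                                            for s in ss.spawn(4)]

    n_hap = 2 * cfg.N
    # standing variation: frequencies from a 1/x neutral SFS
    if cfg.n_standing:
        grid = np.arange(1, n_hap) / n_hap
        wgt = (1.0 / np.arange(1, n_hap))
        wgt /= wgt.sum()
        freqs = rng_burn.choice(grid, size=cfg.n_standing, p=wgt)
        positions = np.sort(rng_burn.choice(cfg.L, size=cfg.n_standing,
                                            replace=False)).astype(np.int64)
        H = np.zeros((cfg.n_standing, n_hap), dtype=np.uint8)
        for i, f in enumerate(freqs):
            k = max(1, int(round(f * n_hap)))
            H[i, rng_burn.choice(n_hap, size=min(k, n_hap - 1), replace=False)] = 1
    else:
        positions = np.empty(0, dtype=np.int64)
        H = np.empty((0, n_hap), dtype=np.uint8)

    for _ in range(cfg.T_burn):
        positions, H = _next_generation(positions, H, cfg.L, cfg.mu, cfg.r, rng_burn)
        positions, H = _purge(positions, H, keep_fixed=False)

    # split: both daughters start as copies of the ancestral population
    pos_ref, H_ref = positions.copy(), H.copy()
    for _ in range(cfg.T_split):
        pos_ref, H_ref = _next_generation(pos_ref, H_ref, cfg.L, cfg.mu, cfg.r, rng_ref)
        pos_ref, H_ref = _purge(pos_ref, H_ref, keep_fixed=True)

    sweep = cfg.sweep
    attempts = 0
    while True:
        attempts += 1
        pos_test, H_test, ok = _evolve_test_pop(positions.copy(), H.copy(),
                                                cfg, rng_test, sweep)
        if ok or attempts >= 10_000:
            break
    if sweep and sweep.condition_on_fixation and not ok:
        raise RuntimeError("sweep failed to fix within the restart budget")

    final_freq = _sweep_freq(pos_test, H_test, sweep.position) if sweep else 0.0

    # sample diploids and merge the two populations over the union of sites
    samp_ref = np.sort(rng_out.choice(cfg.N, size=cfg.n_sample, replace=False))
    samp_test = np.sort(rng_out.choice(cfg.N, size=cfg.n_sample, replace=False))
    cols_ref = np.stack([2 * samp_ref, 2 * samp_ref + 1], axis=1).reshape(-1)
    cols_test = np.stack([2 * samp_test, 2 * samp_test + 1], axis=1).reshape(-1)

    union = np.union1d(pos_ref, pos_test)
    n_s = 2 * cfg.n_sample

    def _aligned(pos_src, H_src, cols):
        out = np.zeros((union.size, len(cols)), dtype=np.uint8)
        idx = np.searchsorted(union, pos_src)
        out[idx] = H_src[:, cols]
        return out

    hap_ref = _aligned(pos_ref, H_ref, cols_ref)
    hap_test = _aligned(pos_test, H_test, cols_test)
    haps = np.hstack([hap_ref, hap_test])

    seg = (haps.sum(axis=1) > 0) & (haps.sum(axis=1) < haps.shape[1])
    haps = haps[seg]
    union = union[seg]

    ref_bases = rng_out.choice(list("ACGT"), size=union.size)
    shift = rng_out.integers(1, 4, size=union.size)
    order = np.array(list("ACGT"))
    base_idx = np.searchsorted(order, ref_bases)
    alt_bases = order[(base_idx + shift) % 4]

    samples = [f"{cfg.ref_name}_{i:02d}" for i in range(cfg.n_sample)] \
        + [f"{cfg.test_name}_{i:02d}" for i in range(cfg.n_sample)]
    pops = {s: (cfg.ref_name if j < cfg.n_sample else cfg.test_name)
            for j, s in enumerate(samples)}
    sites = pd.DataFrame({
        "chrom": pd.Series([cfg.chrom] * union.size, dtype=str),
        "pos": union.astype(np.int64),
        "ref": pd.Series(ref_bases, dtype=str),
        "alt": pd.Series(alt_bases, dtype=str),
    })
    hapset = HaplotypeSet(sites, haps, samples, pops)
    gset = hapset.to_genotype_set()

    # realized FST on the sampled data (1 valid SNP is enough per window)
    comp = wc_fst_site(gset, cfg.ref_name, cfg.test_name)
    wins = make_windows({cfg.chrom: cfg.L}, 100_000)
    fst_frame = windowed_fst(comp, wins, min_snps=1)
    valid = fst_frame[fst_frame["valid"]]
    realized = float(valid["fst"].mean()) if len(valid) else float("nan")

    truth = SweepTruth(
        position=sweep.position if sweep else None,
        s=sweep.s if sweep else None,
        fixed=bool(sweep) and final_freq == 1.0,
        final_freq=final_freq,
        split_time=cfg.T_split,
        realized_fst=realized,
    )

    files: dict = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files["vcf"] = out / "sim.vcf"
        sio.write_vcf(hapset, files["vcf"], contig_lengths={cfg.chrom: cfg.L})
        files["map"] = out / "map.tsv"
        rate = cfg.r * 1e8  # per-bp prob -> cM/Mb
        with open(files["map"], "w") as fh:
            fh.write(f"{cfg.chrom}\t0\t0.0\n")
            fh.write(f"{cfg.chrom}\t{cfg.L}\t{rate * cfg.L / 1e6:.6g}\n")
        files["gff"] = out / "genes.gff3"
        _write_tiled_gff(files["gff"], cfg.chrom, cfg.L)
        files["pops"] = out / "pops.tsv"
        with open(files["pops"], "w") as fh:
            for s in samples:
                fh.write(f"{s}\t{pops[s]}\n")
        files["truth"] = out / "truth.json"
        with open(files["truth"], "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return SimResult(hapset, gset, truth, cfg, files)


def tiled_genes(chrom: str, length: int, spacing: int = 20_000,
                gene_length: int = 5_000) -> list[GeneModel]:
    """Deterministic toy gene models: one gene every ``spacing`` bp."""
    genes = []
    i = 0
    for start0 in range(0, length - gene_length + 1, spacing):
        i += 1
        genes.append(GeneModel(f"gene{i:04d}", chrom, start0 + 1,
                               start0 + gene_length, "+"))
    return genes


def _write_tiled_gff(path, chrom, length):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in tiled_genes(chrom, length):
            fh.write(f"{chrom}\tsweepscan\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                     f"ID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# fast drift-only null
# ---------------------------------------------------------------------------

def drift_only(n_sites: int, N: int, T: int, seed: int = 0,
               sfs_shape: float = 1.0) -> pd.DataFrame:
    """Paired (p_ref, p_test) frequency table from the drift null the
    XP-CLR model conditions on.

    Ancestral frequencies are drawn proportional to x**(-sfs_shape) on the
    1/2N ... (2N-1)/2N grid (a neutral SFS for shape 1).  The test
    frequency then evolves by T binomial(2N) resampling steps; the
    reference column keeps the ancestral frequency, because the model
    treats the reference population as the frequency baseline the test
    population disperses around — with this pairing the moment estimator
    of omega targets 1 - (1 - 1/2N)^T, about T/2N for T << 2N, exactly.
    Fixation and loss are absorbing, and each trajectory is a martingale.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * N
    grid = np.arange(1, n_hap) / n_hap
    wgt = np.arange(1, n_hap, dtype=float) ** (-sfs_shape)
    wgt /= wgt.sum()
    p0 = rng.choice(grid, size=n_sites, p=wgt)
    p = p0.copy()
    for _ in range(T):
        p = rng.binomial(n_hap, p) / n_hap
    return pd.DataFrame({"p0": p0, "p_ref": p0, "p_test": p})


# ---------------------------------------------------------------------------
# synthetic expression matrices
# ---------------------------------------------------------------------------

def expression_sim(n_genes: int, n_tissues: int = 11, n_clusters: int = 10,
                   seed: int = 0, noise_sd: float = 0.4,
                   low_cluster: bool = True,
                   spike_clusters: int | None = None):
    """Synthetic gene-by-tissue expression with known cluster labels.

    Cluster centroids are built in log2 space (base level + per-tissue
    variation); ``spike_clusters`` of them (default about half) get one
    strong single-tissue spike, and the last cluster is a low-expression
    cluster when ``low_cluster`` is set.  Gene profiles are the centroid
    plus Gaussian noise in log space, mapped back to non-negative raw
    values.  Returns (DataFrame genes x tissues, true label array).
    """
    rng = np.random.default_rng(seed)
    if spike_clusters is None:
        spike_clusters = n_clusters // 2
    tissues = (_TISSUES[:n_tissues] if n_tissues <= len(_TISSUES)
               else [f"tissue_{i:02d}" for i in range(n_tissues)])
    centroids = np.empty((n_clusters, n_tissues))
    for k in range(n_clusters):
        base = rng.uniform(4.0, 8.0)
        centroids[k] = base + rng.normal(0.0, 1.0, size=n_tissues)
        if k < spike_clusters:
            centroids[k, rng.integers(0, n_tissues)] += 4.0
    if low_cluster:
        centroids[-1] = rng.uniform(0.05, 0.3, size=n_tissues)
    labels = np.sort(rng.integers(0, n_clusters, size=n_genes))
    log_expr = centroids[labels]
    if noise_sd > 0:
        log_expr = log_expr + rng.normal(0.0, noise_sd, size=log_expr.shape)
    raw = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    frame = pd.DataFrame(raw, columns=tissues,
                         index=[f"gene{i:04d}" for i in range(1, n_genes + 1)])
    return frame, labels
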