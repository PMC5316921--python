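"""Shared fixtures: toy dataset builders and session-scoped simulations
reused by the unit and acceptance tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan.data import GenotypeSet, HaplotypeSet
from sweepscan.simulate import SimConfig, SweepSpec, simulate

# frozen study conditions for the sweep scenario: scaled recombination
# (100 cM/Mb) keeps the hitchhiking footprint about one 100-kb window wide
# on a 500-kb chromosome; the sweep sits on the 50-kb XP-CLR grid inside
# window [200k, 300k); T_split = 50 bounds background drift fixation.
SWEEP_SCENARIO = dict(N=200, L=500_000, mu=2e-6, r=1e-6, T_burn=100,
                      T_split=50, n_standing=800, n_sample=20)
SWEEP_POS = 225_000
SWEEP_S = 0.7
SCENARIO_RATE_CM_MB = 100.0  # matches r = 1e-6 /bp


def make_hapset(matrix, positions=None, chrom="chr1", pops=None):
    """HaplotypeSet from a (sites x haplotypes) 0/1 array; two haplotypes
    per sample, all samples in one population 'P' unless ``pops`` maps
    sample index -> name."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_sites, n_hap = matrix.shape
    assert n_hap % 2 == 0
    n_samp = n_hap // 2
    if positions is None:
        positions = np.arange(n_sites) * 100 + 100
    samples = [f"s{i}" for i in range(n_samp)]
    if pops is None:
        popmap = {s: "P" for s in samples}
    else:
        popmap = {f"s{i}": pops[i] for i in range(n_samp)}
    sites = pd.DataFrame({
        "chrom": pd.Series([chrom] * n_sites, dtype=str),
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": pd.Series(["A"] * n_sites, dtype=str),
        "alt": pd.Series(["T"] * n_sites, dtype=str),
    })
    return HaplotypeSet(sites, matrix, samples, popmap)


def make_gset(dosages, positions=None, chrom="chr1", pops=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samp = dosages.shape
    if positions is None:
        positions = np.arange(n_sites) * 100 + 100
    samples = [f"s{i}" for i in range(n_samp)]
    if pops is None:
        popmap = {s: "P" for s in samples}
    else:
        popmap = {f"s{i}": pops[i] for i in range(n_samp)}
    sites = pd.DataFrame({
        "chrom": pd.Series([chrom] * n_sites, dtype=str),
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": pd.Series(["A"] * n_sites, dtype=str),
        "alt": pd.Series(["T"] * n_sites, dtype=str),
    })
    return GenotypeSet(sites, dosages, samples, popmap)


@pytest.fixture(scope="session")
def sweep_sim():
    """One sweep-scenario replicate, reused across tests."""
    cfg = SimConfig(seed=300, sweep=SweepSpec(position=SWEEP_POS, s=SWEEP_S),
                    **SWEEP_SCENARIO)
    return simulate(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    """One neutral replicate of the same scenario geometry."""
    cfg = SimConfig(seed=77, **SWEEP_SCENARIO)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sweep_sim_dir(tmp_path_factory):
    """Sweep-scenario replicate written to disk (VCF/map/GFF/pops/truth)."""
    out = tmp_path_factory.mktemp("sweep_sim")
    cfg = SimConfig(seed=301, sweep=SweepSpec(position=SWEEP_POS, s=SWEEP_S),
                    **SWEEP_SCENARIO)
    res = simulate(cfg, out_dir=out)
    return res, out
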