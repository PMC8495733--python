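"""Shared fixtures: one mid-sized simulated ChIP experiment reused across
metric tests, plus small helpers."""
from __future__ import annotations

import numpy as np
import pytest

from sonichip import qc_metrics as qc
from sonichip import synthetic_data as sd
from sonichip.core import AlignedReadSet


@pytest.fixture(scope="session")
def motif():
    return sd.demo_motif()


@pytest.fixture(scope="session")
def sim_experiment(motif):
    """A clean (no-occlusion) simulated dataset: genome, sites, reads, truth.

    Mean fragment length 200 bp (sd 30), 20k reads, half background.
    """
    genome = sd.simulate_genome(300_000, 0.45, seed=11)
    sites = sd.place_sites(genome, motif, n_direct=60, n_indirect=40, seed=12)
    reads = sd.simulate_chip_reads(
        genome, sites, sd.IPEfficiencyModel.no_occlusion(),
        mean_frag_len=200, frag_sd=30, n_reads=20_000, read_len=36,
        background_fraction=0.5, seed=13,
    )
    truth = sd.truth_intervals(sites, genome)
    return {"genome": genome, "sites": sites, "reads": reads, "truth": truth,
            "motif": motif}


def uniform_reads(n: int, genome_len: int, seed: int, read_len: int = 36,
                  chrom: str = "chrS") -> AlignedReadSet:
    """i.i.d. uniform single-end reads on one toy chromosome."""
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, genome_len - read_len, n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return AlignedReadSet(
        np.full(n, chrom, dtype=object), starts,
        np.full(n, read_len, dtype=np.int64), strand, {chrom: genome_len},
    )
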