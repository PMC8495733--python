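"""Synthetic ChIP-seq experiments with a fragment-size -> quality mechanism.

The simulator generates a toy genome carrying direct (motif-bearing) and
indirect (motif-free) binding sites, shears it according to a sonication
decay model, and emits single-end reads whose enrichment depends on the
fragment-length distribution through two mechanisms:

* epitope occlusion — the probability that an antibody pulls down a
  site-bearing fragment decays logistically with fragment length above a
  factor-specific midpoint (CTCF-like factors are insensitive, TAL1-like
  factors are not);
* footprint loss — fragments shorter than the protein footprint
  (``min_len``) no longer carry an intact site and are lost.

Signal fragments that fail immunoprecipitation are replaced by background
fragments, so sequencing depth is held fixed while the fraction of reads at
true sites rises and falls with sonication — the same pattern the quality
metrics downstream are designed to detect.  An electropherogram of the
unenriched input chromatin (fluorescence ~ mass per size bin) accompanies
each dataset.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignedReadSet, IntervalSet
from .fragsize import Electropherogram, SonicationModel
from .motif_analysis import DNA, PWMotif

__all__ = [
    "SimGenome",
    "TruthSite",
    "IPEfficiencyModel",
    "SimulatedExperiment",
    "simulate_genome",
    "place_sites",
    "predict_fragment_length",
    "simulate_chip_reads",
    "simulate_electropherogram",
    "simulate_experiment_grid",
    "truth_intervals",
    "demo_motif",
    "draw_fragment_lengths",
]


@dataclass
class SimGenome:
    """A toy chromosome: a nucleotide string over {A,C,G,T}."""

    name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("genome length must be >= 1")
        if set(self.sequence) - set(DNA):
            raise ValueError("sequence may contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, self.length, width):
                fh.write(self.sequence[i : i + width] + "\n")


@dataclass
class TruthSite:
    """A planted binding site: direct sites carry an embedded motif word."""

    position: int            # 0-based centre
    kind: str                # 'direct' | 'indirect'
    embedded_motif: str | None = None
    strength: float = 1.0

    def __post_init__(self):
        if self.kind not in ("direct", "indirect"):
            raise ValueError("kind must be 'direct' or 'indirect'")
        if (self.kind == "direct") != (self.embedded_motif is not None):
            raise ValueError("direct sites (and only direct sites) carry a motif word")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass(frozen=True)
class IPEfficiencyModel:
    """Fragment-length-dependent immunoprecipitation efficiency.

    pulldown(L) = 1 / (1 + exp((L - occlusion_midpoint) / occlusion_scale))
    for L >= min_len, and 0 below the footprint ``min_len``.
    """

    occlusion_midpoint: float = 300.0
    occlusion_scale: float = 60.0
    min_len: float = 150.0
    name: str = "TAL1-like"

    def pulldown(self, lengths) -> np.ndarray:
        L = np.asarray(lengths, dtype=float)
        z = np.clip((L - self.occlusion_midpoint) / self.occlusion_scale, -60, 60)
        p = 1.0 / (1.0 + np.exp(z))
        p[L < self.min_len] = 0.0
        return p

    @classmethod
    def tal1_like(cls) -> "IPEfficiencyModel":
        """Occlusion-sensitive: pulldown decays beyond ~300 bp fragments."""
        return cls(occlusion_midpoint=300.0, occlusion_scale=60.0, min_len=150.0,
                   name="TAL1-like")

    @classmethod
    def ctcf_like(cls) -> "IPEfficiencyModel":
        """Occlusion-insensitive: epitope stays exposed on long fragments."""
        return cls(occlusion_midpoint=3000.0, occlusion_scale=200.0, min_len=150.0,
                   name="CTCF-like")

    @classmethod
    def no_occlusion(cls, min_len: float = 0.0) -> "IPEfficiencyModel":
        return cls(occlusion_midpoint=1e9, occlusion_scale=1.0, min_len=min_len,
                   name="ideal")


# ---------------------------------------------------------------------------

def demo_motif(
    consensus: str = "ACGGTAGCATGC",
    sharpness: float = 0.97,
    name: str = "SYNTH_TF",
) -> PWMotif:
    """A synthetic position-probability matrix for simulations.

    Each position puts ``sharpness`` on the consensus base and splits the
    remainder over the other three — an information content typical of a
    sharp transcription-factor motif.  Purely synthetic; it stands in for a
    real database motif in offline runs.
    """
    if not 0.25 < sharpness < 1:
        raise ValueError("sharpness must be in (0.25, 1)")
    idx = [DNA.index(c) for c in consensus.upper()]
    probs = np.full((len(idx), 4), (1 - sharpness) / 3)
    for i, b in enumerate(idx):
        probs[i, b] = sharpness
    return PWMotif(name=name, probs=probs)


def simulate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0,
                    name: str = "chrS") -> SimGenome:
    """i.i.d. random genome with P(G)+P(C) = gc_fraction; deterministic in seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = np.frombuffer(DNA.encode(), dtype=np.uint8)[codes].tobytes().decode()
    return SimGenome(name=name, sequence=seq)


def _resolve_strengths(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "lognormal":
        _, mean, sd = spec
        sigma2 = math.log(1 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"strengths must be scalar, ('lognormal', mean, sd), or length-{n}")
    return arr


def place_sites(
    genome: SimGenome,
    motif: PWMotif,
    n_direct: int,
    n_indirect: int,
    strengths=1.0,
    seed: int = 0,
    margin: int = 100,
) -> list[TruthSite]:
    """Plant non-overlapping binding sites; direct sites get a motif word
    sampled from the PWM written into the genome at the site centre.

    The passed genome's sequence is modified in place (motif embedding);
    the returned list is ordered by position.
    """
    rng = np.random.default_rng(seed)
    n = n_direct + n_indirect
    w = motif.width
    spacing = 2 * margin + w  # no two site windows overlap
    lo, hi = margin + w, genome.length - margin - w
    if hi <= lo or (hi - lo) < n * spacing:
        raise ValueError(
            f"genome of {genome.length} bp too short for {n} disjoint sites "
            f"with {spacing} bp spacing"
        )
    # sample non-overlapping centres via the gap construction: choose n sorted
    # uniform values in the shrunken range, then re-inflate by the spacing
    slack = (hi - lo) - n * spacing
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    centers = lo + offsets + spacing * np.arange(n) + spacing // 2
    kinds = np.array(["direct"] * n_direct + ["indirect"] * n_indirect)
    rng.shuffle(kinds)
    strength_vals = _resolve_strengths(strengths, n, rng)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    base_bytes = np.frombuffer(DNA.encode(), dtype=np.uint8)
    sites: list[TruthSite] = []
    for pos, kind, s in zip(centers, kinds, strength_vals):
        word = None
        if kind == "direct":
            codes = np.array([rng.choice(4, p=motif.probs[i]) for i in range(w)])
            word = base_bytes[codes].tobytes().decode()
            start = int(pos) - w // 2
            seq[start : start + w] = base_bytes[codes]
        sites.append(TruthSite(position=int(pos), kind=str(kind),
                               embedded_motif=word, strength=float(s)))
    genome.sequence = seq.tobytes().decode()
    return sites


def truth_intervals(sites: Sequence[TruthSite], genome: SimGenome,
                    halfwidth: int = 100) -> IntervalSet:
    """Truth peak intervals (site centre +- halfwidth) as a BED-able set."""
    starts = [max(0, s.position - halfwidth) for s in sites]
    ends = [min(genome.length, s.position + halfwidth) for s in sites]
    names = [f"{s.kind}_{i}" for i, s in enumerate(sites)]
    return IntervalSet.from_arrays(genome.name, starts, ends, name=names,
                                   score=[s.strength for s in sites])


def predict_fragment_length(model: SonicationModel, cycles: float,
                            n_cells: float | None = None) -> float:
    """Predicted average chromatin length after the given sonication cycles."""
    return model.predict(cycles, n_cells)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


def draw_fragment_lengths(rng: np.random.Generator, n: int, mean: float,
                          sd: float, floor: float = 1.0) -> np.ndarray:
    """Log-normal fragment lengths (bp), truncated below at ``floor`` by
    resampling."""
    mu, sigma = _lognormal_params(mean, sd)
    out = rng.lognormal(mu, sigma, size=n)
    for _ in range(100):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    out[out < floor] = floor
    return out


def simulate_chip_reads(
    genome: SimGenome,
    sites: Sequence[TruthSite],
    ip_model: IPEfficiencyModel,
    mean_frag_len: float,
    frag_sd: float,
    n_reads: int,
    read_len: int = 36,
    background_fraction: float = 0.2,
    seed: int = 0,
) -> AlignedReadSet:
    """Simulate single-end ChIP-seq reads at fixed sequencing depth.

    Signal fragments are drawn over sites (weighted by strength), each
    covering the site centre at a uniform offset, and survive pulldown with
    probability ``ip_model.pulldown(length)``; failed pulldowns are replaced
    by background fragments placed uniformly, so lower IP efficiency lowers
    the fraction of reads at sites rather than the read count.  Each fragment
    emits one read from a uniformly chosen end: forward read at the fragment
    start, or reverse read whose 5' end is the last fragment base.
    """
    if not 0 <= background_fraction <= 1:
        raise ValueError("background_fraction must be in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if len(sites) == 0 and background_fraction < 1:
        raise ValueError("no sites given but background_fraction < 1")
    if mean_frag_len < read_len:
        raise ValueError("mean_frag_len should be >= read_len")
    if genome.length <= mean_frag_len:
        raise ValueError("genome shorter than typical fragment")
    rng = np.random.default_rng(seed)
    n_sig = int(round((1 - background_fraction) * n_reads))
    starts_list, len_list = [], []
    if n_sig > 0:
        strengths = np.array([s.strength for s in sites], dtype=float)
        if strengths.sum() <= 0:
            raise ValueError("site strengths sum to zero")
        site_pos = np.array([s.position for s in sites], dtype=np.int64)
        idx = rng.choice(len(sites), size=n_sig, p=strengths / strengths.sum())
        lengths = draw_fragment_lengths(rng, n_sig, mean_frag_len, frag_sd,
                                        floor=read_len)
        keep = rng.random(n_sig) < ip_model.pulldown(lengths)
        lengths = np.round(lengths[keep]).astype(np.int64)
        centers = site_pos[idx[keep]]
        offset = (rng.random(len(lengths)) * lengths).astype(np.int64)
        frag_start = np.clip(centers - offset, 0, genome.length - lengths)
        starts_list.append(frag_start)
        len_list.append(lengths)
    n_bg = n_reads - sum(len(a) for a in starts_list)
    if n_bg > 0:
        lengths = np.round(
            draw_fragment_lengths(rng, n_bg, mean_frag_len, frag_sd, floor=read_len)
        ).astype(np.int64)
        lengths = np.minimum(lengths, genome.length)
        frag_start = (rng.random(n_bg) * (genome.length - lengths + 1)).astype(np.int64)
        starts_list.append(frag_start)
        len_list.append(lengths)
    frag_start = np.concatenate(starts_list)
    frag_len = np.concatenate(len_list)
    forward = rng.random(len(frag_start)) < 0.5
    read_start = np.where(forward, frag_start, frag_start + frag_len - read_len)
    read_start = np.clip(read_start, 0, genome.length - read_len)
    strand = np.where(forward, "+", "-")
    return AlignedReadSet(
        chrom=np.full(len(read_start), genome.name, dtype=object),
        start=read_start,
        length=np.full(len(read_start), read_len, dtype=np.int64),
        strand=strand,
        chrom_sizes={genome.name: genome.length},
    )


def simulate_electropherogram(
    fragment_lengths,
    bin_width: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Electropherogram:
    """Histogram of fragment lengths with intensity proportional to mass
    (length x count) per bin, plus optional additive Gaussian noise clipped
    at zero — a minimal model of a Bioanalyzer trace."""
    lengths = np.asarray(fragment_lengths, dtype=float)
    if lengths.size < 1:
        raise ValueError("need at least one fragment")
    lo = math.floor(lengths.min() / bin_width) * bin_width
    hi = (math.floor(lengths.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 3:  # ensure >= 2 trace points
        edges = np.append(edges, edges[-1] + bin_width)
    mass, _ = np.histogram(lengths, bins=edges, weights=lengths)
    centers = edges[:-1] + bin_width / 2.0
    intensity = mass.astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0, noise_sd, size=intensity.size), 0, None)
    return Electropherogram(size_bp=centers, intensity=intensity)


# ---------------------------------------------------------------------------
# experiment grid

@dataclass
class SimulatedExperiment:
    """One synthetic dataset: reads, input trace, truth intervals, metadata."""

    name: str
    reads: AlignedReadSet
    trace: Electropherogram
    truth: IntervalSet
    sites: list[TruthSite]
    genome: SimGenome
    metadata: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(outdir / "genome.fa")
        self.reads.to_sam(outdir / "reads.sam")
        self.truth.to_bed(outdir / "truth.bed")
        self.trace.to_csv(outdir / "trace.csv")
        (outdir / "metadata.json").write_text(json.dumps(self.metadata, indent=2))


GRID_DEFAULTS = dict(
    genome_length=1_000_000,
    gc_fraction=0.45,
    n_direct=100,
    n_indirect=60,
    strength=1.0,
    n_reads=30_000,
    read_len=36,
    background_fraction=0.9,
    frag_cv=0.25,          # lognormal sd = frag_cv * mean
    n_input_fragments=50_000,
    # truth windows comparable to a called-peak width: wide enough that reads
    # from long (but efficiently pulled-down) fragments still overlap them
    truth_halfwidth=250,
)


def _factor_model(profile) -> IPEfficiencyModel:
    if isinstance(profile, IPEfficiencyModel):
        return profile
    key = str(profile).lower().replace("_", "-")
    if key.startswith("ctcf"):
        return IPEfficiencyModel.ctcf_like()
    if key.startswith("tal1"):
        return IPEfficiencyModel.tal1_like()
    if key in ("ideal", "none", "no-occlusion"):
        return IPEfficiencyModel.no_occlusion()
    raise ValueError(f"unknown factor profile {profile!r}")


def simulate_experiment_grid(
    config: pd.DataFrame | Iterable[Mapping],
    motif: PWMotif,
    seed: int = 0,
    sonication_model: SonicationModel | None = None,
    **defaults,
) -> list[SimulatedExperiment]:
    """One complete synthetic dataset per scenario row.

    Each row must provide a ``factor`` profile and either ``mean_frag_len``
    directly or ``cycles`` (+ optional ``n_cells``), which are mapped through
    the sonication decay model.  All rows share one genome and truth-site set
    (so scenarios differ only in shearing and replicate seed); row-level keys
    override the module-level GRID_DEFAULTS.
    """
    if isinstance(config, pd.DataFrame):
        rows = config.to_dict("records")
    else:
        rows = [dict(r) for r in config]
    if not rows:
        raise ValueError("empty scenario table")
    base = dict(GRID_DEFAULTS)
    base.update(defaults)
    sonication_model = sonication_model or SonicationModel()
    genome = simulate_genome(base["genome_length"], base["gc_fraction"],
                             seed=np.random.SeedSequence([seed, 0]).generate_state(1)[0] % (2**31))
    sites = place_sites(
        genome, motif, base["n_direct"], base["n_indirect"],
        strengths=base["strength"],
        seed=int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31)),
    )
    truth = truth_intervals(sites, genome, halfwidth=base["truth_halfwidth"])
    out = []
    for i, row in enumerate(rows):
        params = dict(base)
        params.update({k: v for k, v in row.items() if v is not None})
        if "mean_frag_len" in params and params.get("mean_frag_len") is not None:
            mean_len = float(params["mean_frag_len"])
        elif "cycles" in params:
            mean_len = sonication_model.predict(
                float(params["cycles"]), params.get("n_cells")
            )
        else:
            raise ValueError(f"scenario row {i} needs 'mean_frag_len' or 'cycles'")
        frag_sd = float(params.get("frag_sd") or params["frag_cv"] * mean_len)
        ip_model = _factor_model(params.get("factor", "TAL1-like"))
        sub = np.random.SeedSequence([seed, 2, i]).generate_state(2) % (2**31)
        reads = simulate_chip_reads(
            genome, sites, ip_model,
            mean_frag_len=mean_len, frag_sd=frag_sd,
            n_reads=int(params["n_reads"]), read_len=int(params["read_len"]),
            background_fraction=float(params["background_fraction"]),
            seed=int(sub[0]),
        )
        input_lengths = draw_fragment_lengths(
            np.random.default_rng(int(sub[1])),
            int(params["n_input_fragments"]), mean_len, frag_sd,
        )
        trace = simulate_electropherogram(input_lengths, bin_width=10.0)
        name = str(row.get("name", f"scenario_{i}"))
        meta = {
            "name": name,
            "factor": ip_model.name,
            "mean_frag_len": mean_len,
            "frag_sd": frag_sd,
            "cycles": params.get("cycles"),
            "n_cells": params.get("n_cells"),
            "n_reads": int(params["n_reads"]),
            "read_len": int(params["read_len"]),
            "background_fraction": float(params["background_fraction"]),
            "n_direct": int(base["n_direct"]),
            "n_indirect": int(base["n_indirect"]),
            "genome_length": genome.length,
            "seed": seed,
            "row": i,
        }
        out.append(SimulatedExperiment(
            name=name, reads=reads, trace=trace, truth=truth,
            sites=sites, genome=genome, metadata=meta,
        ))
    return out
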