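"""Alignment-level ChIP-seq quality metrics.

Strand cross-correlation: in a successful ChIP, read 5' ends pile up on the
forward strand upstream of each bound site and on the reverse strand
downstream of it, so correlating the per-position forward and reverse 5'-end
count vectors as a function of a strand shift produces a peak at the typical
fragment length and a spurious "phantom" peak at the read length.  From the
profile cc(shift):

    NSC = cc(fragment_shift) / min(cc)
    RSC = (cc(fragment_shift) - min(cc)) / (cc(read_length) - min(cc))

with the fragment shift located as the argmax outside an exclusion zone of
read_length +- 10 bp (the background-subtracted RSC form is the standard
ENCODE definition; RSC > 0.8 marks a usable experiment and values around
1.5-2.5 typify clean transcription-factor data).

FRiP is the fraction of mapped reads overlapping a (merged) peak set by at
least 1 bp; FRiP-hc restricts the peak set to peaks that overlap a
high-confidence reference before counting.  A minimal Poisson sliding-window
peak caller is provided for synthetic end-to-end runs only — it makes no
claim to reproduce any production caller's output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import AlignedReadSet, IntervalSet

__all__ = [
    "CrossCorrelationProfile",
    "NSCResult",
    "OverlapResult",
    "read_alignments",
    "strand_cc_profile",
    "nsc_rsc",
    "frip",
    "overlap_peaks",
    "frip_hc",
    "call_peaks_simple",
]


def read_alignments(path: str | Path, drop_mito: bool = True,
                    drop_unplaced: bool = True) -> AlignedReadSet:
    """Load mapped reads from SAM/BAM, removing unmapped records always and
    mitochondrial / unplaced-contig records per config."""
    return AlignedReadSet.from_sam(path, drop_mito=drop_mito,
                                   drop_unplaced=drop_unplaced)


@dataclass
class CrossCorrelationProfile:
    shift: np.ndarray
    cc: np.ndarray
    read_length: int

    @property
    def cc_min(self) -> float:
        return float(np.min(self.cc))


@dataclass
class NSCResult:
    nsc: float
    rsc: float
    est_fragment_length: int
    phantom_shift: int
    cc_fragment: float
    cc_phantom: float
    cc_min: float
    diagnostics: list[str] = field(default_factory=list)


def strand_cc_profile(reads: AlignedReadSet, max_shift: int = 400) -> CrossCorrelationProfile:
    """Pearson correlation of forward vs d-shifted reverse 5'-end counts.

    Computed per chromosome over dense position vectors (positions beyond
    chromosome end minus shift are excluded, never paired across
    chromosomes) and pooled by summing sufficient statistics.
    """
    if not reads.chrom_sizes:
        raise ValueError("chrom_sizes required for the cross-correlation")
    fwd = reads.strand == "+"
    if fwd.all() or (~fwd).all():
        raise ValueError("both strands are required for a cross-correlation")
    shifts = np.arange(0, max_shift + 1)
    n = np.zeros(len(shifts))
    sx = np.zeros(len(shifts))
    sy = np.zeros(len(shifts))
    sxx = np.zeros(len(shifts))
    syy = np.zeros(len(shifts))
    sxy = np.zeros(len(shifts))
    five = reads.five_prime()
    seen = 0
    for chrom, size in reads.chrom_sizes.items():
        on = reads.chrom == chrom
        if not on.any():
            continue
        seen += int(on.sum())
        f = np.bincount(five[on & fwd], minlength=size).astype(float)
        r = np.bincount(five[on & ~fwd], minlength=size).astype(float)
        if len(f) > size or len(r) > size:
            raise ValueError(f"read 5' end beyond chromosome {chrom} bounds")
        cf, cr = np.concatenate([[0], f.cumsum()]), np.concatenate([[0], r.cumsum()])
        cf2, cr2 = np.concatenate([[0], (f * f).cumsum()]), np.concatenate([[0], (r * r).cumsum()])
        for j, d in enumerate(shifts):
            m = size - d
            if m < 2:
                continue
            n[j] += m
            sx[j] += cf[m]
            sxx[j] += cf2[m]
            sy[j] += cr[size] - cr[d]
            syy[j] += cr2[size] - cr2[d]
            sxy[j] += float(np.dot(f[:m], r[d:]))
    if seen != len(reads):
        raise ValueError("some reads map to chromosomes absent from chrom_sizes")
    var_x = sxx - sx * sx / n
    var_y = syy - sy * sy / n
    if (var_x <= 0).any() or (var_y <= 0).any():
        raise ValueError("zero-variance strand count vector at some shift")
    cc = (sxy - sx * sy / n) / np.sqrt(var_x * var_y)
    return CrossCorrelationProfile(shift=shifts, cc=cc, read_length=reads.read_length)


def _smooth(cc: np.ndarray, bandwidth: int) -> np.ndarray:
    """Hann-kernel smoothing with edge renormalisation; identity for
    bandwidth < 3."""
    if bandwidth < 3:
        return cc
    kernel = np.hanning(bandwidth + 2)[1:-1]
    kernel /= kernel.sum()
    return np.convolve(cc, kernel, mode="same") / np.convolve(
        np.ones_like(cc), kernel, mode="same"
    )


def nsc_rsc(profile: CrossCorrelationProfile,
            exclusion_halfwidth: int = 10,
            smoothing_bandwidth: int = 21) -> NSCResult:
    """NSC, RSC and the fragment-length estimate from a cc profile.

    Peak locations (fragment peak outside the phantom exclusion zone
    read_length +- exclusion_halfwidth; phantom peak inside it) are found on
    a Hann-smoothed profile so a single noisy shift cannot displace the
    fragment-length estimate; the reported cc values are read from the raw
    profile at the located shifts.  An undefined RSC (phantom denominator
    <= 0) is reported as NaN with a diagnostic rather than an error.
    """
    zone = np.abs(profile.shift - profile.read_length) <= exclusion_halfwidth
    if not zone.any():
        raise ValueError("profile does not cover the read-length phantom zone")
    if zone.all():
        raise ValueError("exclusion zone covers the whole profile")
    diagnostics: list[str] = []
    cc = profile.cc
    smoothed = _smooth(cc, smoothing_bandwidth)
    out_idx = np.flatnonzero(~zone)
    frag_i = out_idx[np.argmax(smoothed[out_idx])]
    in_idx = np.flatnonzero(zone)
    ph_i = in_idx[np.argmax(smoothed[in_idx])]
    cc_min = float(cc.min())
    cc_frag = float(cc[frag_i])
    cc_ph = float(cc[ph_i])
    nsc = cc_frag / cc_min if cc_min > 0 else math.nan
    if cc_min <= 0:
        diagnostics.append("cc_min <= 0: NSC undefined")
    denom = cc_ph - cc_min
    if denom > 0:
        rsc = (cc_frag - cc_min) / denom
    else:
        rsc = math.nan
        diagnostics.append("phantom peak does not exceed cc_min: RSC undefined")
    return NSCResult(
        nsc=nsc, rsc=rsc,
        est_fragment_length=int(profile.shift[frag_i]),
        phantom_shift=int(profile.shift[ph_i]),
        cc_fragment=cc_frag, cc_phantom=cc_ph, cc_min=cc_min,
        diagnostics=diagnostics,
    )


def frip(reads: AlignedReadSet, peaks: IntervalSet, rule: str = "overlap") -> float:
    """Fraction of mapped reads in peaks.

    ``rule="overlap"``: a read counts if its full interval overlaps a merged
    peak by >= 1 bp (common FRiP convention); ``rule="five_prime"`` requires
    the 5' end itself to fall inside a peak.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    if len(peaks) == 0:
        return 0.0
    lookup = peaks._merged_lookup()
    hits = 0
    if rule == "overlap":
        starts, ends = reads.start, reads.end
    elif rule == "five_prime":
        starts = reads.five_prime()
        ends = starts + 1
    else:
        raise ValueError(f"unknown FRiP rule {rule!r}")
    for chrom, (ms, me) in lookup.items():
        on = reads.chrom == chrom
        if not on.any():
            continue
        from .core import _any_overlap

        hits += int(_any_overlap(starts[on], ends[on], ms, me).sum())
    return hits / reads.total_mapped


@dataclass
class OverlapResult:
    intervals: IntervalSet
    fraction: float  # |result| / |a|; NaN when a is empty


def overlap_peaks(a: IntervalSet, b: IntervalSet) -> OverlapResult:
    """Subset of a's intervals having >= 1 bp overlap with any interval of b
    (the "overlapped-hc" set when b is a high-confidence reference)."""
    if len(a) == 0:
        return OverlapResult(intervals=a, fraction=math.nan)
    mask = a.overlaps(b)
    return OverlapResult(intervals=a.subset(mask), fraction=float(mask.mean()))


def frip_hc(reads: AlignedReadSet, peaks: IntervalSet, hc: IntervalSet,
            rule: str = "overlap") -> float:
    """FRiP over only the dataset's peaks that overlap the high-confidence
    reference set."""
    return frip(reads, overlap_peaks(peaks, hc).intervals, rule=rule)


def call_peaks_simple(
    reads: AlignedReadSet,
    control: AlignedReadSet | None = None,
    window: int = 200,
    fdr_like_threshold: float = 1e-5,
    fragment_length: int = 200,
) -> IntervalSet:
    """Poisson sliding-window caller for synthetic end-to-end runs.

    Estimated fragment centres (5' ends shifted inward by half the fragment
    length) are counted in non-overlapping windows; each window is tested
    against Poisson(lambda_local), lambda_local = max(genome-wide rate,
    depth-scaled control rate), and adjacent significant windows are merged.
    Scores are -log10 p of the most significant constituent window.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    if not reads.chrom_sizes:
        raise ValueError("chrom_sizes required to tile windows")
    if window > max(reads.chrom_sizes.values()):
        raise ValueError("window larger than every chromosome")
    half = fragment_length // 2
    five = reads.five_prime()
    centers = np.where(reads.strand == "+", five + half, five - half)
    genome_total = sum(reads.chrom_sizes.values())
    lam_global = len(reads) * window / genome_total
    scale = len(reads) / len(control) if control is not None and len(control) else 1.0
    rows = []
    for chrom, size in sorted(reads.chrom_sizes.items()):
        on = reads.chrom == chrom
        if not on.any():
            continue
        nw = math.ceil(size / window)
        c = np.clip(centers[on], 0, size - 1)
        counts = np.bincount(c // window, minlength=nw)
        lam = np.full(nw, lam_global)
        if control is not None and len(control):
            c_on = control.chrom == chrom
            cc = np.clip(
                np.where(control.strand[c_on] == "+",
                         control.five_prime()[c_on] + half,
                         control.five_prime()[c_on] - half),
                0, size - 1,
            )
            ctrl_counts = np.bincount(cc // window, minlength=nw) * scale
            lam = np.maximum(lam, ctrl_counts)
        pvals = stats.poisson.sf(counts - 1, lam)
        sig = pvals <= fdr_like_threshold
        i = 0
        while i < nw:
            if sig[i]:
                j = i
                while j + 1 < nw and sig[j + 1]:
                    j += 1
                best = float(pvals[i : j + 1].min())
                rows.append((chrom, i * window, min((j + 1) * window, size),
                             -math.log10(max(best, 1e-300))))
                i = j + 1
            else:
                i += 1
    if not rows:
        import pandas as pd

        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name", "score"]))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    df["name"] = [f"peak_{i}" for i in range(len(df))]
    return IntervalSet(df)
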