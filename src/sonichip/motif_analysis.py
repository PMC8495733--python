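"""PWM motif scanning with exact p-value score thresholds.

Peaks are classified as direct (>= 1 significant motif match anywhere in the
peak sequence, either strand) or indirect (no match), mirroring the common
FIMO-style analysis at a per-position p-value cutoff (default 1e-4) with no
multiple-testing correction across positions.

Scoring is the standard log2 likelihood ratio against a 0-order background.
The score -> p-value map is computed exactly by dynamic programming over a
floor-quantised integer score grid (default 10^4 bins over the total score
range).  The scanner evaluates candidate words on the *same* grid, so the
per-position type-I error of a threshold at level alpha is exactly
P(Q >= T) <= alpha — quantisation can never make the test anti-conservative.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import IntervalSet

__all__ = [
    "BackgroundModel",
    "PWMotif",
    "ScoreMatrix",
    "ScoreThreshold",
    "MotifHit",
    "MotifSplit",
    "parse_motif",
    "parse_motifs",
    "log_odds",
    "pvalue_threshold",
    "scan_sequence",
    "peak_motif_fraction",
]

DNA = "ACGT"
_CODE = {c: i for i, c in enumerate(DNA)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
DEFAULT_BINS = 10_000


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background nucleotide probabilities (A, C, G, T)."""

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities")
        if (p <= 0).any():
            raise ValueError("background probabilities must all be > 0")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("background probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def from_sequences(cls, seqs: Sequence[str], pseudocount: float = 1.0) -> "BackgroundModel":
        counts = np.full(4, pseudocount, dtype=float)
        for seq in seqs:
            for i, base in enumerate(DNA):
                counts[i] += seq.upper().count(base)
        return cls(tuple(counts / counts.sum()))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass
class PWMotif:
    """Per-position nucleotide probability matrix (width x ACGT)."""

    name: str
    probs: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = 1e-4

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a (width, 4) matrix with width >= 1")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position's probabilities must sum to 1 (+-1e-6)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls, name: str, counts, pseudocount: float = 1e-4
    ) -> "PWMotif":
        """Counts -> probabilities with a pseudocount of
        ``pseudocount * column_total`` spread uniformly over the 4 bases."""
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        totals = counts.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("every position needs a positive count total")
        eps = pseudocount * totals
        probs = (counts + eps / 4.0) / (totals + eps)
        return cls(name=name, probs=probs, counts=counts, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# parsing

def _parse_pcm_text(text: str, pseudocount: float) -> list[PWMotif]:
    motifs, name, rows = [], None, []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no count rows")
            motifs.append(PWMotif.from_counts(name, np.array(rows, float), pseudocount))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].strip() or "motif", []
        else:
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise ValueError(f"expected 4 columns per position, got {line!r}")
            rows.append([float(p) for p in parts])
    flush()
    if name is None and rows:
        motifs.append(PWMotif.from_counts("motif", np.array(rows, float), pseudocount))
    if not motifs:
        raise ValueError("no motifs found in PCM text")
    return motifs


def _parse_meme_text(text: str) -> list[PWMotif]:
    from Bio import motifs as bio_motifs

    parsed = bio_motifs.parse(io.StringIO(text), "minimal")
    out = []
    for m in parsed:
        probs = np.array([[m.pwm[b][i] for b in DNA] for i in range(m.length)])
        probs = probs / probs.sum(axis=1, keepdims=True)
        out.append(PWMotif(name=m.name or "motif", probs=probs))
    if not out:
        raise ValueError("no motifs found in MEME text")
    return out


def parse_motifs(path: str | Path, pseudocount: float = 1e-4) -> list[PWMotif]:
    """Parse all motifs from a HOCOMOCO PCM/PWM-style or MEME-format file."""
    text = Path(path).read_text()
    if "letter-probability matrix" in text or "MEME version" in text:
        return _parse_meme_text(text)
    return _parse_pcm_text(text, pseudocount)


def parse_motif(path: str | Path, pseudocount: float = 1e-4) -> PWMotif:
    """Parse the first motif of a recognised motif file."""
    return parse_motifs(path, pseudocount)[0]


# ---------------------------------------------------------------------------
# scoring

@dataclass
class ScoreMatrix:
    """Log2-odds score matrix with its quantisation grid.

    Entries are log2(p_ib / bg_b); zero probabilities with zero pseudocount
    yield -inf entries, which are flagged and can never contribute a hit.
    """

    values: np.ndarray
    background: BackgroundModel
    motif_name: str = "motif"
    n_bins: int = DEFAULT_BINS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size == 0:
            raise ValueError("score matrix has no finite entries")

    @property
    def width(self) -> int:
        return self.values.shape[0]

    @property
    def has_neg_inf(self) -> bool:
        return bool(np.isneginf(self.values).any())

    @property
    def delta(self) -> float:
        """Quantisation step: total score range / n_bins."""
        vals = np.where(np.isfinite(self.values), self.values, np.nan)
        lo = np.nansum(np.nanmin(vals, axis=1))
        hi = np.nansum(np.nanmax(vals, axis=1))
        rng = hi - lo
        return rng / self.n_bins if rng > 0 else 1.0

    def quantised(self) -> np.ndarray:
        """Floor-quantised integer score matrix; -inf entries map to a
        sentinel low enough that any word containing one can never reach a
        finite threshold."""
        d = self.delta
        q = np.full(self.values.shape, np.iinfo(np.int64).min // (4 * self.width), dtype=np.int64)
        finite = np.isfinite(self.values)
        q[finite] = np.floor(self.values[finite] / d).astype(np.int64)
        return q


def log_odds(motif: PWMotif, bg: BackgroundModel | None = None, n_bins: int = DEFAULT_BINS) -> ScoreMatrix:
    """log2(p/bg) score matrix for the motif against a 0-order background."""
    if bg is None:
        bg = BackgroundModel.uniform()
    with np.errstate(divide="ignore"):
        values = np.log2(motif.probs / bg.array[None, :])
    return ScoreMatrix(values=values, background=bg, motif_name=motif.name, n_bins=n_bins)


@dataclass
class ScoreThreshold:
    """Score cutoff with its exact null distribution on the quantised grid."""

    alpha: float
    delta: float
    attainable: bool
    qscore: int | None = None          # integer-grid threshold
    p_attained: float | None = None    # exact P(Q >= qscore)
    qmin: int = 0
    tail: np.ndarray | None = None     # P(Q >= qmin + i) for the finite part

    @property
    def score(self) -> float:
        """Threshold on the (quantised) log2-odds scale."""
        if self.qscore is None:
            return math.inf
        return self.qscore * self.delta

    def pvalue(self, qtotal: int) -> float:
        """Exact p-value of a quantised word score under the background."""
        if self.tail is None:
            return math.nan
        i = qtotal - self.qmin
        if i < 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])


def _null_pmf(q: np.ndarray, values: np.ndarray, bg: np.ndarray):
    """Exact pmf of the quantised total score of a bg-i.i.d. word.

    Positions with -inf entries contribute only through their finite bases;
    the lost ("dead word") mass can never reach a finite threshold.  Returns
    (pmf, qmin) for the finite part; pmf may sum to < 1 when -inf entries
    exist.
    """
    finite = np.isfinite(values)
    pmf = np.array([1.0])
    qmin = 0
    for i in range(values.shape[0]):
        idx = np.flatnonzero(finite[i])
        if idx.size == 0:
            return np.zeros(1), 0  # every word is dead
        qi = q[i, idx]
        pi = bg[idx]
        lo, hi = qi.min(), qi.max()
        row = np.zeros(hi - lo + 1)
        np.add.at(row, qi - lo, pi)
        pmf = np.convolve(pmf, row)
        qmin += lo
    return pmf, qmin


def pvalue_threshold(
    scores: ScoreMatrix, alpha: float, bg: BackgroundModel | None = None
) -> ScoreThreshold:
    """Smallest quantised score T with exact null P(Q >= T) <= alpha.

    ``bg`` defaults to the background the matrix was built against.  When even
    the maximum score has tail probability > alpha the threshold is flagged
    unattainable and scans report zero hits.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    bg = scores.background if bg is None else bg
    q = scores.quantised()
    pmf, qmin = _null_pmf(q, scores.values, bg.array)
    tail = np.cumsum(pmf[::-1])[::-1]
    d = scores.delta
    hit = np.flatnonzero(tail <= alpha)
    if hit.size == 0:
        return ScoreThreshold(alpha=alpha, delta=d, attainable=False,
                              qmin=qmin, tail=tail)
    i = int(hit[0])
    return ScoreThreshold(
        alpha=alpha, delta=d, attainable=True, qscore=qmin + i,
        p_attained=float(tail[i]), qmin=qmin, tail=tail,
    )


@dataclass
class MotifHit:
    seq_id: str | None
    offset: int          # 0-based, forward-strand coordinates of the match start
    strand: str          # '+' or '-'
    score: float         # log2-odds on the quantised grid
    pvalue: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _CODE.items():
        code[arr == ord(base)] = i
    return code


def _window_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Quantised total score at each offset; windows touching an ambiguous
    base (N) score minus infinity (sentinel)."""
    w = q.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    sentinel = np.iinfo(np.int64).min // (4 * w)
    totals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(w):
        c = codes[i : i + n]
        valid = c >= 0
        ok &= valid
        totals += np.where(valid, q[i, np.clip(c, 0, 3)], 0)
    totals[~ok] = sentinel
    return totals


def scan_sequence(
    seq: str,
    scores: ScoreMatrix,
    threshold: ScoreThreshold,
    seq_id: str | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All offsets (both strands) whose quantised score reaches the threshold.

    Hit offsets are reported in forward-strand coordinates of the match start;
    a minus-strand hit at reverse-complement offset j maps to L - w - j.
    """
    if not threshold.attainable:
        return []
    w = scores.width
    L = len(seq)
    if L < w:
        return []
    q = scores.quantised()
    d = scores.delta
    hits: list[MotifHit] = []
    codes = _encode(seq)

    def collect(totals: np.ndarray, strand: str):
        for j in np.flatnonzero(totals >= threshold.qscore):
            off = int(j) if strand == "+" else L - w - int(j)
            hits.append(
                MotifHit(
                    seq_id=seq_id, offset=off, strand=strand,
                    score=float(totals[j] * d),
                    pvalue=threshold.pvalue(int(totals[j])),
                )
            )

    collect(_window_scores(codes, q), "+")
    if both_strands:
        rc = np.where(codes >= 0, 3 - codes, -1)[::-1]
        collect(_window_scores(rc, q), "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# peak classification

def _sequence_source(genome):
    """Accept a dict name->seq, a SimGenome, a pyfaidx.Fasta, or a FASTA path."""
    if isinstance(genome, Mapping):
        return lambda c: str(genome[c]), lambda c: len(genome[c])
    if hasattr(genome, "sequence") and hasattr(genome, "name"):  # SimGenome
        return (
            lambda c, g=genome: _named_seq(g, c),
            lambda c, g=genome: len(_named_seq(g, c)),
        )
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        return lambda c: str(fa[c][:]), lambda c: len(fa[c])
    # pyfaidx.Fasta or similar indexable
    return lambda c: str(genome[c][:]), lambda c: len(genome[c])


def _named_seq(sim_genome, chrom: str) -> str:
    if chrom != sim_genome.name:
        raise KeyError(f"chromosome {chrom!r} not in genome {sim_genome.name!r}")
    return sim_genome.sequence


@dataclass
class MotifSplit:
    """Partition of a peak set into with-motif / without-motif classes."""

    with_motif: IntervalSet
    without_motif: IntervalSet
    fraction: float
    alpha: float
    threshold: ScoreThreshold
    hits: list[MotifHit] = field(default_factory=list)

    @property
    def n_with(self) -> int:
        return len(self.with_motif)

    @property
    def n_without(self) -> int:
        return len(self.without_motif)


def peak_motif_fraction(
    peaks: IntervalSet,
    genome,
    motif: PWMotif,
    bg: BackgroundModel | None = None,
    alpha: float = 1e-4,
    n_bins: int = DEFAULT_BINS,
    collect_hits: bool = False,
) -> MotifSplit:
    """Classify every peak by presence of >= 1 significant motif match.

    The partition is exhaustive and disjoint; ``fraction`` is the share of
    peaks in the with-motif class.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    bg = bg or BackgroundModel.uniform()
    scores = log_odds(motif, bg, n_bins=n_bins)
    thr = pvalue_threshold(scores, alpha)
    get_seq, get_len = _sequence_source(genome)
    has = np.zeros(len(peaks), dtype=bool)
    all_hits: list[MotifHit] = []
    for i, row in enumerate(peaks.df.itertuples(index=False)):
        clen = get_len(row.chrom)
        if row.end > clen:
            raise ValueError(
                f"peak {row.name} [{row.start},{row.end}) beyond end of {row.chrom} ({clen} bp)"
            )
        seq = get_seq(row.chrom)[row.start : row.end]
        hits = scan_sequence(seq, scores, thr, seq_id=str(row.name))
        has[i] = bool(hits)
        if collect_hits:
            all_hits.extend(hits)
    return MotifSplit(
        with_motif=peaks.subset(has),
        without_motif=peaks.subset(~has),
        fraction=float(has.mean()),
        alpha=alpha,
        threshold=thr,
        hits=all_hits,
    )
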