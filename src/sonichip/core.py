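"""Core genomic containers shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; SAM output converts
to 1-based on write per the format standard.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = ["IntervalSet", "AlignedReadSet"]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]

#: chromosome names dropped by default when reading alignments (mitochondrial
#: genome plus anything that looks like an unplaced/alternate contig).
MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})


def _is_unplaced(name: str) -> bool:
    return "_" in name or name.startswith(("chrUn", "Un"))


class IntervalSet:
    """Named genomic intervals (peaks, truth sites) with overlap algebra.

    Backed by a DataFrame with columns chrom, start, end, name, score.
    Intervals are 0-based half-open; disjointness is not required (use
    :meth:`merge`).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col, default in (("name", None), ("score", 0.0)):
            if col not in df.columns:
                df[col] = default
        anon = df["name"].isna() | (df["name"] == ".")
        if anon.any():
            df.loc[anon, "name"] = [f"iv_{i}" for i in np.flatnonzero(anon.to_numpy())]
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"missing interval columns: {sorted(missing)}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("intervals must satisfy start < end")
        self.df = df

    # -- construction -------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str] | str,
        start: Sequence[int],
        end: Sequence[int],
        name: Sequence[str] | None = None,
        score: Sequence[float] | float = 0.0,
    ) -> "IntervalSet":
        start = np.asarray(start, dtype=np.int64)
        if isinstance(chrom, str):
            chrom = np.full(len(start), chrom, dtype=object)
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "start": start,
                "end": np.asarray(end, dtype=np.int64),
                "name": (
                    [f"iv_{i}" for i in range(len(start))] if name is None else list(name)
                ),
                "score": score,
            }
        )
        return cls(df)

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        """Read BED3+/BED6/ENCODE narrowPeak.  Column 10 (summit offset) of a
        narrowPeak file is kept as a ``summit`` column when present."""
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        ncol = raw.shape[1]
        names = _BED_COLS[: min(ncol, 6)] + [f"col{i}" for i in range(6, ncol)]
        raw.columns = names
        if ncol >= 10:  # narrowPeak: signalValue, pValue, qValue, peak(summit)
            raw = raw.rename(columns={"col9": "summit"})
        keep = [c for c in ("chrom", "start", "end", "name", "score", "strand", "summit") if c in raw.columns]
        return cls(raw[keep])

    def to_bed(self, path: str | Path) -> None:
        out = self.df.copy()
        out["score"] = out["score"].fillna(0)
        out[["chrom", "start", "end", "name", "score"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    # -- basics -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def total_length(self) -> int:
        m = self.merge().df
        return int((m["end"] - m["start"]).sum())

    def sort(self) -> "IntervalSet":
        df = self.df.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
        return IntervalSet(df)

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self.df.loc[np.asarray(mask, dtype=bool)])

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(pd.concat([self.df, other.df], ignore_index=True))

    # -- overlap algebra ----------------------------------------------------
    def merge(self) -> "IntervalSet":
        """Collapse overlapping/adjacent-with-overlap intervals per chromosome."""
        rows = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s < cur_e:  # strict: touching intervals stay separate
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        if not rows:
            return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"] = [f"merged_{i}" for i in range(len(df))]
        df["score"] = 0.0
        return IntervalSet(df)

    def _merged_lookup(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        m = self.merge().df
        return {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in m.groupby("chrom")
        }

    def overlaps(self, other: "IntervalSet") -> np.ndarray:
        """Boolean mask over self's rows: has >=1 bp overlap with any interval
        of *other* (half-open semantics)."""
        lookup = other._merged_lookup()
        mask = np.zeros(len(self), dtype=bool)
        for chrom, sub in self.df.groupby("chrom"):
            if chrom not in lookup:
                continue
            ms, me = lookup[chrom]
            mask[sub.index.to_numpy()] = _any_overlap(
                sub["start"].to_numpy(), sub["end"].to_numpy(), ms, me
            )
        return mask


def _any_overlap(
    starts: np.ndarray, ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Vectorised: does [start, end) overlap any of the sorted disjoint
    [m_start, m_end) intervals by >= 1 bp?"""
    if len(m_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    # first candidate whose end is > start
    idx = np.searchsorted(m_ends, starts, side="right")
    ok = idx < len(m_starts)
    out = np.zeros(len(starts), dtype=bool)
    out[ok] = m_starts[idx[ok]] < ends[ok]
    return out


@dataclass
class AlignedReadSet:
    """Mapped single-end reads: chromosome, 0-based start, length, strand."""

    chrom: np.ndarray
    start: np.ndarray
    length: np.ndarray
    strand: np.ndarray  # '+' / '-'
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="U1")
        n = len(self.start)
        if not (len(self.chrom) == len(self.length) == len(self.strand) == n):
            raise ValueError("read field arrays must have equal length")
        if n and (self.start < 0).any():
            raise ValueError("read starts must be >= 0")
        if n and (self.length <= 0).any():
            raise ValueError("read lengths must be > 0")
        if n and not np.isin(self.strand, ["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def total_mapped(self) -> int:
        return len(self)

    @property
    def read_length(self) -> int:
        """Modal read length of the set."""
        if len(self) == 0:
            raise ValueError("empty read set has no read length")
        vals, counts = np.unique(self.length, return_counts=True)
        return int(vals[np.argmax(counts)])

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    def five_prime(self) -> np.ndarray:
        """0-based 5' end position of each read (end-1 for minus strand)."""
        pos = self.start.copy()
        rev = self.strand == "-"
        pos[rev] = self.end[rev] - 1
        return pos

    def subset(self, mask: np.ndarray) -> "AlignedReadSet":
        mask = np.asarray(mask, dtype=bool)
        return AlignedReadSet(
            self.chrom[mask], self.start[mask], self.length[mask], self.strand[mask],
            dict(self.chrom_sizes),
        )

    # -- SAM I/O ------------------------------------------------------------
    @classmethod
    def from_sam(
        cls,
        path: str | Path,
        drop_mito: bool = True,
        drop_unplaced: bool = True,
    ) -> "AlignedReadSet":
        """Load mapped reads from SAM/BAM, filtering mitochondrial and
        unplaced-contig records per config, and unmapped records always."""
        chroms, starts, lengths, strands = [], [], [], []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            chrom_sizes = dict(zip(fh.references, fh.lengths))
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                ref = rec.reference_name
                if drop_mito and ref in MITO_NAMES:
                    continue
                if drop_unplaced and _is_unplaced(ref):
                    continue
                chroms.append(ref)
                starts.append(rec.reference_start)
                lengths.append(rec.reference_length or rec.query_length)
                strands.append("-" if rec.is_reverse else "+")
        if drop_mito:
            chrom_sizes = {c: l for c, l in chrom_sizes.items() if c not in MITO_NAMES}
        if drop_unplaced:
            chrom_sizes = {c: l for c, l in chrom_sizes.items() if not _is_unplaced(c)}
        if not chroms:
            raise ValueError(f"no reads remain after filtering: {path}")
        return cls(chroms, starts, lengths, strands, chrom_sizes)

    def to_sam(self, path: str | Path) -> None:
        """Write coordinate-sorted SAM (flag 0/16, CIGAR = full-length match)."""
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes required to write SAM")
        order = np.lexsort((self.start, self.chrom.astype(str)))
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(self.chrom_sizes.items())],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            tid = {c: i for i, c in enumerate(sorted(self.chrom_sizes))}
            for j, i in enumerate(order):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read_{j}"
                a.reference_id = tid[self.chrom[i]]
                a.reference_start = int(self.start[i])
                a.mapping_quality = 60
                a.flag = 16 if self.strand[i] == "-" else 0
                a.cigarstring = f"{int(self.length[i])}M"
                a.query_sequence = None
                out.write(a)
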