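"""Peak-centred signal matrices, z-score normalisation, and metapeak output.

Each peak contributes one row: the window is the peak centre (interval
midpoint, or the summit when present and requested) extended ``flank`` bp in
each direction and cut into fixed-width bins; each cell holds the summed
read coverage (optionally fragment-extended reads) over the bin's positions.
Matrices are z-scored globally, aggregated into per-class mean profiles
(with/without motif), and rendered as row-sum-ordered heatmaps with a
bit-stable TSV companion.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlignedReadSet, IntervalSet

__all__ = [
    "SignalMatrix",
    "signal_matrix",
    "zscore_normalize",
    "aggregate_profile",
    "render_heatmap",
]


@dataclass
class SignalMatrix:
    """Rows = peak windows (centre +- flank), cols = bins of fixed width."""

    values: np.ndarray
    row_names: np.ndarray
    bin_width: int
    flank: int
    classes: np.ndarray | None = None   # per-row motif class, e.g. 'with'/'without'
    clipped: np.ndarray | None = None   # rows whose window ran off a chromosome end

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_names = np.asarray(self.row_names, dtype=object)
        if self.values.ndim != 2 or len(self.row_names) != self.values.shape[0]:
            raise ValueError("values must be 2-D with one row name per row")
        if not np.isfinite(self.values).all():
            raise ValueError("signal matrix must be finite")
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=object)
            if len(self.classes) != self.values.shape[0]:
                raise ValueError("one class label per row required")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def with_classes(self, classes) -> "SignalMatrix":
        return replace(self, classes=np.asarray(classes, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_names)
        df.columns = [f"bin_{i}" for i in range(self.n_bins)]
        if self.classes is not None:
            df.insert(0, "class", self.classes)
        return df


def _coverage(reads: AlignedReadSet, chrom: str, size: int,
              fragment_length: int | None) -> np.ndarray:
    """Per-position read coverage, with reads optionally extended from their
    5' end to the estimated fragment length."""
    on = reads.chrom == chrom
    delta = np.zeros(size + 1)
    if fragment_length is None:
        s = reads.start[on]
        e = reads.end[on]
    else:
        fwd = reads.strand[on] == "+"
        s = np.where(fwd, reads.start[on], reads.end[on] - fragment_length)
        e = s + fragment_length
    s = np.clip(s, 0, size)
    e = np.clip(e, 0, size)
    np.add.at(delta, s, 1.0)
    np.add.at(delta, e, -1.0)
    return np.cumsum(delta)[:-1]


def signal_matrix(
    reads: AlignedReadSet,
    peaks: IntervalSet,
    flank: int = 1000,
    bin_width: int = 10,
    fragment_length: int | None = None,
    use_summit: bool = False,
) -> SignalMatrix:
    """Build the peak-centred coverage matrix.

    Windows are [centre - flank, centre + flank) split into
    ceil(2*flank/bin_width) bins; windows clipped at a chromosome end are
    zero-padded and flagged in ``clipped``.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if flank < bin_width:
        raise ValueError("flank must be >= bin_width")
    n_bins = -(-2 * flank // bin_width)  # ceil
    span = n_bins * bin_width
    vals = np.zeros((len(peaks), n_bins))
    clipped = np.zeros(len(peaks), dtype=bool)
    names = peaks.df["name"].to_numpy(dtype=object)
    covs: dict[str, np.ndarray] = {}
    for chrom in peaks.df["chrom"].unique():
        size = reads.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"chromosome {chrom!r} absent from chrom_sizes")
        covs[chrom] = _coverage(reads, chrom, size, fragment_length)
    if use_summit and "summit" in peaks.df.columns:
        centers = (peaks.df["start"] + peaks.df["summit"]).to_numpy()
    else:
        centers = ((peaks.df["start"] + peaks.df["end"]) // 2).to_numpy()
    for i, (chrom, c) in enumerate(zip(peaks.df["chrom"], centers)):
        cov = covs[chrom]
        ws = int(c) - flank
        we = ws + span
        lo, hi = max(ws, 0), min(we, len(cov))
        if lo != ws or hi != we:
            clipped[i] = True
        padded = np.zeros(span)
        if hi > lo:
            padded[lo - ws : hi - ws] = cov[lo:hi]
        vals[i] = padded.reshape(n_bins, bin_width).sum(axis=1)
    return SignalMatrix(values=vals, row_names=names, bin_width=bin_width,
                        flank=flank, clipped=clipped)


def zscore_normalize(m: SignalMatrix, scope: str = "global") -> SignalMatrix:
    """(value - mean) / sd over the chosen scope ('global' over all cells, or
    'per_row')."""
    v = m.values
    if scope == "global":
        sd = v.std()
        if sd == 0:
            raise ValueError("zero variance: cannot z-score a constant matrix")
        out = (v - v.mean()) / sd
    elif scope == "per_row":
        sd = v.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("zero-variance row: cannot z-score per row")
        out = (v - v.mean(axis=1, keepdims=True)) / sd
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return replace(m, values=out)


def aggregate_profile(m: SignalMatrix, group_by=None) -> tuple[pd.DataFrame, dict]:
    """Per-class per-bin mean profile and class sizes.

    ``group_by`` defaults to the matrix's row classes; a single unlabelled
    class 'all' is used when neither is present.
    """
    labels = group_by if group_by is not None else m.classes
    if labels is None:
        labels = np.full(m.values.shape[0], "all", dtype=object)
    labels = np.asarray(labels, dtype=object)
    profiles = {}
    sizes = {}
    for cls in pd.unique(labels):
        rows = m.values[labels == cls]
        sizes[cls] = int(rows.shape[0])
        profiles[cls] = rows.mean(axis=0)
    df = pd.DataFrame(profiles).T
    df.columns = [f"bin_{i}" for i in range(m.n_bins)]
    return df, sizes


def render_heatmap(
    m: SignalMatrix,
    out_png: str | Path | None = None,
    out_tsv: str | Path | None = None,
    cmap: str = "Blues",
) -> SignalMatrix:
    """Order rows (within class) by decreasing total signal, ties broken by
    row name; write a bit-stable TSV and, optionally, a heatmap image."""
    rowsum = m.values.sum(axis=1)
    names = m.row_names.astype(str)
    cls = m.classes.astype(str) if m.classes is not None else np.full(len(names), "all")
    order = np.lexsort((names, -rowsum, cls))
    ordered = SignalMatrix(
        values=m.values[order],
        row_names=m.row_names[order],
        bin_width=m.bin_width,
        flank=m.flank,
        classes=None if m.classes is None else m.classes[order],
        clipped=None if m.clipped is None else m.clipped[order],
    )
    if out_tsv is not None:
        ordered.to_frame().to_csv(out_tsv, sep="\t", float_format="%.6g",
                                  index_label="region")
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(ordered.values, aspect="auto", interpolation="nearest",
                       cmap=cmap)
        ax.set_xlabel(f"bin ({m.bin_width} bp), centre +- {m.flank} bp")
        ax.set_ylabel("peak regions (ordered by total signal)")
        fig.colorbar(im, ax=ax, label="signal")
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return ordered
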