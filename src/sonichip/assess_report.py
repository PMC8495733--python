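"""Dataset assessment, size-binned group tests, and the study-style report.

The pass/low-pass/fail classifier codifies the metric ranges that accompany
each quality tier in sonication-controlled ChIP-seq of sequence-specific
factors: FRiP >= 1% is the gate between a usable and a failed
immunoprecipitation; RSC between 1.5 and 2.5 and an average input-chromatin
length of roughly 190-290 bp mark a fully clean experiment.  It is an
explicit heuristic — the underlying tiering of real datasets is a visual
call on signal tracks — so Pass/LowPass separate "all criteria in range"
from "FRiP acceptable but shearing or cross-correlation off-range", and
Fail is reserved for sub-1% FRiP.  POL2-like rules drop the RSC criterion
(no consistent RSC trend exists for that target) and only bound the
chromatin size from above.

Datasets are binned by average chromatin length (<200, 200-250, >250 bp for
CTCF/TAL1-like factors; <290, >=290 bp for POL2-like) and adjacent bins are
compared with the equal-variance two-sample Student's t-test on FRiP, raw
p-values, no multiple-testing correction.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCRecord",
    "AssessmentRule",
    "Assessment",
    "BinSpec",
    "BinTestResult",
    "assess",
    "bin_and_test",
    "build_report",
    "load_records",
]

LABELS = ("Pass", "LowPass", "Fail")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class QCRecord:
    """One dataset's metric bundle."""

    dataset_id: str
    frip: float | None = None                 # fraction, not percent
    frip_hc: float | None = None
    avg_chromatin_length: float | None = None
    nsc: float | None = None
    rsc: float | None = None
    est_fragment_length: float | None = None
    n_peaks: int | None = None
    motif_fraction: float | None = None
    assessment: str | None = None

    def __post_init__(self):
        for name in ("frip", "frip_hc"):
            v = getattr(self, name)
            if not _missing(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")


@dataclass(frozen=True)
class AssessmentRule:
    """Metric ranges associated with a Pass for one factor class."""

    factor_class: str = "TAL1-like"
    frip_min: float = 0.01
    rsc_range: tuple[float, float] | None = (1.5, 2.5)
    size_range: tuple[float, float] | None = (190.0, 290.0)

    def __post_init__(self):
        if not 0 < self.frip_min < 1:
            raise ValueError("frip_min must be in (0, 1)")
        for rng in (self.rsc_range, self.size_range):
            if rng is not None and not rng[0] < rng[1]:
                raise ValueError(f"empty range {rng}")

    @classmethod
    def for_factor(cls, factor_class: str) -> "AssessmentRule":
        key = factor_class.lower().replace("_", "-").replace("-like", "")
        if key in ("ctcf", "tal1"):
            return cls(factor_class=factor_class)
        if key == "pol2":
            # upper size bound only; RSC shows no consistent trend for POL2
            return cls(factor_class=factor_class, rsc_range=None,
                       size_range=(0.0, 290.0))
        raise ValueError(f"unknown factor class {factor_class!r}")


@dataclass
class Assessment:
    label: str
    reasons: list[str] = field(default_factory=list)


def assess(record: QCRecord, rule: AssessmentRule | None = None) -> Assessment:
    """Deterministic label: Fail when FRiP < frip_min; Pass when FRiP is
    acceptable and every available criterion is in range (missing rsc/size
    are skipped, noted in reasons); LowPass otherwise."""
    rule = rule or AssessmentRule()
    if _missing(record.frip):
        raise ValueError(f"record {record.dataset_id}: FRiP is required to assess")
    reasons: list[str] = []
    if record.frip < rule.frip_min:
        reasons.append(f"FRiP {100 * record.frip:.2f}% < {100 * rule.frip_min:.1f}%")
        return Assessment("Fail", reasons)
    reasons.append(f"FRiP {100 * record.frip:.2f}% >= {100 * rule.frip_min:.1f}%")
    ok = True
    if rule.rsc_range is not None:
        if _missing(record.rsc):
            reasons.append("RSC missing: criterion skipped")
        elif rule.rsc_range[0] <= record.rsc <= rule.rsc_range[1]:
            reasons.append(f"RSC {record.rsc:.2f} in range {rule.rsc_range}")
        else:
            ok = False
            reasons.append(f"RSC {record.rsc:.2f} out of range {rule.rsc_range}")
    if rule.size_range is not None:
        size = record.avg_chromatin_length
        if _missing(size):
            reasons.append("chromatin size missing: criterion skipped")
        elif rule.size_range[0] <= size <= rule.size_range[1]:
            reasons.append(f"size {size:.0f} bp in range {rule.size_range}")
        else:
            ok = False
            reasons.append(f"size {size:.0f} bp out of range {rule.size_range}")
    return Assessment("Pass" if ok else "LowPass", reasons)


@dataclass(frozen=True)
class BinSpec:
    """Chromatin-length bin edges for one factor class (left-closed bins)."""

    edges: tuple[float, ...]
    factor_class: str = "TAL1-like"

    def __post_init__(self):
        if len(self.edges) < 1 or not all(
            a < b for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("edges must be strictly increasing and non-empty")

    @classmethod
    def for_factor(cls, factor_class: str) -> "BinSpec":
        key = factor_class.lower().replace("_", "-").replace("-like", "")
        if key in ("ctcf", "tal1"):
            return cls(edges=(200.0, 250.0), factor_class=factor_class)
        if key == "pol2":
            return cls(edges=(290.0,), factor_class=factor_class)
        raise ValueError(f"unknown factor class {factor_class!r}")

    @property
    def labels(self) -> list[str]:
        e = [f"{v:g}" for v in self.edges]
        mids = [f"{a}-{b}" for a, b in zip(e, e[1:])]
        return [f"<{e[0]}", *mids, f">={e[-1]}"]

    def assign(self, size: float) -> str:
        i = int(np.searchsorted(np.asarray(self.edges), size, side="right"))
        return self.labels[i]


@dataclass
class BinTestResult:
    table: pd.DataFrame      # one row per record: dataset, size, metric, bin
    stats: pd.DataFrame      # per-bin n, mean, sd
    tests: pd.DataFrame      # pairwise t-tests: bin_a, bin_b, t, p
    excluded: list[str] = field(default_factory=list)


def bin_and_test(
    records: Sequence[QCRecord],
    bins: BinSpec,
    metric: str = "frip",
    adjacent_only: bool = True,
    equal_var: bool = True,
) -> BinTestResult:
    """Bin records by average chromatin length and t-test the metric between
    bins (adjacent pairs by default; Student's equal-variance form unless
    ``equal_var=False`` for Welch).  Bins with < 2 records are excluded from
    testing and reported."""
    rows = []
    for r in records:
        size = r.avg_chromatin_length
        value = getattr(r, metric)
        if _missing(size) or _missing(value):
            continue
        rows.append((r.dataset_id, size, value, bins.assign(size)))
    table = pd.DataFrame(rows, columns=["dataset", "avg_chromatin_length", metric, "bin"])
    stats_rows = []
    groups: dict[str, np.ndarray] = {}
    for label in bins.labels:
        vals = table.loc[table["bin"] == label, metric].to_numpy(dtype=float)
        groups[label] = vals
        stats_rows.append(
            {"bin": label, "n": len(vals),
             "mean": float(vals.mean()) if len(vals) else math.nan,
             "sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan}
        )
    excluded = [lbl for lbl, v in groups.items() if len(v) < 2]
    labels = bins.labels
    if adjacent_only:
        pairs = list(zip(labels, labels[1:]))
    else:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    test_rows = []
    for a, b in pairs:
        if a in excluded or b in excluded:
            continue
        va, vb = groups[a], groups[b]
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            # degenerate: no within-group variance
            if va.mean() == vb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, va.mean() - vb.mean()), 0.0
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        test_rows.append({"bin_a": a, "bin_b": b, "t": float(t), "p": float(p)})
    return BinTestResult(
        table=table,
        stats=pd.DataFrame(stats_rows),
        tests=pd.DataFrame(test_rows, columns=["bin_a", "bin_b", "t", "p"]),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# report bundle

_PCT_FIELDS = {"frip": "frip_pct", "frip_hc": "frip_hc_pct"}


def records_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    """QCRecords as a DataFrame with FRiP-like fields as percentages."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for frac, pct in _PCT_FIELDS.items():
            v = d.pop(frac)
            d[pct] = None if _missing(v) else 100.0 * v
        rows.append(d)
    return pd.DataFrame(rows)


def load_records(path: str | Path) -> list[QCRecord]:
    """Re-read a report TSV into QCRecord objects (percent back to fraction)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in dataclasses.fields(QCRecord):
            if f.name in _PCT_FIELDS:
                col = _PCT_FIELDS[f.name]
                v = row.get(col)
                kwargs[f.name] = None if _missing(v) else float(v) / 100.0
            elif f.name in df.columns:
                v = row[f.name]
                kwargs[f.name] = None if _missing(v) else v
        out.append(QCRecord(**kwargs))
    return out


def build_report(
    records: Sequence[QCRecord],
    outdir: str | Path,
    rule: AssessmentRule | None = None,
    bins: BinSpec | None = None,
    metric: str = "frip",
    figures: bool = True,
) -> dict:
    """Write the QC table (TSV), summary (JSON) and guideline figures.

    Returns a dict of output paths plus the assessed records frame under
    ``"frame"`` and the bin test result under ``"bin_test"``.
    """
    if not records:
        raise ValueError("need at least one record")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = list(records)
    if rule is not None:
        for r in records:
            r.assessment = assess(r, rule).label
    frame = records_frame(records)
    tsv = outdir / "qc_records.tsv"
    frame.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    summary: dict = {
        "n_records": len(records),
        "labels": {lbl: int((frame["assessment"] == lbl).sum()) for lbl in LABELS}
        if rule is not None
        else None,
    }
    bin_test = None
    if bins is not None:
        bin_test = bin_and_test(records, bins, metric=metric)
        summary["bins"] = bin_test.stats.to_dict("records")
        summary["tests"] = bin_test.tests.to_dict("records")
        bin_test.stats.to_csv(outdir / "bin_stats.tsv", sep="\t", index=False)
        bin_test.tests.to_csv(outdir / "bin_tests.tsv", sep="\t", index=False)
    js = outdir / "summary.json"
    js.write_text(json.dumps(summary, indent=2, default=float))
    paths = {"tsv": tsv, "json": js, "frame": frame, "bin_test": bin_test}
    if figures:
        paths["figures"] = _report_figures(frame, outdir)
    return paths


def _report_figures(frame: pd.DataFrame, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    sub = frame.dropna(subset=["avg_chromatin_length", "frip_pct"])
    if len(sub):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(sub["avg_chromatin_length"], sub["frip_pct"], s=18)
        ax.axhline(1.0, ls=":", color="gray", label="1% FRiP guideline")
        ax.set_xlabel("average chromatin length (bp)")
        ax.set_ylabel("FRiP (%)")
        ax.legend(frameon=False)
        p = outdir / "frip_vs_size.png"
        fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
        out.append(p)
    if frame["assessment"].notna().any():
        fig, ax = plt.subplots(figsize=(4, 4))
        for i, lbl in enumerate(LABELS):
            vals = frame.loc[frame["assessment"] == lbl, "frip_pct"].dropna()
            ax.scatter(np.full(len(vals), i), vals, s=18)
            if len(vals):
                ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="C3")
        ax.axhline(1.0, ls=":", color="gray")
        ax.set_xticks(range(len(LABELS)), LABELS)
        ax.set_ylabel("FRiP (%)")
        p = outdir / "frip_by_assessment.png"
        fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
        out.append(p)
    return out
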