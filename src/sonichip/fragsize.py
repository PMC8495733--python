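"""Chromatin fragment-size analysis from electropherogram traces.

An Agilent Bioanalyzer run of unenriched (input) chromatin yields a trace of
fluorescence intensity versus fragment size in bp.  The average chromatin
length is summarised over a fixed 100-500 bp window — restricting the window
standardises the measurement and keeps large heterochromatin from skewing the
average — as the intensity-weighted mean size.  Fluorescence is proportional
to DNA mass, so the default weighting is a mass-weighted average; a molar
weighting (intensity divided by size, proportional to molecule count) is
available via ``weighting="molar"``.

The module also fits the sonication decay law

    L(c) = Linf + A * exp(-k * c)

to (cycles, average length) calibration points, per cell-count group, and
inverts the fitted model to plan how many cycles reach a target size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Electropherogram",
    "SizeWindow",
    "SonicationModel",
    "GroupDecayFit",
    "DecayFit",
    "parse_trace",
    "average_fragment_length",
    "fit_decay",
    "cycles_for_target",
]


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive size window (bp) over which the average is computed."""

    lo: float = 100.0
    hi: float = 500.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got ({self.lo}, {self.hi})")


@dataclass
class Electropherogram:
    """A fragment-size trace: strictly increasing sizes (bp) with
    non-negative intensities."""

    size_bp: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.size_bp = np.asarray(self.size_bp, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size_bp.ndim != 1 or self.size_bp.shape != self.intensity.shape:
            raise ValueError("size_bp and intensity must be 1-D vectors of equal length")
        if len(self.size_bp) < 2:
            raise ValueError("a trace needs at least 2 points")
        if not (np.diff(self.size_bp) > 0).all():
            raise ValueError("size_bp must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"size_bp": self.size_bp, "intensity": self.intensity}).to_csv(
            path, index=False
        )


def parse_trace(
    path: str | Path,
    size_col: int = 0,
    intensity_col: int = 1,
    delimiter: str = ",",
    skip_header: int | str = "auto",
    sort: bool = False,
) -> Electropherogram:
    """Parse a two-column CSV electropherogram export.

    ``skip_header="auto"`` drops any leading lines that do not parse as
    numbers (instrument exports carry titles/units).  Non-monotone size rows
    raise unless ``sort=True``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            if isinstance(skip_header, int) and lineno < skip_header:
                continue
            parts = [p.strip() for p in line.strip().split(delimiter)]
            if len(parts) <= max(size_col, intensity_col):
                if skip_header == "auto" and not rows:
                    continue
                continue
            try:
                s = float(parts[size_col])
                i = float(parts[intensity_col])
            except ValueError:
                if skip_header == "auto" and not rows:
                    continue  # header junk before any numeric row
                raise ValueError(f"unparseable row {lineno} in {path!s}: {line!r}")
            rows.append((s, i))
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 usable rows in {path!s}")
    arr = np.array(rows, dtype=float)
    if sort:
        arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
    return Electropherogram(arr[:, 0], arr[:, 1])


def average_fragment_length(
    trace: Electropherogram,
    window: SizeWindow | tuple[float, float] | None = None,
    weighting: str = "intensity",
) -> float:
    """Weighted mean fragment size over the (inclusive) window.

    ``weighting="intensity"`` weights by the raw trace (fluorescence ~ mass);
    ``"molar"`` divides intensity by size first (~ molecule count), which
    recovers the arithmetic mean length of the underlying fragments.
    """
    if window is None:
        window = SizeWindow()
    elif not isinstance(window, SizeWindow):
        window = SizeWindow(*window)
    mask = (trace.size_bp >= window.lo) & (trace.size_bp <= window.hi)
    sizes = trace.size_bp[mask]
    if weighting == "intensity":
        w = trace.intensity[mask]
    elif weighting == "molar":
        w = trace.intensity[mask] / sizes
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    if not total > 0:
        raise ValueError("zero total intensity inside the size window")
    return float((sizes * w).sum() / total)


@dataclass(frozen=True)
class SonicationModel:
    """Exponential sonication decay of chromatin size with cycle number.

    Predicted average length after ``c`` cycles for ``n`` cells:

        L(c, n) = Linf + (L0 * g(n) - Linf) * exp(-k * c / g(n))

    where ``g(n) = (n / cells_ref) ** cell_factor`` is a monotone scaling;
    more cells mean a larger effective starting size and a slower effective
    decay, i.e. more cycles needed to reach a given size.
    """

    L0: float = 1500.0
    Linf: float = 150.0
    k: float = 0.15
    cell_factor: float = 0.25
    cells_ref: float = 20e6

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("decay rate k must be > 0")
        if self.Linf < 0 or self.L0 <= self.Linf:
            raise ValueError("require 0 <= Linf < L0")

    def cell_scale(self, n_cells: float | None) -> float:
        if n_cells is None:
            return 1.0
        if n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        return float((n_cells / self.cells_ref) ** self.cell_factor)

    def predict(self, cycles: float, n_cells: float | None = None) -> float:
        if cycles < 0:
            raise ValueError("cycles must be >= 0")
        g = self.cell_scale(n_cells)
        return float(self.Linf + (self.L0 * g - self.Linf) * math.exp(-self.k * cycles / g))


def _decay(c, linf, a, k):
    return linf + a * np.exp(-k * c)


@dataclass
class GroupDecayFit:
    """Per cell-count-group least-squares fit of L = Linf + A exp(-k c)."""

    n_cells: float
    Linf: float
    A: float
    k: float
    residuals: np.ndarray

    @property
    def model(self) -> SonicationModel:
        return SonicationModel(
            L0=self.Linf + self.A, Linf=self.Linf, k=self.k,
            cell_factor=0.0, cells_ref=self.n_cells,
        )

    def predict(self, cycles: float) -> float:
        return self.model.predict(cycles)


@dataclass
class DecayFit:
    groups: dict[float, GroupDecayFit] = field(default_factory=dict)

    def model_for(self, n_cells: float) -> SonicationModel:
        return self.groups[n_cells].model

    def predict(self, cycles: float, n_cells: float) -> float:
        return self.groups[n_cells].predict(cycles)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"n_cells": g.n_cells, "Linf": g.Linf, "A": g.A, "k": g.k,
                 "rss": float((g.residuals ** 2).sum())}
                for g in self.groups.values()
            ]
        )


def fit_decay(points: pd.DataFrame | Iterable[tuple]) -> DecayFit:
    """Fit the decay law per cell-count group.

    ``points`` is a DataFrame with columns (cycles, avg_length, n_cells) or an
    iterable of such tuples; each group needs >= 3 distinct cycle values.
    """
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["cycles", "avg_length", "n_cells"])
    fit = DecayFit()
    for n_cells, sub in points.groupby("n_cells"):
        c = sub["cycles"].to_numpy(dtype=float)
        y = sub["avg_length"].to_numpy(dtype=float)
        if len(np.unique(c)) < 3:
            raise ValueError(
                f"group n_cells={n_cells}: need >= 3 distinct cycle values, got {len(np.unique(c))}"
            )
        linf0 = max(0.5 * y.min(), 1.0)
        # crude initial rate from the log-linearised first/last points
        span = max(c.max() - c.min(), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = max((y.max() - linf0) / max(y.min() - linf0, 1e-9), 1.0 + 1e-6)
        k0 = math.log(ratio) / span
        a0 = (y.max() - linf0) * math.exp(k0 * c.min())
        try:
            popt, _ = curve_fit(
                _decay, c, y,
                p0=(linf0, a0, max(k0, 1e-3)),
                bounds=([0.0, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:  # non-convergence: report diagnostics
            raise RuntimeError(
                f"decay fit failed for n_cells={n_cells}: {err}; "
                f"cycles={c.tolist()}, lengths={y.tolist()}"
            ) from err
        linf, a, k = (float(v) for v in popt)
        fit.groups[float(n_cells)] = GroupDecayFit(
            n_cells=float(n_cells), Linf=linf, A=a, k=k,
            residuals=y - _decay(c, linf, a, k),
        )
    return fit


def cycles_for_target(
    model: SonicationModel | DecayFit | GroupDecayFit,
    target: float,
    n_cells: float | None = None,
) -> int:
    """Smallest integer cycle count whose predicted length is <= target."""
    if isinstance(model, DecayFit):
        if n_cells is None:
            raise ValueError("n_cells required to select a DecayFit group")
        model = model.model_for(n_cells)
        n_cells = None
    elif isinstance(model, GroupDecayFit):
        model = model.model
        n_cells = None
    l_start = model.predict(0, n_cells)
    if not (model.Linf < target < l_start):
        raise ValueError(
            f"target {target} outside achievable range ({model.Linf}, {l_start})"
        )
    g = model.cell_scale(n_cells)
    c_star = -(g / model.k) * math.log((target - model.Linf) / (l_start - model.Linf))
    c = max(0, math.ceil(c_star - 1e-9))
    while model.predict(c, n_cells) > target:  # guard against rounding
        c += 1
    while c > 0 and model.predict(c - 1, n_cells) <= target:
        c -= 1
    return c
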