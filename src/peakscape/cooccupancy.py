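"""Percentage-overlap matrices between peak classes and external peak sets.

Two intervals co-occur when the gap between them is at most ``maxgap``
(default 150 nt; intersecting intervals have gap 0, and the bound is
inclusive).  Percentages are row-normalized: each cell is the share of
the class's peaks touched by at least one external peak, regardless of
how many.  Queries use per-chromosome sorted arrays with a prefix-max
sweep, so large sets stay fast; a summit-distance mode is available for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import reference_point
from .core_io import Peak, PeakSet


def gap(a: Peak, b: Peak) -> Optional[int]:
    """Edge gap between two intervals; 0 when they intersect; None across chroms."""
    if a.chrom != b.chrom:
        return None
    return max(b.start - a.end, a.start - b.end, 0)


def overlaps_within(a: Peak, b: Peak, maxgap: int = 150) -> bool:
    """True iff the peaks are on one chromosome with gap <= maxgap (inclusive)."""
    if maxgap < 0:
        raise ValueError(f"maxgap must be >= 0, got {maxgap}")
    g = gap(a, b)
    return g is not None and g <= maxgap


class _ChromSweep:
    """Sorted starts + prefix-max ends per chromosome for existence queries."""

    def __init__(self, peaks: Iterable[Peak], mode: str = "interval"):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            if mode == "summit":
                # zero-length interval: the sweep condition then reduces to
                # |summit_a - summit_b| <= maxgap
                pt = reference_point(p)
                iv = (pt, pt)
            else:
                iv = (p.start, p.end)
            per_chrom.setdefault(p.chrom, []).append(iv)
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._maxend[chrom] = np.maximum.accumulate(ends)

    def any_within(self, chrom: str, start: int, end: int, maxgap: int) -> bool:
        """Is there an indexed interval with edge gap <= maxgap of [start,end)?"""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        # need some b with b.start <= end + maxgap and b.end >= start - maxgap
        idx = int(np.searchsorted(starts, end + maxgap, side="right"))
        if idx == 0:
            return False
        return bool(self._maxend[chrom][idx - 1] >= start - maxgap)


def overlap_fraction(
    class_peaks: PeakSet | Sequence[Peak],
    external: PeakSet | Sequence[Peak],
    maxgap: int = 150,
    mode: str = "interval",
) -> tuple[Optional[float], int, int]:
    """``(percentage, numerator, denominator)`` of class peaks with a partner.

    ``mode="summit"`` measures the gap between 1-bp reference points instead
    of whole intervals.  An empty class yields ``(None, 0, 0)`` — undefined,
    not an error.
    """
    if maxgap < 0:
        raise ValueError(f"maxgap must be >= 0, got {maxgap}")
    if mode not in ("interval", "summit"):
        raise ValueError(f"mode must be 'interval' or 'summit', got {mode!r}")
    a_list = list(class_peaks)
    if not a_list:
        return None, 0, 0
    sweep = _ChromSweep(external, mode)
    k = 0
    for p in a_list:
        if mode == "summit":
            pt = reference_point(p)
            start, end = pt, pt
        else:
            start, end = p.start, p.end
        k += sweep.any_within(p.chrom, start, end, maxgap)
    return 100.0 * k / len(a_list), k, len(a_list)


@dataclass
class OverlapMatrix:
    """Row-normalized percentage matrix plus the underlying counts."""

    percent: pd.DataFrame
    numerator: pd.DataFrame
    denominator: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "percent": {c: {m: (None if pd.isna(v) else float(v))
                            for m, v in row.items()}
                        for c, row in self.percent.to_dict(orient="index").items()},
            "numerator": {c: {m: int(v) for m, v in row.items()}
                          for c, row in self.numerator.to_dict(orient="index").items()},
            "denominator": {c: {m: int(v) for m, v in row.items()}
                            for c, row in self.denominator.to_dict(orient="index").items()},
        }


def overlap_matrix(
    classes: Mapping[str, Sequence[Peak]],
    external: Mapping[str, PeakSet | Sequence[Peak]],
    maxgap: int = 150,
    mode: str = "interval",
) -> OverlapMatrix:
    """Overlap percentages for every (peak class, external set) pair.

    Empty classes give NaN cells (undefined percentage); empty external sets
    give 0% columns.
    """
    class_names = list(classes)
    ext_names = list(external)
    pct = pd.DataFrame(index=class_names, columns=ext_names, dtype=float)
    num = pd.DataFrame(0, index=class_names, columns=ext_names, dtype=int)
    den = pd.DataFrame(0, index=class_names, columns=ext_names, dtype=int)
    sweeps = {m: _ChromSweep(external[m], mode) for m in ext_names}
    for cls in class_names:
        peaks = list(classes[cls])
        for m in ext_names:
            if not peaks:
                pct.loc[cls, m] = np.nan
                continue
            sweep = sweeps[m]
            k = 0
            for p in peaks:
                if mode == "summit":
                    pt = reference_point(p)
                    start, end = pt, pt
                else:
                    start, end = p.start, p.end
                k += sweep.any_within(p.chrom, start, end, maxgap)
            pct.loc[cls, m] = 100.0 * k / len(peaks)
            num.loc[cls, m] = k
            den.loc[cls, m] = len(peaks)
    return OverlapMatrix(pct, num, den)


def plot_heatmap(matrix: OverlapMatrix, path: str | Path) -> None:
    """Render the percentage matrix as a labelled heatmap image (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.percent.astype(float)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(data.columns), 1.0 + 0.4 * len(data.index))
    )
    im = ax.imshow(data.values, cmap="RdYlGn", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
    ax.set_yticks(range(len(data.index)), data.index)
    for i in range(len(data.index)):
        for j in range(len(data.columns)):
            v = data.values[i, j]
            if not np.isnan(v):
                ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="% of class peaks overlapping")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
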