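"""Nearest-gene assignment and strand-aware TSS-distance classification.

Each peak is reduced to a single reference point (its summit when known,
otherwise the interval midpoint) and assigned to the gene whose TSS is
nearest in absolute distance on the same chromosome.  Signed distances
follow the gene's reading direction: negative means upstream of the TSS,
positive downstream, so a peak at higher coordinates than a minus-strand
TSS is *upstream*.  Genic location is a five-way call with precedence
TSS > TES > intragenic > upstream/downstream.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, Peak, PeakSet

UNASSIGNED = "unassigned"

LOCATIONS = ("TSS", "TES", "intragenic", "upstream", "downstream")


@dataclass
class PeakGeneAssignment:
    """A peak paired with its nearest gene.

    ``signed_distance``, ``location`` and ``proximity`` are ``None`` for
    peaks on chromosomes without genes (``gene_id == "unassigned"``).
    """

    peak_id: str
    chrom: str
    point: int
    gene_id: str
    signed_distance: Optional[int]
    location: Optional[str]
    proximity: Optional[str]


def reference_point(peak: Peak) -> int:
    """Summit position when present, else the floor midpoint."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def signed_tss_distance(point: int, gene: GeneModel) -> int:
    """Distance from ``point`` to the gene's TSS, negative upstream."""
    return point - gene.tss if gene.strand == "+" else gene.tss - point


def proximity_class(signed_distance: int, threshold: int = 1000) -> str:
    """``proximal`` iff |distance| <= threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return "proximal" if abs(signed_distance) <= threshold else "distal"


def classify_genic_location(peak: Peak, gene: GeneModel) -> str:
    """Five-way genic location with precedence TSS > TES > intragenic > up/down."""
    if peak.start <= gene.tss < peak.end:
        return "TSS"
    if peak.start <= gene.tes < peak.end:
        return "TES"
    if gene.span_start <= peak.start and peak.end <= gene.span_end:
        return "intragenic"
    d = signed_tss_distance(reference_point(peak), gene)
    return "upstream" if d < 0 else "downstream"


class GeneIndex:
    """Per-chromosome sorted-TSS index for nearest-gene queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._genes: dict[str, list[GeneModel]] = {}
        self._tss: dict[str, list[int]] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._genes[chrom] = gs
            self._tss[chrom] = [g.tss for g in gs]

    def nearest(self, chrom: str, point: int) -> Optional[GeneModel]:
        """The gene minimizing |point - tss|; ties go to the smallest gene_id."""
        tss = self._tss.get(chrom)
        if not tss:
            return None
        genes = self._genes[chrom]
        i = bisect_left(tss, point)
        best = min(
            abs(point - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)
        )
        # all genes whose TSS sits at point-best or point+best
        candidates: list[GeneModel] = []
        for target in {point - best, point + best}:
            lo, hi = bisect_left(tss, target), bisect_right(tss, target)
            candidates.extend(genes[lo:hi])
        return min(candidates, key=lambda g: g.gene_id)


def assign_nearest_gene(
    peak: Peak,
    genes: GeneIndex | Sequence[GeneModel],
    proximal_threshold: int = 1000,
) -> PeakGeneAssignment:
    """Assign one peak to its nearest gene by absolute TSS distance."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    point = reference_point(peak)
    gene = index.nearest(peak.chrom, point)
    if gene is None:
        return PeakGeneAssignment(peak.peak_id, peak.chrom, point,
                                  UNASSIGNED, None, None, None)
    d = signed_tss_distance(point, gene)
    return PeakGeneAssignment(
        peak.peak_id, peak.chrom, point, gene.gene_id, d,
        classify_genic_location(peak, gene),
        proximity_class(d, proximal_threshold),
    )


def annotate_peaks(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
    proximal_threshold: int = 1000,
) -> list[PeakGeneAssignment]:
    """Assign every peak in the set; order follows the input peaks."""
    index = GeneIndex(genes)
    return [assign_nearest_gene(p, index, proximal_threshold) for p in peaks]


def location_counts(assignments: Iterable[PeakGeneAssignment]) -> dict[str, int]:
    """Five-way location tally plus the intergenic (upstream+downstream) roll-up."""
    counts = {loc: 0 for loc in LOCATIONS}
    counts[UNASSIGNED] = 0
    for a in assignments:
        counts[a.location if a.location is not None else UNASSIGNED] += 1
    counts["intergenic"] = counts["upstream"] + counts["downstream"]
    return counts


def tss_window_profile(
    distances_by_class: Mapping[str, Sequence[int]],
    window: int = 2000,
    bin: int = 100,
) -> pd.DataFrame:
    """Histogram of signed TSS distances in [-window, +window] per class.

    Bins are half-open ``[lo, lo+bin)`` except the last, which also takes
    ``+window`` (numpy histogram convention).  Densities are per-class bin
    fractions (each class sums to 1 when it has any in-window distance).
    """
    if (2 * window) % bin != 0:
        raise ValueError(f"bin {bin} must divide 2*window {2 * window}")
    edges = np.arange(-window, window + bin, bin)
    out = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:]})
    for cls, dists in distances_by_class.items():
        arr = np.asarray(list(dists), dtype=float)
        counts, _ = np.histogram(arr, bins=edges)
        total = counts.sum()
        out[f"count_{cls}"] = counts
        out[f"density_{cls}"] = counts / total if total else np.zeros_like(counts, dtype=float)
    return out


def write_assignments(assignments: Iterable[PeakGeneAssignment], path: str | Path) -> None:
    """One TSV row per peak: id, chrom, point, gene, distance, location, proximity."""
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tpoint\tgene_id\tsigned_distance\tlocation\tproximity\n")
        for a in assignments:
            d = "" if a.signed_distance is None else a.signed_distance
            fh.write(f"{a.peak_id}\t{a.chrom}\t{a.point}\t{a.gene_id}\t{d}\t"
                     f"{a.location or ''}\t{a.proximity or ''}\n")
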