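"""Expression labelling and the peak-class partition.

A gene is *expressed* when its RPKM reaches the cutoff (inclusive, default
1.0), *silent* below it, and *unknown* when absent from the expression
table.  Peaks inherit the status of their assigned nearest gene and are
additionally split by TSS proximity (|distance| <= threshold) and, within
the proximal set, by orientation (upstream = negative signed distance;
a distance of exactly 0 — the summit on the TSS — counts as downstream,
since transcription initiates inside the peak).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotate import PeakGeneAssignment
from .core_io import ExpressionRecord

logger = logging.getLogger("peakscape")

STATUSES = ("expressed", "silent", "unknown")


def label_expressed(
    records: Iterable[ExpressionRecord],
    cutoff: float = 1.0,
) -> dict[str, str]:
    """Map gene_id -> expressed/silent; genes not in the table are unknown
    (handled by lookups against this mapping, see :func:`gene_status`)."""
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    labels: dict[str, str] = {}
    for r in records:
        if r.rpkm < 0:
            raise ValueError(f"gene {r.gene_id!r}: negative RPKM {r.rpkm}")
        labels[r.gene_id] = "expressed" if r.rpkm >= cutoff else "silent"
    return labels


@dataclass
class PeakClassTable:
    """Per-peak class labels and the class membership lists/counts."""

    rows: list[dict] = field(default_factory=list)
    class_peak_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {cls: len(ids) for cls, ids in self.class_peak_ids.items()}

    def status_by_peak(self) -> dict[str, str]:
        return {r["peak_id"]: r["status"] for r in self.rows}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peak_id\tgene_id\tsigned_distance\tstatus\tproximity\torientation\n")
            for r in self.rows:
                d = "" if r["signed_distance"] is None else r["signed_distance"]
                fh.write(f"{r['peak_id']}\t{r['gene_id']}\t{d}\t{r['status']}\t"
                         f"{r['proximity'] or ''}\t{r['orientation'] or ''}\n")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"counts": self.counts}, fh, sort_keys=True, indent=2)
            fh.write("\n")


def partition_peaks(
    assignments: Sequence[PeakGeneAssignment],
    labels: Mapping[str, str],
    proximal_threshold: int = 1000,
    unknown_as_silent: bool = False,
) -> PeakClassTable:
    """Partition peaks into the six analysis classes.

    Classes: expressed / silent (plus unknown) by target-gene status;
    proximal / distal by |signed distance| vs the threshold; and, within
    proximal, upstream / downstream by the distance sign (0 -> downstream).
    Unassigned peaks (no gene on the chromosome) have unknown status and no
    proximity class.
    """
    table = PeakClassTable(
        class_peak_ids={cls: [] for cls in
                        ("expressed", "silent", "unknown", "proximal", "distal",
                         "proximal_upstream", "proximal_downstream")}
    )
    for a in assignments:
        status = labels.get(a.gene_id, "unknown")
        if status == "unknown" and unknown_as_silent:
            status = "silent"
        proximity = orientation = None
        if a.signed_distance is not None:
            proximity = ("proximal" if abs(a.signed_distance) <= proximal_threshold
                         else "distal")
            if proximity == "proximal":
                orientation = "upstream" if a.signed_distance < 0 else "downstream"
        table.rows.append({
            "peak_id": a.peak_id, "gene_id": a.gene_id,
            "signed_distance": a.signed_distance,
            "status": status, "proximity": proximity, "orientation": orientation,
        })
        table.class_peak_ids[status].append(a.peak_id)
        if proximity is not None:
            table.class_peak_ids[proximity].append(a.peak_id)
        if orientation is not None:
            table.class_peak_ids[f"proximal_{orientation}"].append(a.peak_id)
    return table


def summarize_target_genes(
    assignments: Sequence[PeakGeneAssignment],
    labels: Mapping[str, str],
) -> dict:
    """Unique target genes by expression status with integer percent shares."""
    genes: set[str] = {a.gene_id for a in assignments if a.gene_id != "unassigned"}
    counts = {s: 0 for s in STATUSES}
    for g in genes:
        counts[labels.get(g, "unknown")] += 1
    total = len(genes)
    shares = {s: (round(100 * c / total) if total else 0) for s, c in counts.items()}
    if total and abs(sum(shares.values()) - 100) > 1:
        logger.warning("target-gene percent shares sum to %d", sum(shares.values()))
    return {
        "n_target_genes": total,
        "counts": counts,
        "percent": shares,
    }
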