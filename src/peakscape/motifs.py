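"""IUPAC consensus scanning in summit-centered windows.

The census asks, for each peak class and each core-promoter element, what
fraction of peaks carries at least one match inside a fixed-width window
(default 75 nt) centered on the peak's reference point.  Scanning covers
both strands by default — peaks carry no intrinsic orientation — and
reports every overlapping match.  An ``N`` in the sequence matches only
the pattern code ``N``.

The default pattern registry holds the five elements the census targets:
the TATA box (TATAAA), the initiator INR (YYANWYY), the downstream
promoter element DPE (RGWYV), the TFIIB recognition element BRE (SSRCGCC)
and the TFII-I/BEN SELEX consensus (RGATTR).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import PeakGeneAssignment, reference_point
from .core_io import Peak
from .stats import TestResult, chisq_2x2

logger = logging.getLogger("peakscape")

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# complement map over the full IUPAC alphabet (for reverse-complementing patterns)
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class IupacPattern:
    """A named degenerate consensus over the IUPAC nucleotide alphabet."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"pattern {self.name!r} is empty")
        bad = set(self.pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"pattern {self.name!r}: invalid IUPAC codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)


DEFAULT_PATTERNS: list[IupacPattern] = [
    IupacPattern("TATA", "TATAAA"),
    IupacPattern("INR", "YYANWYY"),
    IupacPattern("DPE", "RGWYV"),
    IupacPattern("BRE", "SSRCGCC"),
    IupacPattern("RGATTR", "RGATTR"),
]


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid DNA characters {sorted(bad)}")
    return seq.translate(DNA_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern:
    """Overlap-tolerant regex for an IUPAC pattern (plus-strand sense).

    Pattern code N also matches sequence N; all other codes exclude N.
    """
    parts = []
    for code in pattern.upper():
        allowed = IUPAC_SETS[code] + ("N" if code == "N" else "")
        parts.append(f"[{allowed}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(
    seq: str,
    pattern: IupacPattern | str,
    strands: str = "both",
) -> list[tuple[int, str]]:
    """All match positions of the pattern in ``seq``.

    Positions are 0-based plus-strand footprint starts.  Minus-strand hits
    are matches of the reverse-complemented pattern scanned on the given
    sequence.  Overlapping matches are all reported.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"strands must be 'plus' or 'both', got {strands!r}")
    pat = pattern.pattern if isinstance(pattern, IupacPattern) else pattern
    seq = seq.upper()
    hits = [(m.start(), "+") for m in _pattern_regex(pat).finditer(seq)]
    if strands == "both":
        rc = pat.upper().translate(IUPAC_COMPLEMENT)[::-1]
        hits.extend((m.start(), "-") for m in _pattern_regex(rc).finditer(seq))
    hits.sort()
    return hits


def summit_region(
    peak: Peak,
    width: int = 75,
    chrom_length: Optional[int] = None,
) -> tuple[int, int, bool]:
    """The ``width``-nt interval centered on the peak's reference point.

    For odd widths the window is exactly ``[point-(w-1)/2, point+(w+1)/2)``;
    even widths round the extra base to the right.  Returns
    ``(start, end, clipped)`` with the window clipped to chromosome bounds.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    point = reference_point(peak)
    if point < 0 or (chrom_length is not None and point >= chrom_length):
        raise ValueError(
            f"peak {peak.peak_id!r}: reference point {point} outside chromosome"
        )
    start = point - (width - 1) // 2
    end = start + width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if clipped:
        logger.debug("peak %s: summit window clipped to [%d, %d)",
                     peak.peak_id, start, end)
    return start, end, clipped


def window_sequence(peak: Peak, genome: Mapping[str, str], width: int = 75) -> str:
    if peak.chrom not in genome:
        raise KeyError(f"peak {peak.peak_id!r}: chromosome {peak.chrom!r} not in genome")
    start, end, _ = summit_region(peak, width, len(genome[peak.chrom]))
    return genome[peak.chrom][start:end]


def motif_census(
    class_peaks: Mapping[str, Sequence[Peak]],
    genome: Mapping[str, str],
    patterns: Sequence[IupacPattern] = DEFAULT_PATTERNS,
    window: int = 75,
    strands: str = "both",
) -> pd.DataFrame:
    """Fraction of peaks per class whose summit window has >= 1 pattern match.

    Columns: class, pattern, n_peaks, n_with_match, fraction, n_total_matches.
    Match multiplicity is tallied separately and does not affect fractions.
    Empty classes are recorded with fraction 0 and flagged in the log.
    """
    rows = []
    for cls in class_peaks:
        peaks = class_peaks[cls]
        if not peaks:
            logger.warning("motif census: class %r has no peaks", cls)
        seqs = [window_sequence(p, genome, window) for p in peaks]
        for pat in patterns:
            n_with = 0
            n_matches = 0
            for s in seqs:
                hits = scan_iupac(s, pat, strands)
                n_with += bool(hits)
                n_matches += len(hits)
            n = len(peaks)
            rows.append({
                "class": cls, "pattern": pat.name,
                "n_peaks": n, "n_with_match": n_with,
                "fraction": n_with / n if n else 0.0,
                "n_total_matches": n_matches,
            })
    return pd.DataFrame(rows)


def census_classes(
    assignments: Sequence[PeakGeneAssignment],
    status_by_peak: Mapping[str, str],
    peaks_by_id: Mapping[str, Peak],
    tss_limit: int = 1000,
) -> dict[str, list[Peak]]:
    """The census classes: expressed/silent peaks within ``tss_limit`` of the
    TSS, and the expressed subset split by orientation."""
    classes: dict[str, list[Peak]] = {
        "expressed_proximal": [], "silent_proximal": [],
        "expressed_upstream": [], "expressed_downstream": [],
    }
    for a in assignments:
        if a.signed_distance is None or abs(a.signed_distance) > tss_limit:
            continue
        status = status_by_peak.get(a.peak_id, "unknown")
        peak = peaks_by_id[a.peak_id]
        if status == "expressed":
            classes["expressed_proximal"].append(peak)
            side = "upstream" if a.signed_distance < 0 else "downstream"
            classes[f"expressed_{side}"].append(peak)
        elif status == "silent":
            classes["silent_proximal"].append(peak)
    return classes


def bre_enrichment(
    proximal: tuple[int, int],
    non_proximal: tuple[int, int],
    active: tuple[int, int],
    silent: tuple[int, int],
) -> dict[str, TestResult]:
    """The two BRE chi-square tests, from (n_with_match, n_total) pairs.

    ``proximal_vs_all``: BRE presence in TSS-proximal vs non-proximal peaks;
    ``active_vs_silent``: BRE presence in proximal peaks of active vs silent
    target genes.
    """
    def _table(a: tuple[int, int], b: tuple[int, int]):
        (ka, na), (kb, nb) = a, b
        return [[ka, na - ka], [kb, nb - kb]]

    return {
        "proximal_vs_all": chisq_2x2(_table(proximal, non_proximal)),
        "active_vs_silent": chisq_2x2(_table(active, silent)),
    }


def bre_census_tests(
    assignments: Sequence[PeakGeneAssignment],
    status_by_peak: Mapping[str, str],
    peaks_by_id: Mapping[str, Peak],
    genome: Mapping[str, str],
    bre: IupacPattern = DEFAULT_PATTERNS[3],
    window: int = 75,
    tss_limit: int = 1000,
    gene_limit: int = 10000,
) -> dict[str, TestResult]:
    """Assemble the BRE contingency tables from peaks within ``gene_limit``
    of a TSS (proximal = within ``tss_limit``) and run both tests."""
    def _has_bre(peak: Peak) -> bool:
        return bool(scan_iupac(window_sequence(peak, genome, window), bre))

    prox, nonprox, act, sil = [0, 0], [0, 0], [0, 0], [0, 0]
    for a in assignments:
        if a.signed_distance is None or abs(a.signed_distance) > gene_limit:
            continue
        hit = _has_bre(peaks_by_id[a.peak_id])
        bucket = prox if abs(a.signed_distance) <= tss_limit else nonprox
        bucket[0] += hit
        bucket[1] += 1
        if abs(a.signed_distance) <= tss_limit:
            status = status_by_peak.get(a.peak_id, "unknown")
            if status == "expressed":
                act[0] += hit
                act[1] += 1
            elif status == "silent":
                sil[0] += hit
                sil[1] += 1
    return bre_enrichment(tuple(prox), tuple(nonprox), tuple(act), tuple(sil))
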