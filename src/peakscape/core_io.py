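"""Domain types, format readers/writers and the top-level pipeline driver.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention).  GTF input, which is 1-based closed, is converted at
the boundary and never stored.  The transcription start site (TSS) of a
plus-strand gene is its span start; for a minus-strand gene it is the last
base of the span (``span_end - 1``).  The transcription end site (TES) is
the opposite terminus.

Formats supported: BED3/BED6 and 10-column narrowPeak for peak sets, GTF
(``gene`` feature lines) or a simple headered TSV for gene models, FASTA
for genome sequence and a two-column TSV for expression tables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger("peakscape")

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


class ConfigError(ValueError):
    """A pipeline configuration that cannot be run."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TES; the reference frame for distances."""

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.span_start < self.span_end:
            raise ValueError(
                f"gene {self.gene_id!r}: span_start must be < span_end "
                f"({self.span_start} >= {self.span_end})"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based, always inside the span)."""
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: the terminus opposite the TSS."""
        return self.span_end - 1 if self.strand == "+" else self.span_start


@dataclass
class Peak:
    """A genomic interval with an optional summit offset from its start."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit_offset: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"peak {self.peak_id!r}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"peak {self.peak_id!r}: summit_offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A named, ordered collection of peaks with unique ids."""

    name: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"peak set {self.name!r}: duplicate peak_id {dup!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}


@dataclass
class ExpressionRecord:
    gene_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative RPKM {self.rpkm}")


# A genome is simply a mapping chrom -> uppercase DNA string over {A,C,G,T,N}.
GenomeSequence = dict


# ---------------------------------------------------------------------------
# Peak I/O
# ---------------------------------------------------------------------------

def _normalize_peak_format(fmt: str) -> str:
    f = fmt.lower()
    if f in ("bed", "bed3", "bed6"):
        return "bed"
    if f in ("narrowpeak", "np"):
        return "narrowpeak"
    raise ValueError(f"unknown peak format {fmt!r}")


def read_peaks(path: str | Path, format: str = "bed", name: Optional[str] = None) -> PeakSet:
    """Read a BED or narrowPeak file into a :class:`PeakSet`.

    Coordinates are kept 0-based half-open.  narrowPeak column 10 becomes the
    summit offset, with the sentinel ``-1`` mapped to "absent".  Missing or
    ``"."`` names get auto-generated ids ``peak_<lineno>``.
    """
    fmt = _normalize_peak_format(format)
    min_cols = 3 if fmt == "bed" else 10
    peaks: list[Peak] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            pid = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{lineno}"
            if pid in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate peak_id {pid!r}")
            seen_ids.add(pid)
            score: Optional[float] = None
            if len(cols) > 4 and cols[4] not in ("", "."):
                score = float(cols[4])
            summit: Optional[int] = None
            if fmt == "narrowpeak":
                try:
                    raw = int(cols[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer summit") from exc
                summit = None if raw == -1 else raw
            try:
                peaks.append(Peak(pid, cols[0], start, end, summit, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name=name or Path(path).stem, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str | Path, format: str = "bed") -> None:
    """Write a peak set as BED6 or narrowPeak (lossless round-trip)."""
    fmt = _normalize_peak_format(format)
    with open(path, "w") as fh:
        for p in peakset:
            score = "." if p.score is None else f"{p.score:g}"
            if fmt == "bed":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\n")
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\t"
                    f"0\t-1\t-1\t{summit}\n"
                )


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from GTF (``gene`` features, 1-based closed) or TSV.

    The TSV dialect is headered ``gene_id  chrom  start  end  strand`` with
    0-based half-open coordinates.  Both are normalized to the internal
    half-open convention; TSS/TES follow from strand.
    """
    fmt = format.lower()
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene_id: str, chrom: str, start: int, end: int, strand: str, lineno: int) -> None:
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(GeneModel(gene_id, chrom, strand, start, end))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc

    with open(path) as fh:
        if fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            required = ["gene_id", "chrom", "start", "end", "strand"]
            if header[: len(required)] != required:
                raise ParseError(f"{path}:1: expected header {required}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                try:
                    start, end = int(cols[2]), int(cols[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                _add(cols[0], cols[1], start, end, cols[4], lineno)
        elif fmt == "gtf":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
                if cols[2] != "gene":
                    continue
                try:
                    start1, end1 = int(cols[3]), int(cols[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                attrs = _parse_gtf_attributes(cols[8])
                if "gene_id" not in attrs:
                    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
                # GTF is 1-based closed: [start1, end1] -> [start1-1, end1)
                _add(attrs["gene_id"], cols[0], start1 - 1, end1, cols[6], lineno)
        else:
            raise ValueError(f"unknown gene-model format {format!r}")
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in the headered TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.span_start}\t{g.span_end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Expression and genome I/O
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a headered two-column TSV ``gene_id  rpkm``."""
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "rpkm"]:
            raise ParseError(f"{path}:1: expected header ['gene_id', 'rpkm'], got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if cols[0] in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {cols[0]!r}")
            seen.add(cols[0])
            try:
                records.append(ExpressionRecord(cols[0], float(cols[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.rpkm:.6g}\n")


def read_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into ``{chrom: uppercase sequence}`` over {A,C,G,T,N}."""
    from Bio import SeqIO

    genome: GenomeSequence = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(f"{path}: chrom {rec.id!r}: invalid characters {sorted(bad)}")
        genome[rec.id] = seq
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Convenience: RPKM
# ---------------------------------------------------------------------------

def compute_rpkm(read_count: float, gene_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    ``read_count * 1e9 / (gene_length * total_mapped)``.
    """
    if gene_length <= 0:
        raise ValueError(f"gene_length must be > 0, got {gene_length}")
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be > 0, got {total_mapped}")
    if read_count < 0:
        raise ValueError(f"read_count must be >= 0, got {read_count}")
    return read_count * 1e9 / (gene_length * total_mapped)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything :func:`run_analysis` needs; thresholds default to the
    values the analysis uses throughout (±1 kb proximal, ±2 kb profile
    window, 100-bp bins, RPKM cutoff 1, 150-nt overlap gap, 75-nt summit
    window, 1 kb motif-census limit, 10 kb gene-assignment limit)."""

    peaks: str
    genes: str
    expression: str
    fasta: Optional[str] = None
    marks: dict[str, str] = field(default_factory=dict)
    out_dir: str = "."
    peak_format: str = "narrowpeak"
    gene_format: str = "tsv"
    proximal_threshold: int = 1000
    tss_window: int = 2000
    hist_bin: int = 100
    rpkm_cutoff: float = 1.0
    maxgap: int = 150
    summit_window: int = 75
    motif_tss_limit: int = 1000
    motif_gene_limit: int = 10000
    unknown_as_silent: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _json_default(x):
    """Coerce numpy scalars so the report serializes deterministically."""
    import numpy as np

    if isinstance(x, np.integer):
        return int(x)
    if isinstance(x, np.floating):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_analysis(config: PipelineConfig) -> dict:
    """Run the full downstream analysis and write TSV tables plus a JSON report.

    Stages: annotate -> stratify -> distribution stats -> motif census (when a
    FASTA is configured) -> co-occupancy matrix (when external mark sets are
    configured).  Missing required inputs raise :class:`ConfigError` before any
    computation.  The report is written with sorted keys so that identical
    inputs give byte-identical output.
    """
    from . import annotate as _ann
    from . import cooccupancy as _co
    from . import motifs as _mo
    from . import stats as _st
    from . import stratify as _str

    for label, p in (("peaks", config.peaks), ("genes", config.genes),
                     ("expression", config.expression)):
        if not p or not os.path.exists(p):
            raise ConfigError(f"required input {label!r} missing: {p!r}")
    if config.fasta and not os.path.exists(config.fasta):
        raise ConfigError(f"fasta not found: {config.fasta!r}")
    for mname, mpath in config.marks.items():
        if not os.path.exists(mpath):
            raise ConfigError(f"mark set {mname!r} not found: {mpath!r}")

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("thresholds: proximal=%d bp, tss_window=%d bp, bin=%d bp, "
                "rpkm_cutoff=%g, maxgap=%d nt, summit_window=%d nt, "
                "motif_tss_limit=%d bp, motif_gene_limit=%d bp",
                config.proximal_threshold, config.tss_window, config.hist_bin,
                config.rpkm_cutoff, config.maxgap, config.summit_window,
                config.motif_tss_limit, config.motif_gene_limit)

    peakset = read_peaks(config.peaks, format=config.peak_format, name="tf")
    genes = read_gene_models(config.genes, format=config.gene_format)
    expression = read_expression(config.expression)

    # --- annotate ---------------------------------------------------------
    assignments = _ann.annotate_peaks(peakset, genes, config.proximal_threshold)
    _ann.write_assignments(assignments, outdir / "assignments.tsv")
    loc_counts = _ann.location_counts(assignments)

    # --- stratify ---------------------------------------------------------
    labels = _str.label_expressed(expression, cutoff=config.rpkm_cutoff)
    table = _str.partition_peaks(
        assignments, labels, config.proximal_threshold,
        unknown_as_silent=config.unknown_as_silent,
    )
    table.to_tsv(outdir / "peak_classes.tsv")
    targets = _str.summarize_target_genes(assignments, labels)

    # --- TSS-distance profiles and tests ----------------------------------
    status = table.status_by_peak()
    dist_by_class = {
        cls: [a.signed_distance for a in assignments
              if a.signed_distance is not None and status.get(a.peak_id) == cls]
        for cls in ("expressed", "silent")
    }
    hist = _ann.tss_window_profile(dist_by_class, window=config.tss_window,
                                   bin=config.hist_bin)
    hist.to_csv(outdir / "tss_histogram.tsv", sep="\t", index=False)

    in_win = {
        cls: [d for d in ds if -config.tss_window <= d <= config.tss_window]
        for cls, ds in dist_by_class.items()
    }
    tests: dict[str, dict] = {}
    expr_up = sum(1 for d in in_win["expressed"] if d < 0)
    expr_dn = len(in_win["expressed"]) - expr_up
    sil_up = sum(1 for d in in_win["silent"] if d < 0)
    sil_dn = len(in_win["silent"]) - sil_up
    contingency = [[expr_up, expr_dn], [sil_up, sil_dn]]
    if min(expr_up + expr_dn, sil_up + sil_dn, expr_up + sil_up, expr_dn + sil_dn) > 0:
        res = _st.chisq_2x2(contingency)
        tests["downstream_abundance_chisq"] = res.to_dict() | {"table": contingency}
    for side, pred in (("upstream", lambda d: d < 0), ("downstream", lambda d: d > 0)):
        x = [abs(d) for d in in_win["expressed"] if pred(d)]
        y = [abs(d) for d in in_win["silent"] if pred(d)]
        if x and y:
            res = _st.wilcoxon_rank_sum(x, y)
            tests[f"tss_distance_wilcoxon_{side}"] = res.to_dict()

    report: dict = {
        "config": {
            k: getattr(config, k)
            for k in ("proximal_threshold", "tss_window", "hist_bin", "rpkm_cutoff",
                      "maxgap", "summit_window", "motif_tss_limit",
                      "motif_gene_limit", "unknown_as_silent", "seed")
        },
        "n_peaks": len(peakset),
        "n_genes": len(genes),
        "location_counts": loc_counts,
        "class_counts": table.counts,
        "target_genes": targets,
        "tests": tests,
    }

    # --- motif census (optional) ------------------------------------------
    if config.fasta:
        genome = read_genome(config.fasta)
        census_classes = _mo.census_classes(
            assignments, status, peakset.by_id(),
            tss_limit=config.motif_tss_limit,
        )
        census = _mo.motif_census(
            census_classes, genome, _mo.DEFAULT_PATTERNS,
            window=config.summit_window,
        )
        census.to_csv(outdir / "motif_census.tsv", sep="\t", index=False)
        bre = _mo.bre_census_tests(
            assignments, status, peakset.by_id(), genome,
            window=config.summit_window, tss_limit=config.motif_tss_limit,
            gene_limit=config.motif_gene_limit,
        )
        report["motifs"] = {
            "census": census.to_dict(orient="records"),
            "bre_enrichment": {k: v.to_dict() for k, v in bre.items()},
        }

    # --- co-occupancy (optional) ------------------------------------------
    if config.marks:
        peaks_by_id = peakset.by_id()
        class_peaks = {
            cls: [peaks_by_id[i] for i in ids]
            for cls, ids in table.class_peak_ids.items()
        }
        external = {
            mname: read_peaks(mpath, format=config.peak_format, name=mname)
            for mname, mpath in sorted(config.marks.items())
        }
        matrix = _co.overlap_matrix(class_peaks, external, maxgap=config.maxgap)
        matrix.percent.to_csv(outdir / "overlap_matrix.tsv", sep="\t")
        report["cooccupancy"] = matrix.to_dict()

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report
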