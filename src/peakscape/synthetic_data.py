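"""Synthetic genomes, gene models, expression tables, TF peaks and mark sets.

The generator builds a complete, self-consistent input bundle for the
pipeline, together with a ground-truth ledger sufficient to recompute every
expected output:

* a uniform-random ACGT genome with non-overlapping genes (>= 2 kb apart),
  strands assigned at random;
* an expression table in which each gene is drawn expressed or silent and
  given a log-normal RPKM with a clean margin around the cutoff
  (medians 10 and 0.1 by default; an adversarial mode puts mass exactly at
  the cutoff to exercise the boundary rule);
* a TF peak set in which a configurable fraction of peaks is linked to a
  random gene, the summit placed at a strand-aware TSS offset drawn from a
  truncated normal whose parameters depend on the target gene's expression
  class (expressed genes biased upstream, silent genes symmetric — the
  asymmetry the distance profiles and the downstream-abundance test are
  meant to detect); the remainder fall uniformly in gene-free space;
* IUPAC motif instances planted at class-dependent rates inside 75-nt
  summit windows, never overwriting one another;
* external "mark" peak sets seeded from the TF peaks with a configurable
  conditional co-occupancy probability q plus uniform background peaks.

Randomness is split into one child stream per artifact (genome, expression,
peaks, motifs, marks), all derived from a single master seed, so outputs
are reproducible bit-for-bit and regenerating one artifact does not perturb
the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy import stats as sps

from .core_io import (
    ExpressionRecord,
    GeneModel,
    Peak,
    PeakSet,
    write_expression,
    write_gene_models,
    write_genome,
    write_peaks,
)
from .motifs import IUPAC_SETS, IupacPattern, DEFAULT_PATTERNS

logger = logging.getLogger("peakscape")

_PATTERNS_BY_NAME = {p.name: p for p in DEFAULT_PATTERNS}


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults give ~1000 TSS-linked
    peaks per expression class (2500 peaks x 0.8 linked x 0.5 expressed)."""

    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 1_500_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (2_000, 10_000)
    gene_spacing: int = 2_000
    frac_expressed: float = 0.5
    rpkm_cutoff: float = 1.0
    expressed_median_rpkm: float = 10.0
    silent_median_rpkm: float = 0.1
    rpkm_sigma: float = 0.8
    adversarial_expression: bool = False
    n_peaks: int = 2_500
    frac_tss_linked: float = 0.8
    offset_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"expressed": (-300.0, 400.0),
                                 "silent": (0.0, 800.0)}
    )
    offset_bound: int = 10_000
    peak_width: tuple[int, int] = (150, 400)
    summit_window: int = 75
    motif_plant_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TATA": {"expressed": 0.4, "silent": 0.1},
            "BRE": {"proximal": 0.3, "distal": 0.05},
        }
    )
    marks: dict[str, float] = field(default_factory=lambda: {"H3K4me3": 0.5})
    mark_jitter: int = 100
    mark_background_per_mb: float = 5.0
    proximal_threshold: int = 1_000

    def __post_init__(self) -> None:
        probs = [self.frac_expressed, self.frac_tss_linked, *self.marks.values()]
        probs += [r for d in self.motif_plant_rate.values() for r in d.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.gene_spacing < 0 or self.chrom_length <= 0:
            raise ValueError("invalid genome geometry")


@dataclass
class SimResult:
    """Everything the simulator produced plus the ground-truth ledger."""

    config: SimConfig
    genome: Optional[dict[str, str]]
    genes: list[GeneModel]
    expression: list[ExpressionRecord]
    peaks: PeakSet
    marks: dict[str, PeakSet]
    ledger: dict


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_genome(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    with_sequence: bool = True,
) -> tuple[Optional[dict[str, str]], list[GeneModel]]:
    """Uniform-random genome plus non-overlapping genes >= spacing apart.

    Raises before emitting anything if the requested genes cannot be packed
    into the chromosomes at the required spacing.  ``with_sequence=False``
    skips sequence synthesis for coordinate-only studies.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1

    genome: Optional[dict[str, str]] = {} if with_sequence else None
    genes: list[GeneModel] = []
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1,
                               size=n_here)
        needed = int(lengths.sum()) + config.gene_spacing * max(n_here - 1, 0)
        slack = config.chrom_length - needed
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_here} genes into {chrom} "
                f"(need {needed} bp, have {config.chrom_length})"
            )
        # split the slack into n_here+1 non-negative gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here)) if n_here else np.array([], dtype=int)
        extra = np.diff(np.concatenate([[0], cuts]))
        pos = 0
        for j in range(n_here):
            pos += int(extra[j]) + (config.gene_spacing if j else 0)
            start = pos
            end = start + int(lengths[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(GeneModel(f"g{gene_no:04d}", chrom, strand, start, end))
        if with_sequence:
            genome[chrom] = _random_sequence(config.chrom_length, rng)  # type: ignore[index]
    if with_sequence:
        for chrom in chrom_names:
            genome.setdefault(chrom, _random_sequence(config.chrom_length, rng))  # type: ignore[union-attr]
    return genome, genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SimConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[ExpressionRecord], dict[str, str]]:
    """Assign each gene expressed/silent and draw an RPKM on the right side
    of the cutoff (log-normal, resampled across the boundary)."""
    records: list[ExpressionRecord] = []
    classes: dict[str, str] = {}
    for g in genes:
        expressed = rng.random() < config.frac_expressed
        classes[g.gene_id] = "expressed" if expressed else "silent"
        if config.adversarial_expression and rng.random() < 0.1:
            # boundary mass: exactly the cutoff counts as expressed
            rpkm = config.rpkm_cutoff
            classes[g.gene_id] = "expressed"
            records.append(ExpressionRecord(g.gene_id, rpkm))
            continue
        median = (config.expressed_median_rpkm if expressed
                  else config.silent_median_rpkm)
        for _ in range(1000):
            rpkm = float(median * np.exp(rng.normal(0.0, config.rpkm_sigma)))
            if expressed and rpkm >= config.rpkm_cutoff:
                break
            if not expressed and rpkm < config.rpkm_cutoff:
                break
        else:  # pragma: no cover - astronomically unlikely with sane medians
            rpkm = config.rpkm_cutoff if expressed else config.rpkm_cutoff / 2
        records.append(ExpressionRecord(g.gene_id, rpkm))
    return records, classes


# ---------------------------------------------------------------------------
# TF peaks
# ---------------------------------------------------------------------------

def _truncnorm_draw(mu: float, sd: float, bound: int, rng: np.random.Generator) -> int:
    a, b = (-bound - mu) / sd, (bound - mu) / sd
    return int(round(float(sps.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))))


def _free_space(genes: list[GeneModel], chrom: str, length: int) -> list[tuple[int, int]]:
    spans = sorted((g.span_start, g.span_end) for g in genes if g.chrom == chrom)
    free: list[tuple[int, int]] = []
    cursor = 0
    for s, e in spans:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        free.append((cursor, length))
    return free


def generate_peaks(
    config: SimConfig,
    genes: list[GeneModel],
    classes: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[PeakSet, list[dict]]:
    """TF peaks with class-dependent TSS offsets plus background peaks.

    Each peak is linked to a uniformly chosen gene with probability
    ``frac_tss_linked``; its summit sits at TSS + offset in the gene's
    reading direction, the offset drawn from the class's truncated normal.
    Unlinked peaks land uniformly in gene-free space.  The ledger records
    the linked gene, the realized (possibly clip-adjusted) offset and the
    class label for every peak.
    """
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    free = {c: _free_space(genes, c, config.chrom_length) for c in chrom_names}
    free_weights = {
        c: np.array([e - s for s, e in iv], dtype=float) for c, iv in free.items()
    }
    peaks: list[Peak] = []
    ledger: list[dict] = []
    lo_w, hi_w = config.peak_width
    for i in range(config.n_peaks):
        pid = f"peak_{i + 1:05d}"
        width = int(rng.integers(lo_w, hi_w + 1))
        linked = bool(rng.random() < config.frac_tss_linked) and bool(genes)
        if linked:
            gene = genes[int(rng.integers(0, len(genes)))]
            cls = classes[gene.gene_id]
            mu, sd = config.offset_model[cls]
            offset = _truncnorm_draw(mu, sd, config.offset_bound, rng)
            summit = gene.tss + offset if gene.strand == "+" else gene.tss - offset
            summit = min(max(summit, 0), config.chrom_length - 1)
            # realized offset after clipping, in the gene's reading direction
            offset = summit - gene.tss if gene.strand == "+" else gene.tss - summit
            chrom = gene.chrom
        else:
            gene, cls, offset = None, "background", None
            weights_all = np.array(
                [free_weights[c].sum() for c in chrom_names], dtype=float
            )
            chrom = chrom_names[int(rng.choice(len(chrom_names),
                                               p=weights_all / weights_all.sum()))]
            ivs, w = free[chrom], free_weights[chrom]
            j = int(rng.choice(len(ivs), p=w / w.sum()))
            summit = int(rng.integers(ivs[j][0], ivs[j][1]))
        summit_offset = int(rng.integers(0, width))
        start = summit - summit_offset
        if start < 0:
            start = 0
        if start + width > config.chrom_length:
            start = config.chrom_length - width
        summit_offset = summit - start
        peaks.append(Peak(pid, chrom, start, start + width,
                          summit_offset=summit_offset))
        ledger.append({
            "peak_id": pid,
            "chrom": chrom,
            "summit": int(summit),
            "linked_gene": gene.gene_id if gene else None,
            "true_offset": offset,
            "class": cls,
            "planted": {},
        })
    _record_expected_assignments(ledger, genes, classes, config)
    return PeakSet("tfii", peaks), ledger


def _record_expected_assignments(
    ledger: list[dict],
    genes: list[GeneModel],
    classes: Mapping[str, str],
    config: SimConfig,
) -> None:
    """Brute-force nearest-gene truth (independent of the indexed pipeline
    path): minimize |summit - tss|, ties to the smallest gene_id."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for entry in ledger:
        gs = by_chrom.get(entry["chrom"], [])
        if not gs:
            entry.update(nearest_gene=None, nearest_distance=None,
                         nearest_status=None, proximity=None, orientation=None)
            continue
        point = entry["summit"]
        best = min(abs(point - g.tss) for g in gs)
        gene = min((g for g in gs if abs(point - g.tss) == best),
                   key=lambda g: g.gene_id)
        d = point - gene.tss if gene.strand == "+" else gene.tss - point
        prox = "proximal" if abs(d) <= config.proximal_threshold else "distal"
        entry.update(
            nearest_gene=gene.gene_id,
            nearest_distance=int(d),
            nearest_status=classes[gene.gene_id],
            proximity=prox,
            orientation=(("upstream" if d < 0 else "downstream")
                         if prox == "proximal" else None),
        )


def expected_class_counts(ledger_peaks: list[dict]) -> dict[str, int]:
    """Class counts the pipeline should reproduce, from the ledger truth."""
    counts = {cls: 0 for cls in
              ("expressed", "silent", "unknown", "proximal", "distal",
               "proximal_upstream", "proximal_downstream")}
    for e in ledger_peaks:
        counts[e["nearest_status"] or "unknown"] += 1
        if e["proximity"]:
            counts[e["proximity"]] += 1
        if e["orientation"]:
            counts[f"proximal_{e['orientation']}"] += 1
    return counts


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def _instantiate(pattern: IupacPattern, rng: np.random.Generator) -> str:
    return "".join(IUPAC_SETS[c][int(rng.integers(0, len(IUPAC_SETS[c])))]
                   for c in pattern.pattern.upper())


def _peak_label_set(entry: dict) -> set[str]:
    labels = {entry["class"]}
    if entry.get("proximity"):
        labels.add(entry["proximity"])
    return labels


def plant_motifs(
    genome: dict[str, str],
    ledger_peaks: list[dict],
    config: SimConfig,
    rng: np.random.Generator,
    patterns: Optional[Mapping[str, IupacPattern]] = None,
) -> dict[str, str]:
    """Write random instantiations of IUPAC patterns into summit windows.

    For each (pattern, class) rate, each matching peak receives an instance
    with that probability at a uniform position inside its summit window.
    When several class keys match a peak the maximum rate applies.  Planted
    instances never overwrite one another; windows too small for the pattern
    are skipped with a log entry.  Returns the modified genome and annotates
    the ledger in place.
    """
    patterns = patterns or _PATTERNS_BY_NAME
    buffers = {c: bytearray(s, "ascii") for c, s in genome.items()}
    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    half = (config.summit_window - 1) // 2
    for pname in sorted(config.motif_plant_rate):
        rates = config.motif_plant_rate[pname]
        pat = patterns[pname] if pname in patterns else IupacPattern(pname, pname)
        plen = len(pat)
        for entry in ledger_peaks:
            labels = _peak_label_set(entry)
            matching = [rates[k] for k in rates if k in labels]
            rate = max(matching) if matching else 0.0
            if rate == 0.0 or rng.random() >= rate:
                continue
            chrom = entry["chrom"]
            win_lo = max(entry["summit"] - half, 0)
            win_hi = min(win_lo + config.summit_window, len(buffers[chrom]))
            if win_hi - win_lo < plen:
                logger.info("plant_motifs: window of %s too small for %s; skipped",
                            entry["peak_id"], pname)
                continue
            placed = False
            for _ in range(50):
                pos = int(rng.integers(win_lo, win_hi - plen + 1))
                if all(pos + plen <= s or pos >= e for s, e in planted[chrom]):
                    placed = True
                    break
            if not placed:
                logger.info("plant_motifs: no free slot for %s in %s; skipped",
                            pname, entry["peak_id"])
                continue
            inst = _instantiate(pat, rng)
            buffers[chrom][pos : pos + plen] = inst.encode("ascii")
            planted[chrom].append((pos, pos + plen))
            entry["planted"][pname] = pos
    return {c: b.decode("ascii") for c, b in buffers.items()}


# ---------------------------------------------------------------------------
# Mark sets
# ---------------------------------------------------------------------------

def generate_marks(
    config: SimConfig,
    tf_peaks: PeakSet,
    rng: np.random.Generator,
) -> tuple[dict[str, PeakSet], dict]:
    """External mark sets: each TF peak seeds a jittered mark peak with
    probability q, plus uniform background peaks at the per-Mb rate."""
    marks: dict[str, PeakSet] = {}
    ledger: dict = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genome_mb = config.n_chrom * config.chrom_length / 1e6
    lo_w, hi_w = config.peak_width
    for mname in sorted(config.marks):
        q = config.marks[mname]
        peaks: list[Peak] = []
        seeded_from: list[str] = []
        for p in tf_peaks:
            if rng.random() < q:
                jitter = int(rng.integers(-config.mark_jitter, config.mark_jitter + 1))
                start = max(p.start + jitter, 0)
                end = min(p.end + jitter, config.chrom_length)
                if end <= start:
                    continue
                peaks.append(Peak(f"{mname}_s{len(peaks) + 1:05d}", p.chrom, start, end))
                seeded_from.append(p.peak_id)
        n_bg = int(rng.poisson(config.mark_background_per_mb * genome_mb))
        for j in range(n_bg):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            width = int(rng.integers(lo_w, hi_w + 1))
            start = int(rng.integers(0, config.chrom_length - width))
            peaks.append(Peak(f"{mname}_b{j + 1:05d}", chrom, start, start + width))
        marks[mname] = PeakSet(mname, peaks)
        ledger[mname] = {"q": q, "seeded_from": seeded_from, "n_background": n_bg}
    return marks, ledger


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, with_sequence: bool = True) -> SimResult:
    """Generate the full input bundle plus ground-truth ledger.

    One child random stream per artifact so the whole result is
    reproducible bit-for-bit under ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_genome, s_expr, s_peaks, s_motifs, s_marks = ss.spawn(5)
    genome, genes = generate_genome(config, np.random.default_rng(s_genome),
                                    with_sequence=with_sequence)
    expression, classes = generate_expression(config, genes,
                                              np.random.default_rng(s_expr))
    peaks, ledger_peaks = generate_peaks(config, genes, classes,
                                         np.random.default_rng(s_peaks))
    if with_sequence and config.motif_plant_rate:
        genome = plant_motifs(genome, ledger_peaks, config,
                              np.random.default_rng(s_motifs))
    marks, ledger_marks = generate_marks(config, peaks,
                                         np.random.default_rng(s_marks))
    ledger = {
        "config": _config_dict(config),
        "peaks": ledger_peaks,
        "marks": ledger_marks,
        "gene_classes": classes,
        "expected_class_counts": expected_class_counts(ledger_peaks),
    }
    return SimResult(config, genome, genes, expression, peaks, marks, ledger)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["gene_length"] = list(d["gene_length"])
    d["peak_width"] = list(d["peak_width"])
    d["offset_model"] = {k: list(v) for k, v in d["offset_model"].items()}
    return d


def write_simulation(sim: SimResult, outdir: str | Path) -> dict[str, str]:
    """Emit FASTA, gene TSV, expression TSV, narrowPeak files and the ledger.

    Returns the map of artifact name -> written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if sim.genome is not None:
        write_genome(sim.genome, outdir / "genome.fa")
        paths["fasta"] = str(outdir / "genome.fa")
    write_gene_models(sim.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    write_expression(sim.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    write_peaks(sim.peaks, outdir / "tf_peaks.narrowPeak", format="narrowpeak")
    paths["peaks"] = str(outdir / "tf_peaks.narrowPeak")
    marks_dir = outdir / "marks"
    marks_dir.mkdir(exist_ok=True)
    paths["marks"] = {}
    for mname, mset in sim.marks.items():
        mpath = marks_dir / f"{mname}.narrowPeak"
        write_peaks(mset, mpath, format="narrowpeak")
        paths["marks"][mname] = str(mpath)
    with open(outdir / "ledger.json", "w") as fh:
        json.dump(sim.ledger, fh, sort_keys=True, indent=2)
        fh.write("\n")
    paths["ledger"] = str(outdir / "ledger.json")
    return paths
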