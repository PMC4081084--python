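"""The simulator: determinism, calibration, planting and round-trips."""

import json

import numpy as np
import pytest

from peakscape import (
    SimConfig,
    read_expression,
    read_gene_models,
    read_genome,
    read_peaks,
    scan_iupac,
    simulate,
    write_simulation,
)
from peakscape.cooccupancy import overlap_fraction
from peakscape.synthetic_data import generate_genome


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=5, n_peaks=100, n_genes=30, n_chrom=2,
                        chrom_length=400_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_simulation(simulate(cfg), d1)
        write_simulation(simulate(cfg), d2)
        for rel in ("genome.fa", "genes.tsv", "expression.tsv",
                    "tf_peaks.narrowPeak", "marks/H3K4me3.narrowPeak",
                    "ledger.json"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        a = simulate(SimConfig(seed=1, n_peaks=50, n_genes=10, n_chrom=1,
                               chrom_length=200_000))
        b = simulate(SimConfig(seed=2, n_peaks=50, n_genes=10, n_chrom=1,
                               chrom_length=200_000))
        assert a.genome["chr1"] != b.genome["chr1"]


class TestGenome:
    def test_no_genes_gives_sequence_only(self):
        genome, genes = generate_genome(SimConfig(seed=0, n_genes=0, n_chrom=1,
                                                  chrom_length=10_000))
        assert genes == [] and len(genome["chr1"]) == 10_000

    def test_base_composition_near_uniform(self):
        genome, _ = generate_genome(SimConfig(seed=3, n_genes=0, n_chrom=1,
                                              chrom_length=1_000_000))
        seq = genome["chr1"]
        se = np.sqrt(0.25 * 0.75 / 1_000_000)
        for base in "ACGT":
            assert abs(seq.count(base) / 1_000_000 - 0.25) < 3 * se

    def test_genes_spaced_and_in_bounds(self):
        cfg = SimConfig(seed=7, n_genes=60, n_chrom=2, chrom_length=600_000)
        _, genes = generate_genome(cfg, with_sequence=False)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.span_start)
            for a, b in zip(gs, gs[1:]):
                assert b.span_start - a.span_end >= cfg.gene_spacing
            assert gs[0].span_start >= 0 and gs[-1].span_end <= cfg.chrom_length

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            generate_genome(SimConfig(seed=0, n_genes=100, n_chrom=1,
                                      chrom_length=50_000))


class TestPeaks:
    def test_degenerate_offset_model_places_summits_upstream(self):
        cfg = SimConfig(seed=9, n_peaks=100, n_genes=20, n_chrom=1,
                        chrom_length=500_000, frac_tss_linked=1.0,
                        offset_model={"expressed": (-300.0, 1.0),
                                      "silent": (-300.0, 1.0)},
                        motif_plant_rate={}, marks={})
        sim = simulate(cfg, with_sequence=False)
        genes = {g.gene_id: g for g in sim.genes}
        for e in sim.ledger["peaks"]:
            gene = genes[e["linked_gene"]]
            d = (e["summit"] - gene.tss if gene.strand == "+"
                 else gene.tss - e["summit"])
            assert abs(d + 300) <= 5  # strand-aware, ~300 bp upstream

    def test_zero_peaks_empty_set(self):
        sim = simulate(SimConfig(seed=0, n_peaks=0, n_genes=5, n_chrom=1,
                                 chrom_length=100_000), with_sequence=False)
        assert len(sim.peaks) == 0

    def test_mean_recovered_offset_within_3se(self):
        """Signed distances measured from emitted files match the configured
        offset mean to within 3 standard errors."""
        cfg = SimConfig(seed=21, n_peaks=2000, n_genes=100, n_chrom=2,
                        chrom_length=2_000_000, frac_tss_linked=1.0,
                        motif_plant_rate={}, marks={})
        sim = simulate(cfg, with_sequence=False)
        genes = {g.gene_id: g for g in sim.genes}
        for cls, (mu, sd) in cfg.offset_model.items():
            ds = []
            for e in sim.ledger["peaks"]:
                if sim.ledger["gene_classes"][e["linked_gene"]] != cls:
                    continue
                gene = genes[e["linked_gene"]]
                ds.append(e["summit"] - gene.tss if gene.strand == "+"
                          else gene.tss - e["summit"])
            se = sd / np.sqrt(len(ds))
            assert abs(np.mean(ds) - mu) < 3 * se


class TestExpression:
    def test_classes_sit_on_correct_side_of_cutoff(self, small_sim):
        classes = small_sim.ledger["gene_classes"]
        for rec in small_sim.expression:
            if classes[rec.gene_id] == "expressed":
                assert rec.rpkm >= small_sim.config.rpkm_cutoff
            else:
                assert rec.rpkm < small_sim.config.rpkm_cutoff

    def test_adversarial_mode_places_mass_at_cutoff(self):
        cfg = SimConfig(seed=2, n_genes=200, n_chrom=2, chrom_length=1_500_000,
                        n_peaks=0, adversarial_expression=True,
                        motif_plant_rate={}, marks={})
        sim = simulate(cfg, with_sequence=False)
        assert any(r.rpkm == cfg.rpkm_cutoff for r in sim.expression)


class TestPlanting:
    def test_rate_zero_leaves_genome_unchanged(self):
        kw = dict(seed=14, n_peaks=50, n_genes=10, n_chrom=1,
                  chrom_length=300_000, marks={})
        plain = simulate(SimConfig(motif_plant_rate={}, **kw))
        zero = simulate(SimConfig(
            motif_plant_rate={"TATA": {"expressed": 0.0, "silent": 0.0}}, **kw))
        assert zero.genome == plain.genome

    def test_rate_one_plants_in_every_window(self):
        cfg = SimConfig(seed=15, n_peaks=60, n_genes=12, n_chrom=1,
                        chrom_length=400_000, frac_tss_linked=1.0,
                        motif_plant_rate={"TATA": {"expressed": 1.0,
                                                   "silent": 1.0}},
                        marks={})
        sim = simulate(cfg)
        half = (cfg.summit_window - 1) // 2
        planted = 0
        for e in sim.ledger["peaks"]:
            if "TATA" not in e["planted"]:
                continue  # only skipped when no free slot remained
            planted += 1
            lo = max(e["summit"] - half, 0)
            window = sim.genome[e["chrom"]][lo : lo + cfg.summit_window]
            assert scan_iupac(window, "TATAAA", strands="plus")
        assert planted >= 0.9 * cfg.n_peaks  # collisions are rare

    def test_planted_instances_never_overlap(self, small_sim):
        seen = {}
        for e in small_sim.ledger["peaks"]:
            for pname, pos in e["planted"].items():
                length = {"TATA": 6, "BRE": 7}[pname]
                for s, t in seen.get(e["chrom"], []):
                    assert pos + length <= s or pos >= t
                seen.setdefault(e["chrom"], []).append((pos, pos + length))


class TestMarks:
    def _sim(self, q, bg):
        cfg = SimConfig(seed=31, n_peaks=200, n_genes=40, n_chrom=1,
                        chrom_length=1_000_000, motif_plant_rate={},
                        marks={"m": q}, mark_background_per_mb=bg)
        return simulate(cfg, with_sequence=False)

    def test_q1_no_background_full_overlap(self):
        sim = self._sim(1.0, 0.0)
        pct, _, _ = overlap_fraction(list(sim.peaks), list(sim.marks["m"]), 150)
        assert pct == 100.0

    def test_q0_no_background_zero_overlap(self):
        sim = self._sim(0.0, 0.0)
        assert len(sim.marks["m"]) == 0
        pct, _, _ = overlap_fraction(list(sim.peaks), list(sim.marks["m"]), 150)
        assert pct == 0.0

    def test_ledger_seeding_is_consistent(self):
        sim = self._sim(0.5, 0.0)
        seeded = set(sim.ledger["marks"]["m"]["seeded_from"])
        by_id = sim.peaks.by_id()
        marks = list(sim.marks["m"])
        for pid in seeded:
            assert any(abs(m.start - by_id[pid].start) <= sim.config.mark_jitter
                       and m.chrom == by_id[pid].chrom for m in marks)


class TestRoundTrip:
    def test_files_reproduce_in_memory_objects(self, small_sim, small_sim_paths):
        genes = read_gene_models(small_sim_paths["genes"], "tsv")
        assert genes == small_sim.genes
        peaks = read_peaks(small_sim_paths["peaks"], "narrowpeak")
        assert [(p.peak_id, p.chrom, p.start, p.end, p.summit_offset)
                for p in peaks] == \
               [(p.peak_id, p.chrom, p.start, p.end, p.summit_offset)
                for p in small_sim.peaks]
        genome = read_genome(small_sim_paths["fasta"])
        assert genome == small_sim.genome
        expr = read_expression(small_sim_paths["expression"])
        assert [r.gene_id for r in expr] == [r.gene_id for r in small_sim.expression]
        for a, b in zip(expr, small_sim.expression):
            assert a.rpkm == pytest.approx(b.rpkm, rel=1e-5)
        with open(small_sim_paths["ledger"]) as fh:
            ledger = json.load(fh)
        assert ledger["expected_class_counts"] == \
            small_sim.ledger["expected_class_counts"]
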