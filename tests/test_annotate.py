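"""Nearest-gene assignment, signed distances and location classification."""

import numpy as np
import pytest

from peakscape import (
    GeneModel,
    Peak,
    annotate_peaks,
    assign_nearest_gene,
    classify_genic_location,
    proximity_class,
    reference_point,
    signed_tss_distance,
    tss_window_profile,
)
from peakscape.annotate import GeneIndex, location_counts


def g(gene_id, chrom, strand, start, end):
    return GeneModel(gene_id, chrom, strand, start, end)


class TestReferencePoint:
    @pytest.mark.parametrize("start,end,summit,expected", [
        (100, 200, 50, 150),   # summit wins
        (100, 200, None, 150),  # midpoint
        (100, 201, None, 150),  # floor on odd width
    ])
    def test_cases(self, start, end, summit, expected):
        assert reference_point(Peak("p", "chr1", start, end, summit)) == expected


class TestSignedDistance:
    def test_upstream_on_plus_is_negative(self):
        assert signed_tss_distance(900, g("a", "chr1", "+", 1000, 2000)) == -100

    def test_upstream_of_minus_gene_lies_at_higher_coordinates(self):
        gene = g("a", "chr1", "-", 100, 200)  # tss = 199
        assert signed_tss_distance(250, gene) == -51

    def test_zero_at_tss(self):
        assert signed_tss_distance(1000, g("a", "chr1", "+", 1000, 2000)) == 0

    def test_strand_flip_negates_distance_from_mirrored_tss(self):
        """A minus-strand gene whose TSS sits at the same coordinate sees
        the same point at the negated distance."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = int(rng.integers(1000, 10_000))
            point = int(rng.integers(0, 20_000))
            plus = g("p", "chr1", "+", t, t + 500)
            minus = g("m", "chr1", "-", t - 500, t + 1)  # tss = t
            assert signed_tss_distance(point, minus) == -signed_tss_distance(point, plus)


class TestProximity:
    @pytest.mark.parametrize("d,expected", [
        (-1000, "proximal"),  # boundary inclusive
        (1001, "distal"),
        (0, "proximal"),
    ])
    def test_boundary(self, d, expected):
        assert proximity_class(d, 1000) == expected


class TestGenicLocation:
    def test_peak_over_tss(self):
        assert classify_genic_location(
            Peak("p", "chr1", 950, 1050), g("a", "chr1", "+", 1000, 2000)) == "TSS"

    def test_inside_span_is_intragenic(self):
        assert classify_genic_location(
            Peak("p", "chr1", 1200, 1300), g("a", "chr1", "+", 1000, 2000)) == "intragenic"

    def test_minus_gene_upstream_by_sign(self):
        # tss = 199; peak midpoint 350 -> distance -151 -> upstream
        assert classify_genic_location(
            Peak("p", "chr1", 300, 400), g("a", "chr1", "-", 100, 200)) == "upstream"

    def test_tes_precedence_over_intragenic(self):
        gene = g("a", "chr1", "+", 1000, 2000)  # tes = 1999
        assert classify_genic_location(Peak("p", "chr1", 1950, 2050), gene) == "TES"

    def test_every_peak_gets_one_category(self):
        rng = np.random.default_rng(9)
        genes = [g(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                   s := int(rng.integers(0, 90_000)), s + int(rng.integers(100, 5000)))
                 for i in range(30)]
        peaks = [Peak(f"p{i}", "chr1", s := int(rng.integers(0, 99_000)),
                      s + int(rng.integers(50, 900))) for i in range(200)]
        assignments = annotate_peaks(peaks, genes)
        counts = location_counts(assignments)
        assert sum(counts[loc] for loc in
                   ("TSS", "TES", "intragenic", "upstream", "downstream")) == 200
        assert counts["intergenic"] == counts["upstream"] + counts["downstream"]


class TestNearestGene:
    def test_single_gene(self):
        genes = [g("only", "chr1", "+", 5000, 6000)]
        a = assign_nearest_gene(Peak("p", "chr1", 100, 200), genes)
        assert a.gene_id == "only"

    def test_two_genes_abs_distance(self):
        genes = [g("near", "chr1", "+", 1000, 1500), g("far", "chr1", "+", 2000, 2500)]
        a = assign_nearest_gene(Peak("p", "chr1", 1350, 1450), genes)  # point 1400
        assert a.gene_id == "near" and a.signed_distance == 400

    def test_tie_breaks_lexicographically(self):
        genes = [g("zz", "chr1", "+", 900, 1000), g("aa", "chr1", "+", 1100, 1200)]
        # point 1000: distances 100 to both TSSs
        a = assign_nearest_gene(Peak("p", "chr1", 950, 1050), genes)
        assert a.gene_id == "aa"

    def test_no_genes_on_chromosome_unassigned(self):
        genes = [g("a", "chr2", "+", 0, 100)]
        a = assign_nearest_gene(Peak("p", "chr1", 0, 10), genes)
        assert a.gene_id == "unassigned"
        assert a.signed_distance is None and a.location is None

    def test_matches_brute_force_oracle(self):
        """Indexed assignment equals an exhaustive scan over all pairs."""
        rng = np.random.default_rng(17)
        genes = []
        for i in range(100):
            chrom = f"chr{1 + int(rng.integers(0, 3))}"
            start = int(rng.integers(0, 500_000))
            genes.append(g(f"g{i:03d}", chrom, "+" if rng.random() < 0.5 else "-",
                           start, start + int(rng.integers(200, 20_000))))
        peaks = []
        for i in range(100):
            chrom = f"chr{1 + int(rng.integers(0, 3))}"
            start = int(rng.integers(0, 520_000))
            width = int(rng.integers(100, 1000))
            summit = int(rng.integers(0, width)) if rng.random() < 0.5 else None
            peaks.append(Peak(f"p{i:03d}", chrom, start, start + width, summit))
        index = GeneIndex(genes)
        for p in peaks:
            got = assign_nearest_gene(p, index)
            point = reference_point(p)
            same = [x for x in genes if x.chrom == p.chrom]
            if not same:
                assert got.gene_id == "unassigned"
                continue
            best = min(abs(signed_tss_distance(point, x)) for x in same)
            want = min((x for x in same
                        if abs(signed_tss_distance(point, x)) == best),
                       key=lambda x: x.gene_id)
            assert got.gene_id == want.gene_id

    def test_invariant_to_gene_ordering(self):
        rng = np.random.default_rng(23)
        genes = [g(f"g{i}", "chr1", "+", s := int(rng.integers(0, 100_000)), s + 100)
                 for i in range(50)]
        peaks = [Peak(f"p{i}", "chr1", s := int(rng.integers(0, 100_000)), s + 50)
                 for i in range(50)]
        fwd = annotate_peaks(peaks, genes)
        rev = annotate_peaks(peaks, list(reversed(genes)))
        assert [a.gene_id for a in fwd] == [a.gene_id for a in rev]


class TestTssWindowProfile:
    def test_all_zero_distances_land_in_zero_bin(self):
        df = tss_window_profile({"expressed": [0] * 7}, window=2000, bin=100)
        row = df[(df.bin_lo <= 0) & (df.bin_hi > 0)]
        assert row["count_expressed"].iloc[0] == 7
        assert df["count_expressed"].sum() == 7

    def test_empty_input_all_zero(self):
        df = tss_window_profile({"silent": []})
        assert df["count_silent"].sum() == 0
        assert (df["density_silent"] == 0).all()

    def test_matches_naive_tally(self):
        rng = np.random.default_rng(31)
        dists = rng.integers(-3000, 3000, size=1000)
        df = tss_window_profile({"x": dists.tolist()}, window=2000, bin=100)
        for _, row in df.iterrows():
            lo, hi = row.bin_lo, row.bin_hi
            if hi == 2000:  # last bin takes the right edge
                naive = int(np.sum((dists >= lo) & (dists <= hi)))
            else:
                naive = int(np.sum((dists >= lo) & (dists < hi)))
            assert row["count_x"] == naive
        in_window = int(np.sum((dists >= -2000) & (dists <= 2000)))
        assert df["count_x"].sum() == in_window

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            tss_window_profile({}, window=2000, bin=300)
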