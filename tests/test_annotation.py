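import numpy as np
import pytest

from regcoloc.annotation import (
    GeneAnnotation,
    annotate_peaks,
    assign_target_genes,
    classify_context,
    read_gtf,
    tss_distance_summary,
    write_gtf,
)
from regcoloc.consensus import parse_merged_name
from regcoloc.intervals import GenomicInterval, IntervalSet

from conftest import make_gene


@pytest.fixture
def toy_annotation():
    """Two + strand genes and one - strand gene on chr1, one gene on chr2."""
    return GeneAnnotation(
        [
            make_gene("GeneA", "chr1", "+", 10_000, 16_000,
                      exons=[(10_000, 11_000), (15_000, 16_000)]),
            make_gene("GeneB", "chr1", "+", 50_000, 52_000),
            make_gene("GeneC", "chr1", "-", 80_000, 84_000,
                      exons=[(80_000, 81_000), (83_000, 84_000)]),
            make_gene("GeneD", "chr2", "+", 5_000, 9_000),
        ]
    )


def peak_at(center, chrom="chr1", half=100, name=None):
    return GenomicInterval(chrom, center - half, center + half, name=name)


class TestClassifyContext:
    def test_promoter_window_plus_strand(self, toy_annotation):
        # 500 bp 5' of a + strand TSS lies in the -1kb/+300bp promoter window
        assert classify_context(peak_at(10_000 - 500), toy_annotation) == "promoter"
        assert classify_context(peak_at(10_000 + 300), toy_annotation) == "promoter"
        assert classify_context(peak_at(10_000 + 301), toy_annotation) == "exonic"

    def test_promoter_window_minus_strand_is_mirrored(self, toy_annotation):
        tss = 84_000 - 1  # - strand TSS is the right edge
        assert classify_context(peak_at(tss + 500), toy_annotation) == "promoter"
        assert classify_context(peak_at(tss - 300), toy_annotation) == "promoter"
        assert classify_context(peak_at(tss - 301), toy_annotation) == "exonic"

    def test_exon_outside_promoter_is_exonic(self, toy_annotation):
        assert classify_context(peak_at(15_500), toy_annotation) == "exonic"

    def test_intron_and_intergenic(self, toy_annotation):
        assert classify_context(peak_at(13_000), toy_annotation) == "intronic"
        assert classify_context(peak_at(30_000), toy_annotation) == "intergenic"

    def test_unannotated_chromosome_is_intergenic(self, toy_annotation):
        assert classify_context(peak_at(1_000, chrom="chrUn"), toy_annotation) == "intergenic"

    def test_random_peaks_match_point_in_window_oracle(self, toy_annotation, rng):
        """Exhaustive per-gene window checks reproduce every context call."""
        def oracle(center):
            promoter, exonic, intronic = False, False, False
            for g in toy_annotation.genes:
                if g.chrom != "chr1":
                    continue
                for t in g.transcripts:
                    lo, hi = t.promoter_window()
                    if lo <= center <= hi:
                        promoter = True
                if g.start <= center < g.end:
                    if any(s <= center < e for t in g.transcripts for s, e in t.exons):
                        exonic = True
                    else:
                        intronic = True
            if promoter:
                return "promoter"
            if exonic:
                return "exonic"
            return "intronic" if intronic else "intergenic"

        for _ in range(200):
            c = int(rng.integers(200, 100_000))
            assert classify_context(peak_at(c), toy_annotation) == oracle(c)


class TestAssignTargetGenes:
    def test_intergenic_assigned_to_both_flanking_genes(self, toy_annotation):
        # center 30,000: GeneA TSS at 10,000 (left), GeneB TSS at 50,000 (right)
        got = {(a.gene, a.distance, a.side)
               for a in assign_target_genes(peak_at(30_000), toy_annotation)}
        assert got == {("GeneA", 20_000, "upstream"), ("GeneB", 20_000, "downstream")}

    def test_promoter_peak_single_host_gene(self, toy_annotation):
        assignments = assign_target_genes(peak_at(10_000 - 500), toy_annotation)
        assert len(assignments) == 1
        assert assignments[0].gene == "GeneA"
        assert assignments[0].distance == 500

    def test_exonic_peak_single_host_gene(self, toy_annotation):
        assignments = assign_target_genes(peak_at(15_500), toy_annotation)
        assert [a.gene for a in assignments] == ["GeneA"]

    def test_one_sided_when_no_gene_beyond(self, toy_annotation):
        # beyond every chr1 TSS: only an upstream gene exists
        assignments = assign_target_genes(peak_at(95_000), toy_annotation)
        assert len(assignments) == 1
        assert assignments[0].side == "upstream"

    def test_chromosome_without_genes_is_empty(self, toy_annotation):
        assert assign_target_genes(peak_at(500, chrom="chrUn"), toy_annotation) == []

    def test_assignment_count_invariants(self, sim_default):
        ann = sim_default["annotation"]
        truth = sim_default["truth"]
        for s in truth.sites[:60]:
            peak = GenomicInterval(s["chrom"], s["start"], s["end"], name=s["id"])
            assignments = assign_target_genes(peak, ann)
            ctx = classify_context(peak, ann)
            if ctx in ("promoter", "exonic"):
                assert len(assignments) == 1
            else:
                untied = [a for a in assignments if not a.tied]
                assert len(untied) <= 2

    def test_gene_list_permutation_invariance(self, toy_annotation, rng):
        genes = list(toy_annotation.genes)
        rng.shuffle(genes)
        shuffled = GeneAnnotation(genes)
        for c in (9_500, 13_000, 30_000, 81_500):
            a = {(x.gene, x.distance) for x in assign_target_genes(peak_at(c), toy_annotation)}
            b = {(x.gene, x.distance) for x in assign_target_genes(peak_at(c), shuffled)}
            assert a == b


class TestPublishedDistanceConsistency:
    """Worked examples from the published 22-gene direct-target table: two
    peaks assigned to the same gene on the same side must show distances
    differing by exactly their center difference."""

    @pytest.mark.parametrize(
        "peak_far,dist_far,peak_near,dist_near",
        [
            ("Merged-chr14-99739553-1", 41_644, "Merged-chr14-99739095-1", 41_186),  # Klf5
            ("Merged-chr12-86962262-1", 21_897, "Merged-chr12-86961177-1", 20_812),  # Jdp2
        ],
    )
    def test_distance_differences_follow_centers(self, peak_far, dist_far, peak_near, dist_near):
        chrom, center_near, _ = parse_merged_name(peak_near)
        _, center_far, _ = parse_merged_name(peak_far)
        tss = center_near - dist_near  # fix the TSS from the near peak's row
        gene = make_gene("Target", chrom, "+", tss, tss + 2_000)
        ann = GeneAnnotation([gene])
        for name, center, want in (
            (peak_near, center_near, dist_near),
            (peak_far, center_far, dist_far),
        ):
            peak = GenomicInterval(chrom, center - 200, center + 200, name=name)
            assert peak.center == center
            by_gene = {a.gene: a for a in assign_target_genes(peak, ann)}
            assert by_gene["Target"].distance == want
            assert by_gene["Target"].side == "upstream"
        assert abs(dist_far - dist_near) == abs(center_far - center_near)


class TestTssDistanceSummary:
    def test_peaks_on_tss_give_fraction_one(self, toy_annotation):
        peaks = IntervalSet([peak_at(10_000), peak_at(50_000)])
        s = tss_distance_summary(peaks, toy_annotation)
        assert s["fraction_within_threshold"] == 1.0
        assert s["distances"] == [0, 0]

    def test_no_genes_gives_fraction_zero(self):
        peaks = IntervalSet([peak_at(1_000)])
        s = tss_distance_summary(peaks, GeneAnnotation([]))
        assert s["fraction_within_threshold"] == 0.0

    def test_planted_offsets_recovered(self, toy_annotation):
        # two peaks inside 100 kb of a TSS, one beyond (chr1 TSS max 83,999)
        peaks = IntervalSet(
            [peak_at(12_000), peak_at(60_000), peak_at(83_999 + 150_000)]
        )
        s = tss_distance_summary(peaks, toy_annotation, threshold_bp=100_000)
        assert s["fraction_within_threshold"] == pytest.approx(2 / 3)


class TestGtfRoundTrip:
    def test_write_then_read_preserves_structure(self, tmp_path, sim_default):
        ann = sim_default["annotation"]
        sub = GeneAnnotation(ann.genes[:40])
        path = tmp_path / "genes.gtf"
        write_gtf(sub, path)
        back = read_gtf(path)
        assert len(back) == len(sub)
        for g in sub.genes:
            h = back.gene(g.symbol)
            assert (h.chrom, h.strand) == (g.chrom, g.strand)
            assert h.tss_positions == g.tss_positions
            assert h.transcripts[0].exons == g.transcripts[0].exons

    def test_context_counts_cover_all_peaks(self, sim_default):
        peaks = sim_default["replicates"][0]
        sub = IntervalSet(peaks.intervals[:50])
        table = annotate_peaks(sub, sim_default["annotation"])
        per_peak = table.drop_duplicates("peak")
        assert len(per_peak) == len(sub)
        assert set(per_peak["context"]) <= {"promoter", "exonic", "intronic", "intergenic"}
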