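"""Hi-C filtering, end annotation, linkage and library intersection."""

import pytest

from ncburden import hic
from ncburden.gene_catalog import GeneCatalog
from ncburden.genome_io import GeneFeature, HiCInteractionRecord
from ncburden.hic import (
    annotate_ends,
    filter_interactions,
    intersect_libraries,
    link_ncrna_coding,
    support_fraction,
)

from oracles import naive_overlapping


def rec(s1, s2, reads=10, p=0.005, chrom1="chr1", chrom2=None, b=5000):
    return HiCInteractionRecord(
        chrom1, s1, s1 + b, chrom2 or chrom1, s2, s2 + b, reads, p
    )


class TestFilterInteractions:
    def test_passing_record_kept(self):
        kept = filter_interactions([rec(0, 10_000)])
        assert len(kept) == 1 and kept[0].distance == 10_000

    def test_distance_bounds_strict(self):
        assert filter_interactions([rec(0, 5_000)]) == []           # exactly 5 kb: out
        assert len(filter_interactions([rec(0, 5_001)])) == 1       # just above: in
        assert filter_interactions([rec(0, 20_000_000)]) == []      # exactly 20 Mb: out
        assert len(filter_interactions([rec(0, 19_999_999)])) == 1

    def test_p_strict_reads_inclusive(self):
        assert filter_interactions([rec(0, 10_000, p=0.01)]) == []
        assert len(filter_interactions([rec(0, 10_000, p=0.009999)])) == 1
        assert filter_interactions([rec(0, 10_000, reads=9)]) == []
        assert len(filter_interactions([rec(0, 10_000, reads=10)])) == 1

    def test_trans_removed(self):
        assert filter_interactions([rec(0, 10_000, chrom2="chr2")]) == []

    def test_hand_filtered_fixture(self):
        records = [
            rec(0, 10_000),                      # keep
            rec(0, 5_000),                       # distance too small
            rec(0, 10_000, p=0.5),               # p too large
            rec(0, 10_000, reads=2),             # too few reads
            rec(0, 10_000, chrom2="chr2"),       # trans
            rec(50_000, 120_000),                # keep
            rec(0, 25_000_000),                  # too far
            rec(100_000, 200_000),               # keep
        ]
        assert len(filter_interactions(records)) == 3

    def test_idempotent(self):
        records = [rec(0, 10_000), rec(0, 10_000, p=0.5), rec(5000, 100_000)]
        once = filter_interactions(records)
        twice = filter_interactions([fi.record for fi in once])
        assert [fi.record for fi in twice] == [fi.record for fi in once]


def catalog_of(*genes):
    return GeneCatalog(genes=list(genes), source_priority=["test"])


class TestAnnotateEnds:
    def test_gene_inside_fragment_annotated(self):
        cat = catalog_of(GeneFeature("N1", "N1", "chr1", 1000, 3000))
        fi = filter_interactions([rec(0, 100_000)])
        out = annotate_ends(fi, cat)
        assert out[0].genes_end1 == ["N1"] and out[0].genes_end2 == []

    def test_nine_percent_overlap_not_annotated(self):
        # 10 kb gene overlapping the fragment by 900 bp: 9% < 10%
        cat = catalog_of(GeneFeature("N1", "N1", "chr1", 0, 10_000))
        fi = filter_interactions([rec(9_100, 100_000)])
        assert annotate_ends(fi, cat)[0].genes_end1 == []

    def test_exactly_ten_percent_annotated(self):
        cat = catalog_of(GeneFeature("N1", "N1", "chr1", 0, 10_000))
        fi = filter_interactions([rec(9_000, 100_000)])  # 1000/10000 = 10%
        assert annotate_ends(fi, cat)[0].genes_end1 == ["N1"]

    def test_matches_naive_scan(self):
        import numpy as np

        rng = np.random.default_rng(3)
        genes = [
            GeneFeature(f"N{i}", f"N{i}", "chr1", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 500_000, 80), rng.integers(500, 8000, 80))
            )
        ]
        cat = catalog_of(*genes)
        fis = filter_interactions(
            [rec(int(s), int(s) + 50_000) for s in rng.integers(0, 400_000, 30)]
        )
        for fi in annotate_ends(fis, cat):
            for frag, got in ((fi.record.end_a, fi.genes_end1), (fi.record.end_b, fi.genes_end2)):
                class F:
                    chrom, start, end = frag
                want = sorted(
                    g.gene_id for g in naive_overlapping(F, genes)
                    if (min(g.end, F.end) - max(g.start, F.start)) / g.length >= 0.10
                )
                assert got == want


class TestLinkage:
    NC = GeneFeature("N1", "N1", "chr1", 1000, 3000, biotype="lncRNA")
    CODING = GeneFeature("PC1", "PC1", "chr1", 100_000, 120_000, strand="+")

    def _linked(self, interactions, lib="lib1"):
        fis = annotate_ends(filter_interactions(interactions), catalog_of(self.NC))
        return link_ncrna_coding(fis, {"N1"}, catalog_of(self.CODING), library=lib)

    def test_ncrna_to_promoter_link(self):
        # end2 = [100000, 105000) covers the + strand promoter [98000, 102000)
        links = self._linked([rec(0, 100_000)])
        assert {(l.ncrna_id, l.coding_gene_id) for l in links} == {("N1", "PC1")}
        assert any(l.via_promoter for l in links)

    def test_gene_body_mode_also_reported(self):
        links = self._linked([rec(0, 100_000)])
        # the fragment covers 5 kb of the 20 kb gene body (25% >= 10%)
        assert any(not l.via_promoter for l in links)

    def test_no_coding_gene_no_link(self):
        fis = annotate_ends(filter_interactions([rec(0, 10_000)]), catalog_of(self.NC))
        links = link_ncrna_coding(fis, {"N1"}, catalog_of(self.CODING))
        assert links == []

    def test_hand_enumerated_links(self):
        other_nc = GeneFeature("N2", "N2", "chr1", 51_000, 53_000)
        cat = catalog_of(self.NC, other_nc)
        interactions = [
            rec(0, 100_000),        # N1 -> PC1 (promoter + body)
            rec(50_000, 100_000),   # N2 -> PC1
            rec(0, 50_000),         # N1 -> N2 only: no coding partner
            rec(200_000, 300_000),  # nothing annotated
        ]
        fis = annotate_ends(filter_interactions(interactions), cat)
        links = link_ncrna_coding(fis, {"N1", "N2"}, catalog_of(self.CODING))
        pairs = {(l.ncrna_id, l.coding_gene_id) for l in links}
        assert pairs == {("N1", "PC1"), ("N2", "PC1")}

    def test_minus_strand_promoter_at_end(self):
        minus = GeneFeature("PC2", "PC2", "chr1", 100_000, 120_000, strand="-")
        # TSS at 119999; fragment [115000, 120000) covers promoter [117999, 121999)
        fis = annotate_ends(filter_interactions([rec(0, 115_000)]), catalog_of(self.NC))
        links = link_ncrna_coding(fis, {"N1"}, catalog_of(minus))
        assert any(l.via_promoter for l in links)

    def test_referential_integrity(self):
        links = self._linked([rec(0, 100_000), rec(0, 100_000, reads=30)])
        for l in links:
            assert l.n_interactions >= 1


class TestIntersection:
    def test_identical_pair_common(self):
        a = filter_interactions([rec(0, 100_000)])
        b = filter_interactions([rec(0, 100_000, reads=50, p=1e-4)])
        common, _ = intersect_libraries(a, [], b, [])
        assert len(common) == 1

    def test_bin_shift_not_common(self):
        a = filter_interactions([rec(0, 100_000)])
        b = filter_interactions([rec(5_000, 100_000)])
        common, _ = intersect_libraries(a, [], b, [])
        assert common == []

    def test_unordered_pair_equality(self):
        a = filter_interactions([rec(0, 100_000)])
        b = filter_interactions(
            [HiCInteractionRecord("chr1", 100_000, 105_000, "chr1", 0, 5_000, 20, 0.001)]
        )
        common, _ = intersect_libraries(a, [], b, [])
        assert len(common) == 1

    def test_symmetric_and_counted(self):
        lib1 = filter_interactions([rec(0, 100_000), rec(0, 50_000), rec(10_000, 90_000),
                                    rec(0, 200_000), rec(0, 300_000)])
        lib2 = filter_interactions([rec(0, 100_000), rec(10_000, 90_000), rec(0, 300_000),
                                    rec(5_000, 400_000), rec(0, 500_000), rec(0, 600_000),
                                    rec(0, 700_000)])
        c12, _ = intersect_libraries(lib1, [], lib2, [])
        c21, _ = intersect_libraries(lib2, [], lib1, [])
        assert len(c12) == len(c21) == 3

    def test_dual_support_merge(self):
        nc = TestLinkage.NC
        coding = TestLinkage.CODING
        def links_for(lib):
            fis = annotate_ends(filter_interactions([rec(0, 100_000)]), catalog_of(nc))
            return link_ncrna_coding(fis, {"N1"}, catalog_of(coding), library=lib)
        _, merged = intersect_libraries([], links_for("lib1"), [], links_for("lib2"))
        assert all(l.library_support == {"lib1", "lib2"} for l in merged)


class TestSupportFraction:
    def _link(self, nc, libs=("lib1", "lib2")):
        return hic.GeneLink(nc, "PC1", True, frozenset(libs), 1)

    def test_hand_counted_fraction(self):
        links = [self._link("N1"), self._link("N2"), self._link("N9", libs=("lib1",))]
        summary = support_fraction(
            links, {"N1", "N2", "N3", "N4"}, [f"N{i}" for i in range(1, 11)],
            require_dual=True,
        )
        assert summary.n_supported_candidates == 2
        assert summary.fraction == pytest.approx(0.5)
        assert summary.fraction_all == pytest.approx(0.2)
        assert summary.enrichment.ratio == pytest.approx(0.5 / 0.2)

    def test_no_links_zero(self):
        summary = support_fraction([], {"N1"}, ["N1", "N2"], require_dual=False)
        assert summary.fraction == 0.0 and summary.enrichment is None

    def test_percent_rounding_of_reported_fraction(self):
        # 251 supported of 1030 candidates reads as 24% to the nearest integer
        links = [self._link(f"N{i}") for i in range(251)]
        candidates = {f"N{i}" for i in range(1030)}
        summary = support_fraction(links, candidates, [f"N{i}" for i in range(5000)],
                                   require_dual=True)
        assert round(100 * summary.fraction) == 24
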