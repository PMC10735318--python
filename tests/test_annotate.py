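"""Element classification, gene-relative geometry, and conserved-box
scanning over aligned segments."""

import pytest

from deepcne._seq import revcomp
from deepcne.annotate import (BUILTIN_MOTIFS, BoxMotif, classify_element,
                              relative_geometry, scan_boxes)
from deepcne.regions import AnnotationSet, GeneModel, GenomicInterval


def _gene_with_structure():
    # + strand gene: exon1 [1000,1400), intron [1400,2200), exon2 [2200,3000)
    # with 3' UTR [2600,3000)
    return GeneModel("g1", "chr1", 1000, 3000, "+",
                     exons=[(1000, 1400), (2200, 3000)],
                     utr3=[(2600, 3000)], utr5=[(1000, 1100)])


@pytest.fixture()
def ann():
    a = AnnotationSet()
    a.add_gene(_gene_with_structure())
    return a


class TestClassify:
    def test_tss_overlap_is_promoter(self, ann):
        cls = classify_element(GenomicInterval("chr1", 950, 1050), ann)
        assert cls.label == "promoter"

    def test_utr3_overlap(self, ann):
        cls = classify_element(GenomicInterval("chr1", 2700, 2800), ann)
        assert cls.label == "utr3"

    def test_wholly_inside_intron(self, ann):
        cls = classify_element(GenomicInterval("chr1", 1600, 1700), ann)
        assert cls.label == "intron"

    def test_partially_in_intron_is_not_intron(self, ann):
        cls = classify_element(GenomicInterval("chr1", 2100, 2300), ann)
        assert cls.label == "enhancer"

    def test_distant_element_is_enhancer(self, ann):
        cls = classify_element(GenomicInterval("chr1", 11_000, 11_100), ann)
        assert cls.label == "enhancer"

    def test_promoter_takes_precedence(self):
        # gene whose TSS window reaches into its own 3' UTR (tiny gene)
        a = AnnotationSet()
        a.add_gene(GeneModel("g2", "chr1", 1000, 1600, "+",
                             exons=[(1000, 1600)], utr3=[(1300, 1600)]))
        cls = classify_element(GenomicInterval("chr1", 1350, 1450), a)
        assert cls.label == "promoter"

    def test_minus_strand_tss_at_gene_end(self):
        a = AnnotationSet()
        a.add_gene(GeneModel("g3", "chr1", 5000, 8000, "-",
                             exons=[(5000, 8000)]))
        assert classify_element(GenomicInterval("chr1", 8100, 8200), a).label \
            == "promoter"
        assert classify_element(GenomicInterval("chr1", 5000, 5100), a,
                                tss_window=500).label == "enhancer"

    def test_no_annotation_flags_enhancer(self):
        cls = classify_element(GenomicInterval("chr1", 0, 100), None)
        assert cls.label == "enhancer" and "no-annotation" in cls.evidence

    def test_classification_is_total(self, ann):
        for s in range(0, 4000, 137):
            cls = classify_element(GenomicInterval("chr1", s, s + 60), ann)
            assert cls.label in ("promoter", "enhancer", "intron", "utr3")


class TestGeometry:
    def test_upstream_of_minus_gene_lies_after_gene_end(self):
        g = GeneModel("g1", "chr1", 1000, 2000, "-", exons=[(1000, 2000)])
        pos, orient = relative_geometry(GenomicInterval("chr1", 2500, 2600),
                                        g, ["+"])
        assert pos == "upstream" and orient == "same"

    def test_inverted_chain_flags_opposite(self):
        g = GeneModel("g1", "chr1", 1000, 2000, "+", exons=[(1000, 2000)])
        pos, orient = relative_geometry(GenomicInterval("chr1", 100, 200),
                                        g, ["+", "-"])
        assert pos == "upstream" and orient == "opposite"
        _, orient2 = relative_geometry(GenomicInterval("chr1", 100, 200),
                                       g, ["-", "-"])
        assert orient2 == "same"

    def test_reference_segment_is_same_by_definition(self):
        g = GeneModel("g1", "chr1", 1000, 2000, "+", exons=[(1000, 2000)])
        _, orient = relative_geometry(GenomicInterval("chr1", 1200, 1300),
                                      g, [])
        assert orient == "same"

    def test_missing_chain_is_unknown(self):
        g = GeneModel("g1", "chr1", 1000, 2000, "+", exons=[(1000, 2000)])
        pos, orient = relative_geometry(GenomicInterval("chr1", 1500, 1600),
                                        g, None)
        assert pos == "internal" and orient == "unknown"


def _aln(**seqs):
    return dict(seqs)


class TestScanBoxes:
    def test_ebox_perfect(self):
        occ = scan_boxes(_aln(a="TTCACGTGTT", b="TTCACGTGTT", c="TTCACGTGTT"))
        names = {(o.name, o.conservation) for o in occ}
        assert ("E-box", "perfect") in names

    def test_attgg_reports_reverse_strand_ccaat(self):
        occ = scan_boxes(_aln(a="GGATTGGAA", b="GGATTGGAA"))
        ccaat = [o for o in occ if o.name == "CCAAT"]
        assert ccaat and all(o.strand == "-" for o in ccaat)

    def test_carg_w_position_semantics(self):
        hits = scan_boxes(_aln(a="CCAATTTTGG"))
        assert any(o.name == "CArG" for o in hits)
        misses = scan_boxes(_aln(a="CCAATGTTGG"))
        assert not any(o.name == "CArG" for o in misses)

    def test_gap_counts_as_mismatch(self):
        occ = scan_boxes(_aln(a="CCAAT", b="CC-AT"), max_mismatch_species=1)
        ccaat = [o for o in occ if o.name == "CCAAT" and o.strand == "+"]
        assert len(ccaat) == 1
        assert ccaat[0].conservation == "near_perfect(1)"
        assert not scan_boxes(_aln(a="CCAAT", b="CC-AT"),
                              max_mismatch_species=0)

    def test_monotone_in_allowed_mismatches(self):
        aln = _aln(a="TTCACGTGTT", b="TTCACGAGTT", c="TTCACGTGTT")
        k0 = scan_boxes(aln, max_mismatch_species=0)
        k1 = scan_boxes(aln, max_mismatch_species=1)
        key = lambda o: (o.name, o.col_start, o.strand)
        assert {key(o) for o in k0} <= {key(o) for o in k1}

    def test_revcomp_consistency(self):
        """Scanning reverse-complemented segments swaps +/- reports per motif
        and preserves total counts."""
        aln = _aln(a="GGCCAATTTCTTTGCACGTGAT", b="GGCCAATTTCTTTGCACGTGAT")
        fwd = scan_boxes(aln)
        rc = scan_boxes({k: revcomp(v) for k, v in aln.items()})
        def counts(occs):
            out = {}
            for o in occs:
                out[o.name] = out.get(o.name, 0) + 1
            return out
        assert counts(fwd) == counts(rc)
        # non-palindromic motifs swap strands; self-complementary patterns
        # (E-box CAnnTG, CArG CCW6GG) are always reported forward
        palindromic = {"E-box", "CArG"}
        def strand_key(occs, flip):
            out = []
            for o in occs:
                s = o.strand
                if flip and o.name not in palindromic:
                    s = "+" if s == "-" else "-"
                out.append((o.name, s))
            return sorted(out)
        assert strand_key(fwd, flip=False) == strand_key(rc, flip=True)

    def test_unequal_columns_rejected(self):
        with pytest.raises(ValueError):
            scan_boxes(_aln(a="CCAAT", b="CCAATT"))

    def test_motif_validation(self):
        with pytest.raises(ValueError):
            BoxMotif("bad", "CCA")
        with pytest.raises(ValueError):
            BoxMotif("bad", "CCAXT")
        with pytest.raises(ValueError):
            BoxMotif("bad", "CCAAT", "sideways")
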