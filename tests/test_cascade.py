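"""The discovery cascade: nearest genes, the dual acceptance rule, staged
search E-value bookkeeping, and the reversed-genome control."""

import math

import numpy as np
import pytest

from deepcne._seq import random_seq, revcomp
from deepcne.align import AlignmentHit, default_scheme
from deepcne.cascade import (HomologyMap, accept_candidates, nearest_gene,
                             reversed_control, staged_search)
from deepcne.regions import (AnnotationSet, ConservedRegionSet, GeneModel,
                             GenomicInterval)
from deepcne.stats import GumbelParams, evalue, score_threshold


def _gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gid, chrom, start, end, strand, exons=[(start, end)])


def _ann(*genes):
    ann = AnnotationSet()
    for g in genes:
        ann.add_gene(g)
    return ann


def _hit(e, qs=100, qe=150, ts=5000, te=5050):
    h = AlignmentHit("chr1", qs, qe, "chr1", ts, te, "+", 100)
    h.evalue = e
    return h


class TestNearestGene:
    def test_containment_gives_zero(self):
        ann = _ann(_gene("g1", 1000, 2000))
        gid, d = nearest_gene(GenomicInterval("chr1", 1500, 1600), ann)
        assert (gid, d) == ("g1", 0)

    def test_upstream_of_plus_gene_is_negative(self):
        ann = _ann(_gene("g1", 10_000, 12_000, "+"))
        gid, d = nearest_gene(GenomicInterval("chr1", 9_400, 9_500), ann)
        assert (gid, d) == ("g1", -500)

    def test_strand_awareness(self):
        ann = _ann(_gene("g1", 10_000, 12_000, "-"))
        # 500 bases beyond the gene end = 5' side of a minus-strand gene
        gid, d = nearest_gene(GenomicInterval("chr1", 12_500, 12_600), ann)
        assert (gid, d) == ("g1", -500)

    def test_no_genes_returns_none(self):
        gid, d = nearest_gene(GenomicInterval("chr1", 0, 10), _ann())
        assert gid is None and d is None

    def test_matches_exhaustive_scan(self, rng):
        genes = []
        for k in range(30):
            s = int(rng.integers(0, 95_000))
            genes.append(_gene(f"g{k}", s, s + int(rng.integers(500, 3000)),
                               "+" if rng.random() < 0.5 else "-"))
        ann = _ann(*genes)
        for _ in range(200):
            s = int(rng.integers(0, 99_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(20, 500)))
            gid, d = nearest_gene(iv, ann)
            # independent exhaustive scan over all genes
            def gap(g):
                if iv.start < g.end and g.start < iv.end:
                    return 0
                return (g.start - iv.end) if iv.end <= g.start \
                    else (iv.start - g.end)
            best = min(genes, key=lambda g: (gap(g), g.start, g.gene_id))
            assert gid == best.gene_id
            assert abs(d) == gap(best)


class TestAcceptance:
    HOM = HomologyMap([("qgene", "tgene")])

    def _anns(self):
        q = _ann(_gene("qgene", 90, 400))
        t = _ann(_gene("tgene", 5100, 5400))
        return q, t

    def test_relaxed_with_homologous_neighbours_accepted(self):
        """A hit with E=0.46 whose nearest genes are homologs passes via the
        homolog-proximity path."""
        q, t = self._anns()
        out = accept_candidates([_hit(0.46)], q, t, self.HOM)
        assert len(out) == 1
        assert out[0].acceptance_path == "homolog_proximity"
        assert out[0].query_nearest_gene == "qgene"
        assert out[0].target_nearest_gene == "tgene"

    def test_relaxed_without_homology_rejected(self):
        q, t = self._anns()
        rejects = []
        out = accept_candidates([_hit(0.46)], q, t, HomologyMap([]),
                                rejects=rejects)
        assert out == [] and len(rejects) == 1

    def test_above_relaxed_always_rejected(self):
        q, t = self._anns()
        out = accept_candidates([_hit(11.0)], q, t, self.HOM)
        assert out == []

    def test_strict_path_needs_no_annotation(self):
        out = accept_candidates([_hit(5e-5)], None, None, None)
        assert len(out) == 1 and out[0].acceptance_path == "strict_evalue"

    def test_missing_annotation_warns_for_relaxed_candidates(self):
        with pytest.warns(UserWarning):
            out = accept_candidates([_hit(0.5), _hit(2e-5)], None, None, None)
        assert [c.acceptance_path for c in out] == ["strict_evalue"]

    def test_strict_path_recorded_when_both_apply(self):
        q, t = self._anns()
        out = accept_candidates([_hit(5e-5)], q, t, self.HOM)
        assert out[0].acceptance_path == "strict_evalue"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            accept_candidates([], None, None, None, strict=10, relaxed=1e-4)

    def test_threshold_monotonicity(self):
        """Accepted set at strict=1e-5 is a subset of the set at 1e-4."""
        q, t = self._anns()
        hits = [_hit(e) for e in (1e-6, 5e-5, 2e-4, 0.46, 3.0, 20.0)]
        tight = accept_candidates(hits, q, t, self.HOM, strict=1e-5)
        loose = accept_candidates(hits, q, t, self.HOM, strict=1e-4)
        tight_hits = {id(c.hit) for c in tight}
        loose_hits = {id(c.hit) for c in loose}
        assert tight_hits <= loose_hits


class TestStagedSearch:
    def test_evalue_linear_in_target_span(self, rng, default_gumbel):
        """The same alignment found against a 10x smaller target search space
        gets an E-value exactly 10x smaller."""
        sch = default_scheme()
        shared = random_seq(rng, 150)
        qg = {"chr1": random_seq(rng, 300) + shared + random_seq(rng, 300)}
        tg = {"chr1": random_seq(rng, 4000) + shared + random_seq(rng, 5850)}
        regions = ConservedRegionSet([GenomicInterval("chr1", 300, 450)], 750)
        full_hits, full_stage = staged_search(
            regions, qg, tg, sch, default_gumbel, 400)
        sub = ConservedRegionSet([GenomicInterval("chr1", 3800, 4800)], 10_000)
        sub_hits, sub_stage = staged_search(
            regions, qg, sub, sch, default_gumbel, 400,
            target_genome_for_subset=tg, full_target_length=10_000)
        top_full = full_hits[0]
        top_sub = sub_hits[0]
        assert top_full.score == top_sub.score
        assert top_full.evalue / top_sub.evalue == pytest.approx(10.0)
        assert sub_stage.reduction_applied == pytest.approx(10.0)
        # subset hit mapped back to genome coordinates
        assert (top_sub.target_start, top_sub.target_end) == \
            (top_full.target_start, top_full.target_end)

    def test_empty_query_regions(self, default_gumbel):
        regions = ConservedRegionSet([], 1000)
        hits, stage = staged_search(regions, {"chr1": "ACGT" * 100},
                                    {"chr1": "ACGT" * 100}, default_scheme(),
                                    default_gumbel, 100)
        assert hits == [] and stage.n_hits == 0

    def test_uncalibrated_rejected(self):
        regions = ConservedRegionSet([GenomicInterval("chr1", 0, 100)], 1000)
        with pytest.raises(ValueError):
            staged_search(regions, {"chr1": "A" * 200}, {"chr1": "A" * 200},
                          default_scheme(), None, 100)

    def test_cascade_consistency(self, default_gumbel):
        """Re-scoring the same alignment against the full genome multiplies
        the E-value by exactly the reduction factor."""
        score = 300
        e_sub = evalue(score, default_gumbel, 2_000, 500)
        e_full = evalue(score, default_gumbel, 2_000 * 59, 500)
        assert e_full / e_sub == pytest.approx(59.0, rel=1e-12)


class TestReversedControl:
    def test_reversal_is_not_complementation(self, rng, default_gumbel):
        """The control reverses the target base order only: a target carrying
        the *reversed* query yields a full-strength control hit, while the
        reverse complement must not."""
        sch = default_scheme()
        core = random_seq(rng, 200)
        qg = {"chr1": random_seq(rng, 100) + core + random_seq(rng, 100)}
        regions = ConservedRegionSet([GenomicInterval("chr1", 0, 400)], 400)
        t_reversed = {"chr1": random_seq(rng, 1000) + core[::-1]
                      + random_seq(rng, 1000)}
        t_revcomp = {"chr1": random_seq(rng, 1000) + revcomp(core)
                     + random_seq(rng, 1000)}
        nr_hit = reversed_control(regions, qg, t_reversed, sch,
                                  default_gumbel, 500, both_strands=False)
        nr_miss = reversed_control(regions, qg, t_revcomp, sch,
                                   default_gumbel, 500, both_strands=False)
        assert nr_hit.n_at_threshold >= 1
        assert nr_hit.min_evalue < 1e-10
        assert nr_miss.n_at_threshold == 0

    def test_reversed_target_finds_no_planted_elements(self, pipeline_run):
        """Searching the reversed invertebrate genome recovers none of the
        planted elements: every control hit is chance-level, far above the
        astronomically small E-values genuine planted alignments reach."""
        nr = pipeline_run.null_reports["mollusc"]
        strict_hits = [c for c in pipeline_run.candidates
                       if c.acceptance_path == "strict_evalue"]
        assert strict_hits, "pipeline should recover planted elements"
        best_real = min(c.hit.evalue for c in strict_hits)
        assert best_real < 1e-10
        assert nr.min_evalue > 1e-4


def test_homology_map_symmetry_and_duplicates():
    hm = HomologyMap([("a1", "b1"), ("a1", "b2")])
    assert hm.is_homolog("a1", "b1") and hm.is_homolog("b1", "a1")
    assert hm.homologs_of("a1") == {"b1", "b2"}
    assert not hm.is_homolog("a1", None)
    assert len(hm) == 2
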