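"""The synthetic-genome generator: sequence evolution, planted truth,
divergence calibration, determinism, and the load-bearing confounders."""

import numpy as np
import pandas as pd
import pytest

from deepcne._seq import encode
from deepcne.align import default_scheme
from deepcne.cascade import staged_search
from deepcne.regions import merge_hits_to_regions, subtract_annotated
from deepcne.stats import score_threshold
from deepcne.synthetic import (FixtureConfig, build_truth_set, evolve_sequence,
                               write_fixture)


class TestEvolveSequence:
    def test_zero_rate_is_identity(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=500))
        assert evolve_sequence(s, 0.0, 0.0, seed=3) == s

    def test_full_substitution_changes_every_base(self):
        out = evolve_sequence("ACGT" * 10, 1.0, 0.0, seed=1)
        assert all(a != b for a, b in zip("ACGT" * 10, out))

    def test_substitution_rate_calibrated(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=10_000))
        fracs = []
        for seed in range(10):
            out = evolve_sequence(s, 0.10, 0.0, seed=seed)
            mism = sum(a != b for a, b in zip(s, out)) / len(s)
            fracs.append(mism)
        assert np.mean(fracs) == pytest.approx(0.10, abs=0.01)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGTN", 0.1)
        with pytest.raises(ValueError):
            evolve_sequence("", 0.1)

    def test_deterministic(self):
        s = "ACGT" * 100
        assert evolve_sequence(s, 0.2, 0.05, seed=9) == \
            evolve_sequence(s, 0.2, 0.05, seed=9)

    def test_indels_change_length(self):
        s = "ACGT" * 500
        outs = {len(evolve_sequence(s, 0.0, 0.02, seed=k)) for k in range(5)}
        assert outs != {len(s)}


class TestBuildTruthSet:
    def test_element_counts(self):
        cfg = FixtureConfig(species_names=("a", "b"), n_gene_loci=3,
                            elements_per_locus=1, genome_length=60_000,
                            rna_gene_count=1, pseudogene_count=1, seed=2)
        fx = build_truth_set(cfg)
        reg = fx.truth[fx.truth.element_class == "regulatory"]
        assert (reg.groupby("species").size() == 3).all()

    def test_zero_divergence_gives_identical_elements(self):
        cfg = FixtureConfig(species_names=("a", "b"), n_gene_loci=3,
                            genome_length=60_000, regulatory_divergence=0.0,
                            inverted_element=False, seed=4)
        fx = build_truth_set(cfg)
        reg = fx.truth[fx.truth.element_class == "regulatory"]
        for eid, grp in reg.groupby("element_id"):
            seqs = {fx.genomes[r.species][r.chromosome][r.start:r.end]
                    for r in grp.itertuples()}
            assert len(seqs) == 1

    def test_divergence_calibration(self):
        """Mean pairwise identity of planted elements ~ 1 - 2*divergence
        (star tree, two branches) within 3 s.d. of binomial noise."""
        cfg = FixtureConfig(seed=13, inverted_element=False)
        fx = build_truth_set(cfg)
        d = cfg.regulatory_divergence
        reg = fx.truth[fx.truth.element_class == "regulatory"]
        sp_a, sp_b = cfg.species_names[:2]
        same = total = 0
        for eid, grp in reg.groupby("element_id"):
            ra = grp[grp.species == sp_a].iloc[0]
            rb = grp[grp.species == sp_b].iloc[0]
            a = fx.genomes[sp_a][ra.chromosome][ra.start:ra.end]
            b = fx.genomes[sp_b][rb.chromosome][rb.start:rb.end]
            same += sum(x == y for x, y in zip(a, b))
            total += len(a)
        identity = same / total
        expected = 1 - 2 * d
        sd = np.sqrt(expected * (1 - expected) / total)
        assert abs(identity - expected) <= 3 * sd + 4 * d * d / 3

    def test_determinism_byte_identical(self):
        cfg = FixtureConfig(seed=21, n_gene_loci=4, genome_length=80_000)
        fa = build_truth_set(cfg)
        fb = build_truth_set(cfg)
        assert fa.genomes == fb.genomes
        assert fa.truth.equals(fb.truth)
        assert fa.orthology.equals(fb.orthology)

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            build_truth_set(FixtureConfig(genome_length=30_000, n_gene_loci=10))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FixtureConfig(regulatory_divergence=0.3, background_divergence=0.2)
        with pytest.raises(ValueError):
            FixtureConfig(gc_content=1.5)
        with pytest.raises(ValueError):
            FixtureConfig(species_names=("only",))

    def test_single_inverted_element(self, default_fixture):
        tr = default_fixture.truth
        inv = tr[(tr.element_class == "regulatory") & (tr.strand == "-")]
        assert len(inv) == 1
        assert inv.iloc[0].species == default_fixture.config.species_names[-1]

    def test_truth_intervals_within_genomes(self, default_fixture):
        for r in default_fixture.truth.itertuples():
            glen = len(default_fixture.genomes[r.species][r.chromosome])
            assert 0 <= r.start < r.end <= glen


class TestWriteFixture:
    def test_roundtrip_through_own_readers(self, tmp_path, default_fixture):
        from deepcne import io as dio

        paths = write_fixture(default_fixture, tmp_path)
        for sp in default_fixture.config.species_names:
            assert dio.read_fasta(paths[f"fasta:{sp}"]) == \
                default_fixture.genomes[sp]
            assert dio.read_gff3(paths[f"gff3:{sp}"]) == \
                default_fixture.annotations[sp]
        assert dio.read_orthology(paths["orthology"]).equals(
            default_fixture.orthology)
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert truth.equals(default_fixture.truth)

    def test_fasta_line_width(self, tmp_path, default_fixture):
        paths = write_fixture(default_fixture, tmp_path)
        with open(paths["fasta:refvert"]) as fh:
            assert all(len(line.rstrip()) <= 80 for line in fh)

    def test_empty_annotations_write_header_only(self, tmp_path):
        from deepcne import io as dio
        from deepcne.regions import AnnotationSet

        path = tmp_path / "empty.gff3"
        dio.write_gff3(AnnotationSet(), path)
        content = open(path).read()
        assert content.startswith("##gff-version 3")
        assert dio.read_gff3(path) == AnnotationSet()


def test_confounders_are_load_bearing(default_fixture, default_gumbel):
    """With masking disabled, at least one coding or RNA-gene confounder is
    reported as a conserved hit at E <= 1e-4 -- proving the masking stage
    actually removes something that would otherwise contaminate results."""
    fx = default_fixture
    sch = default_scheme()
    ref, hub, target = fx.config.species_names
    g_hub, g_ref, g_t = fx.genomes[hub], fx.genomes[ref], fx.genomes[target]
    len_ref = sum(map(len, g_ref.values()))
    len_hub = sum(map(len, g_hub.values()))
    from deepcne.regions import ConservedRegionSet, GenomicInterval
    whole = ConservedRegionSet(
        [GenomicInterval(c, 0, len(s)) for c, s in g_hub.items()], len_hub)
    ms1 = score_threshold(default_gumbel, 2 * len_ref, len_hub, 1.0)
    s1_hits, _ = staged_search(whole, g_hub, g_ref, sch, default_gumbel, ms1)
    s1_hits = [h for h in s1_hits if h.evalue <= 1.0]
    unmasked = merge_hits_to_regions(s1_hits, "query", genome_length=len_hub)
    len_t = sum(map(len, g_t.values()))
    ms2 = score_threshold(default_gumbel, 2 * len_t, unmasked.total_span, 100.0)
    hits, _ = staged_search(unmasked, g_hub, g_t, sch, default_gumbel, ms2)
    conf = fx.truth[(fx.truth.species == hub)
                    & fx.truth.element_class.isin(["coding", "rna_gene"])]
    leaked = [
        h for h in hits if h.evalue <= 1e-4 and any(
            h.query_start < r.end and r.start < h.query_end
            for r in conf.itertuples())]
    assert leaked, "expected conserved coding/RNA confounders without masking"

    # and masking removes them: no confounder interval survives subtraction
    masked = subtract_annotated(unmasked, fx.annotations[hub])
    for iv in masked:
        for r in conf.itertuples():
            assert not (iv.start < r.end and r.start < iv.end
                        and r.element_class == "coding")
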