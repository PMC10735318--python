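"""Synthetic multi-species genomes with planted, slowly evolving features.

The generator emulates the input structure the discovery cascade assumes:
each of several species carries, near homologous genes, regulatory elements
that descend from a common ancestor and evolve slowly, embedded in fast or
unrelated background; protein-coding exons, structural-RNA genes and
pseudogenes are planted as *conserved confounders* -- they too survive
cross-species alignment, so the annotation-masking stage is load-bearing and
testable.  A star phylogeny (ancestor -> each species directly) is used: the
pipeline only performs pairwise searches, so a richer tree would add
parameters without adding test power.

Every planted feature is reported in a truth table for recall/precision
scoring.  Coordinates are 0-based half-open throughout; conversion to GFF3's
1-based inclusive convention happens only in the writers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._seq import composition_from_gc, decode, encode, random_codes, revcomp_codes
from .regions import AnnotationSet, GeneModel, GenomicInterval

#: element placements cycled across loci
PLACEMENTS = ("tss", "upstream", "intron", "utr3", "downstream")

#: truth-table classes
ELEMENT_CLASSES = ("regulatory", "coding", "rna_gene", "pseudogene")

RNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")

CHROM = "chr1"

_UPSTREAM_GAP = 1500
_DOWNSTREAM_GAP = 1500


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic fixture.

    Divergences are expected substitutions per site along one
    ancestor->species branch; two species are therefore separated by twice the
    branch value.  ``background_divergence`` may be the string "independent",
    in which case each species' non-feature DNA is drawn fresh (no detectable
    similarity) -- the regime assumed at deep evolutionary distances.
    """

    species_names: tuple[str, ...] = ("refvert", "slowfish", "mollusc")
    genome_length: int = 200_000
    n_gene_loci: int = 12
    elements_per_locus: int = 1
    element_length_range: tuple[int, int] = (120, 200)
    regulatory_divergence: float = 0.08
    background_divergence: float | str = "independent"
    coding_fraction: float = 0.03
    rna_gene_count: int = 2
    pseudogene_count: int = 2
    gc_content: float = 0.40
    indel_rate: float = 0.0
    indel_len_mean: float = 3.0
    conserved_feature_divergence: float | None = None
    inverted_element: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.species_names) < 2:
            raise ValueError("need at least two species")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("species names must be unique")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")
        if not 0.0 <= self.regulatory_divergence < 1.0:
            raise ValueError("regulatory_divergence must be in [0,1)")
        if isinstance(self.background_divergence, str):
            if self.background_divergence != "independent":
                raise ValueError(
                    "background_divergence must be a rate or 'independent'")
        elif not self.regulatory_divergence < self.background_divergence < 1.0:
            raise ValueError(
                "need regulatory_divergence < background_divergence < 1")
        lo, hi = self.element_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad element_length_range")
        if not 1 <= self.elements_per_locus <= len(PLACEMENTS):
            raise ValueError(
                f"elements_per_locus must be in 1..{len(PLACEMENTS)}")
        if self.n_gene_loci < 1:
            raise ValueError("need at least one gene locus")

    @property
    def feature_divergence(self) -> float:
        """Branch divergence of conserved confounders (CDS, RNA genes,
        pseudogenes); defaults to the regulatory rate so that they, too,
        survive conservation detection unless masked."""
        if self.conserved_feature_divergence is None:
            return self.regulatory_divergence
        return self.conserved_feature_divergence


def evolve_sequence(seq: str, subst_prob: float, indel_rate: float = 0.0,
                    indel_len_mean: float = 3.0, seed: int = 0) -> str:
    """Evolve a DNA string: independent per-site substitution to one of the
    other three bases with probability subst_prob, plus Poisson indel events
    with geometric lengths.  Deterministic given the seed."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    codes = encode(seq)
    if (codes > 3).any():
        bad = int(np.argmax(codes > 3))
        raise ValueError(f"non-ACGT base {seq[bad]!r} at position {bad}")
    if not 0.0 <= subst_prob <= 1.0:
        raise ValueError("subst_prob must be in [0,1]")
    rng = np.random.default_rng(seed)
    return decode(_evolve_codes(codes, subst_prob, indel_rate, indel_len_mean, rng))


def _evolve_codes(codes: np.ndarray, subst_prob: float, indel_rate: float,
                  indel_len_mean: float, rng: np.random.Generator) -> np.ndarray:
    n = len(codes)
    out = codes.copy()
    if subst_prob > 0 and n:
        hit = rng.random(n) < subst_prob
        k = int(hit.sum())
        if k:
            # +1..+3 mod 4: uniform over the three other bases
            out[hit] = (out[hit] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    if indel_rate > 0 and n:
        n_events = rng.poisson(indel_rate * n)
        if n_events:
            comp = np.bincount(codes, minlength=4).astype(float)
            comp = comp / comp.sum() if comp.sum() else np.full(4, 0.25)
            positions = np.sort(rng.integers(0, n + 1, size=n_events))[::-1]
            is_ins = rng.random(n_events) < 0.5
            lengths = rng.geometric(min(1.0, 1.0 / max(indel_len_mean, 1.0)),
                                    size=n_events)
            for pos, ins, ln in zip(positions, is_ins, lengths):
                if ins:
                    insert = random_codes(rng, int(ln), comp)
                    out = np.concatenate([out[:pos], insert, out[pos:]])
                else:
                    out = np.concatenate([out[:pos], out[pos + int(ln):]])
    return out


class _Planned(NamedTuple):
    start: int           # ancestral coordinate
    length: int
    kind: str            # "regulatory" | "coding" | "rna_gene" | "pseudogene" | "part_bg"
    seg_id: str
    part: tuple | None   # (locus_index, part_name) for gene-part membership
    info: dict


class Fixture(NamedTuple):
    """In-memory fixture: genomes, annotations, orthology, truth, config."""

    genomes: dict[str, dict[str, str]]
    annotations: dict[str, AnnotationSet]
    orthology: pd.DataFrame
    truth: pd.DataFrame
    config: FixtureConfig


def _gene_geometry(cfg: FixtureConfig):
    lo, hi = cfg.element_length_range
    cds_each = max(60, int(round(cfg.coding_fraction * cfg.genome_length
                                 / (2 * cfg.n_gene_loci))))
    return dict(
        cds_each=cds_each,
        utr5_len=max(120, hi + 20),
        intron_len=max(800, hi + 200),
        utr3_len=max(400, hi + 120),
    )


def _plan_locus(cfg, i, geo, elem_lens, placements):
    """Absolute ancestral positions of every feature of locus i."""
    strand = "+" if i % 2 == 0 else "-"
    spacing = cfg.genome_length // cfg.n_gene_loci
    hi = cfg.element_length_range[1]
    block_start = i * spacing
    gene_start = block_start + _UPSTREAM_GAP + hi + 600
    order = ["utr5", "cds1", "intron", "cds2", "utr3"]
    lens = {"utr5": geo["utr5_len"], "cds1": geo["cds_each"],
            "intron": geo["intron_len"], "cds2": geo["cds_each"],
            "utr3": geo["utr3_len"]}
    if strand == "-":
        order = order[::-1]
    part_start = {}
    pos = gene_start
    for p in order:
        part_start[p] = pos
        pos += lens[p]
    gene_end = pos

    plan: list[_Planned] = []
    embedded: dict[str, tuple[str, int]] = {}
    for placement, elen in zip(placements, elem_lens):
        eid = f"elem_L{i}_{placement}"
        info = dict(locus=i, placement=placement)
        if placement == "upstream":
            s = (gene_start - _UPSTREAM_GAP - elen if strand == "+"
                 else gene_end + _UPSTREAM_GAP)
            plan.append(_Planned(s, elen, "regulatory", eid, None, info))
        elif placement == "downstream":
            s = (gene_end + _DOWNSTREAM_GAP if strand == "+"
                 else gene_start - _DOWNSTREAM_GAP - elen)
            plan.append(_Planned(s, elen, "regulatory", eid, None, info))
        else:
            embedded[{"tss": "utr5", "intron": "intron", "utr3": "utr3"}[placement]] = \
                (placement, elen)

    for p in order:
        pstart, plen = part_start[p], lens[p]
        if p.startswith("cds"):
            plan.append(_Planned(pstart, plen, "coding", f"cds_L{i}_{p}",
                                 (i, p), dict(locus=i)))
            continue
        if p in embedded:
            placement, elen = embedded[p]
            eid = f"elem_L{i}_{placement}"
            if placement == "tss":
                # at the transcription start edge of the 5' UTR
                es = pstart if strand == "+" else pstart + plen - elen
            elif placement == "intron":
                es = pstart + 80
            else:  # utr3
                es = pstart + 50
            chunks = [(pstart, es - pstart, "part_bg"),
                      (es, elen, "regulatory"),
                      (es + elen, pstart + plen - (es + elen), "part_bg")]
            for ci, (cs, cl, ck) in enumerate(chunks):
                if cl <= 0:
                    continue
                sid = eid if ck == "regulatory" else f"L{i}.{p}.bg{ci}"
                inf = dict(locus=i, placement=placement) if ck == "regulatory" else {}
                plan.append(_Planned(cs, cl, ck, sid, (i, p), inf))
        else:
            plan.append(_Planned(pstart, plen, "part_bg", f"L{i}.{p}", (i, p), {}))

    # conserved confounders parked beyond the gene neighbourhood
    conf = gene_end + _DOWNSTREAM_GAP + hi + 400
    if i < cfg.rna_gene_count:
        rtype = RNA_TYPES[i % len(RNA_TYPES)]
        rlen = 300 if rtype == "rRNA" else 120
        plan.append(_Planned(conf, rlen, "rna_gene", f"rna{i}", None,
                             dict(rna_type=rtype)))
        conf += rlen + 300
    if i < cfg.pseudogene_count:
        plan.append(_Planned(conf, 400, "pseudogene", f"pg{i}", None, {}))
        conf += 700
    block_end = (i + 1) * spacing if i + 1 < cfg.n_gene_loci else cfg.genome_length
    if conf > block_end or gene_start - _UPSTREAM_GAP - hi < block_start:
        raise ValueError(
            "planted features overflow their locus block: increase "
            "genome_length or reduce feature sizes/counts")
    meta = dict(index=i, strand=strand, gene_start=gene_start,
                gene_end=gene_end, lens=lens)
    return plan, meta


def _plan_fixture(cfg: FixtureConfig, rng: np.random.Generator):
    geo = _gene_geometry(cfg)
    lo, hi = cfg.element_length_range
    plan: list[_Planned] = []
    loci_meta = []
    for i in range(cfg.n_gene_loci):
        placements = [PLACEMENTS[(i + j) % len(PLACEMENTS)]
                      for j in range(cfg.elements_per_locus)]
        elem_lens = [int(rng.integers(lo, hi + 1)) for _ in placements]
        lp, meta = _plan_locus(cfg, i, geo, elem_lens, placements)
        plan.extend(lp)
        loci_meta.append(meta)
    plan.sort(key=lambda f: f.start)
    last = 0
    for f in plan:
        if f.start < last:
            raise ValueError(f"planted features overlap near {f.seg_id}")
        last = f.start + f.length
    if last > cfg.genome_length:
        raise ValueError("planted features overflow the genome length")
    return plan, loci_meta


def build_truth_set(config: FixtureConfig) -> Fixture:
    """Generate per-species genomes, annotations, an orthology table and the
    planted-feature truth table.  Byte-identical for identical config+seed."""
    master = np.random.default_rng(config.seed)
    plan, loci_meta = _plan_fixture(config, master)
    comp = composition_from_gc(config.gc_content)
    independent = config.background_divergence == "independent"

    # ancestral sequences: features in plan order, then gap filler
    anc: dict[str, np.ndarray] = {}
    for f in plan:
        anc[f.seg_id] = random_codes(master, f.length, comp)

    inverted_elem = None
    inverted_species = config.species_names[-1] if config.inverted_element else None
    if config.inverted_element:
        regs = [f.seg_id for f in plan if f.kind == "regulatory"]
        if regs:
            inverted_elem = regs[-1]

    # gap (intergenic background) segments between planned features
    gaps = []
    cursor = 0
    for f in plan:
        if f.start > cursor:
            gaps.append((cursor, f.start))
        cursor = f.start + f.length
    if cursor < config.genome_length:
        gaps.append((cursor, config.genome_length))
    anc_gaps = {g: random_codes(master, g[1] - g[0], comp) for g in gaps}

    # assemble per species
    events = sorted(
        [(f.start, "feat", f) for f in plan] + [(g[0], "gap", g) for g in gaps])
    genomes, annotations = {}, {}
    truth_rows = []
    for sp_i, sp in enumerate(config.species_names):
        rng = np.random.default_rng([config.seed, 1000 + sp_i])
        pieces = []
        spans: dict[str, tuple[int, int]] = {}
        part_spans: dict[tuple, list[tuple[int, int]]] = {}
        cur = 0
        for _, etype, obj in events:
            if etype == "gap":
                a = anc_gaps[obj]
                piece = (random_codes(rng, len(a), comp) if independent
                         else _evolve_codes(a, config.background_divergence,
                                            config.indel_rate,
                                            config.indel_len_mean, rng))
            else:
                f = obj
                a = anc[f.seg_id]
                if f.kind == "part_bg":
                    piece = (random_codes(rng, len(a), comp) if independent
                             else _evolve_codes(a, config.background_divergence,
                                                0.0, 0.0, rng))
                else:
                    rate = (config.regulatory_divergence if f.kind == "regulatory"
                            else config.feature_divergence)
                    piece = _evolve_codes(a, rate, 0.0, 0.0, rng)
                    if f.seg_id == inverted_elem and sp == inverted_species:
                        piece = revcomp_codes(piece)
                spans[f.seg_id] = (cur, cur + len(piece))
                if f.part is not None:
                    part_spans.setdefault(f.part, []).append((cur, cur + len(piece)))
            pieces.append(piece)
            cur += len(piece)
        genomes[sp] = {CHROM: decode(np.concatenate(pieces))}
        annotations[sp] = _annotation_for_species(sp, spans, part_spans,
                                                  plan, loci_meta)
        truth_rows.extend(
            _truth_for_species(sp, spans, plan, inverted_elem, inverted_species))

    truth = pd.DataFrame(truth_rows, columns=[
        "element_id", "species", "chromosome", "start", "end", "strand",
        "locus_id", "element_class", "placement"])
    orows = []
    for i in range(config.n_gene_loci):
        for a, b in itertools.combinations(config.species_names, 2):
            orows.append((f"{a}_g{i}", f"{b}_g{i}"))
    orthology = pd.DataFrame(orows, columns=["query_gene_id", "target_gene_id"])
    return Fixture(genomes, annotations, orthology, truth, config)


def _annotation_for_species(sp, spans, part_spans, plan, loci_meta) -> AnnotationSet:
    ann = AnnotationSet()
    for meta in loci_meta:
        i = meta["index"]
        pspan = {}
        for p in ("utr5", "cds1", "intron", "cds2", "utr3"):
            ivs = part_spans[(i, p)]
            pspan[p] = (min(s for s, _ in ivs), max(e for _, e in ivs))
        gstart = min(s for s, _ in pspan.values())
        gend = max(e for _, e in pspan.values())
        exon1 = (min(pspan["utr5"][0], pspan["cds1"][0]),
                 max(pspan["utr5"][1], pspan["cds1"][1]))
        exon2 = (min(pspan["cds2"][0], pspan["utr3"][0]),
                 max(pspan["cds2"][1], pspan["utr3"][1]))
        strand = meta["strand"]
        gene = GeneModel(gene_id=f"{sp}_g{i}", chromosome=CHROM,
                         start=gstart, end=gend, strand=strand,
                         exons=sorted([exon1, exon2]),
                         utr3=[pspan["utr3"]], utr5=[pspan["utr5"]])
        ann.add_gene(gene)
        ann.add_interval(GenomicInterval(CHROM, gstart, gend, strand, "gene"))
        for ex in sorted([exon1, exon2]):
            ann.add_interval(GenomicInterval(CHROM, ex[0], ex[1], strand, "exon"))
        for c in ("cds1", "cds2"):
            ann.add_interval(GenomicInterval(CHROM, *pspan[c], strand, "CDS"))
        ann.add_interval(GenomicInterval(CHROM, *pspan["utr3"], strand,
                                         "three_prime_UTR"))
        ann.add_interval(GenomicInterval(CHROM, *pspan["utr5"], strand,
                                         "five_prime_UTR"))
    for f in plan:
        if f.kind == "rna_gene":
            s, e = spans[f.seg_id]
            ann.add_interval(GenomicInterval(CHROM, s, e, "+", f.info["rna_type"]))
        elif f.kind == "pseudogene":
            s, e = spans[f.seg_id]
            ann.add_interval(GenomicInterval(CHROM, s, e, "+", "pseudogene"))
    return ann


def _truth_for_species(sp, spans, plan, inverted_elem, inverted_species):
    rows = []
    for f in plan:
        if f.kind not in ("regulatory", "coding", "rna_gene", "pseudogene"):
            continue
        s, e = spans[f.seg_id]
        strand = "+"
        if f.kind == "regulatory" and f.seg_id == inverted_elem and sp == inverted_species:
            strand = "-"
        placement = f.info.get("placement",
                               "cds" if f.kind == "coding" else "intergenic")
        locus = f.info.get("locus", -1)
        rows.append((f.seg_id, sp, CHROM, s, e, strand,
                     f"L{locus}", f.kind, placement))
    return rows


def write_fixture(fixture: Fixture, out_dir) -> dict[str, str]:
    """Write the fixture as FASTA + GFF3 per species, orthology TSV, truth TSV
    and truth BED.  Returns the paths written, keyed by role."""
    import os

    from . import io as dio

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for sp, genome in fixture.genomes.items():
        fa = os.path.join(out_dir, f"{sp}.fa")
        dio.write_fasta(genome, fa)
        paths[f"fasta:{sp}"] = fa
        gff = os.path.join(out_dir, f"{sp}.gff3")
        dio.write_gff3(fixture.annotations[sp], gff)
        paths[f"gff3:{sp}"] = gff
    orth = os.path.join(out_dir, "orthology.tsv")
    fixture.orthology.to_csv(orth, sep="\t", index=False)
    paths["orthology"] = orth
    truth_tsv = os.path.join(out_dir, "truth.tsv")
    fixture.truth.to_csv(truth_tsv, sep="\t", index=False)
    paths["truth"] = truth_tsv
    bed = os.path.join(out_dir, "truth.bed")
    ivs = [GenomicInterval(r.chromosome, r.start, r.end, r.strand,
                           f"{r.element_id}|{r.species}")
           for r in fixture.truth.itertuples()]
    dio.write_bed(ivs, bed)
    paths["truth_bed"] = bed
    return paths
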