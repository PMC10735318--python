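"""Interval algebra over genomic coordinates (0-based, half-open).

Conserved regions are built by projecting alignment hits onto one side and
merging; annotated coding/RNA/pseudogene DNA is subtracted before the next
search stage; the ratio genome_length / remaining span is the search-space
reduction factor that drives the cascade's sensitivity gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

#: closed vocabulary of annotation categories
CATEGORIES = frozenset({
    "CDS", "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "pseudogene",
    "gene", "exon", "five_prime_UTR", "three_prime_UTR",
})

#: what the pipeline masks out of conserved regions: DNA whose conservation
#: is explained by coding (or formerly coding) function
DEFAULT_EXCLUDED = frozenset({
    "CDS", "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "pseudogene",
})


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int
    end: int
    strand: str | None = None
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chromosome == other.chromosome
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """A gene with its transcription start, exon structure and UTRs."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start position (0-based base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _)
                in zip(ex[:-1], ex[1:]) if a_end < b_start]


class AnnotationSet:
    """Categorised intervals plus gene models for one genome."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (),
                 genes: Iterable[GeneModel] = ()):
        self.intervals: list[GenomicInterval] = []
        for iv in intervals:
            if iv.label not in CATEGORIES:
                raise ValueError(f"unknown annotation category {iv.label!r}")
            self.intervals.append(iv)
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            self.genes[g.gene_id] = g

    def add_interval(self, iv: GenomicInterval) -> None:
        if iv.label not in CATEGORIES:
            raise ValueError(f"unknown annotation category {iv.label!r}")
        self.intervals.append(iv)

    def add_gene(self, gene: GeneModel) -> None:
        self.genes[gene.gene_id] = gene

    def by_category(self, categories: Iterable[str]) -> list[GenomicInterval]:
        cats = set(categories)
        unknown = cats - CATEGORIES
        if unknown:
            raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
        return [iv for iv in self.intervals if iv.label in cats]

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return sorted((g for g in self.genes.values() if g.chromosome == chromosome),
                      key=lambda g: (g.start, g.gene_id))

    def __eq__(self, other):
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        key = lambda iv: (iv.chromosome, iv.start, iv.end, iv.label or "", iv.strand or "")
        return (sorted(self.intervals, key=key) == sorted(other.intervals, key=key)
                and self.genes == other.genes)


def _merge_sorted(pairs: list[tuple[int, int]], merge_gap: int = 0) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1] + merge_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class ConservedRegionSet:
    """Sorted, non-overlapping intervals with genome-fraction bookkeeping."""

    def __init__(self, intervals: Iterable[GenomicInterval], genome_length: int,
                 merge_gap: int = 0):
        if genome_length <= 0:
            raise ValueError("genome_length must be positive")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
        self.intervals: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            for s, e in _merge_sorted(by_chrom[chrom], merge_gap):
                self.intervals.append(GenomicInterval(chrom, s, e))
        self.genome_length = int(genome_length)

    @property
    def total_span(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def genome_fraction(self) -> float:
        return self.total_span / self.genome_length

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def merge_hits_to_regions(hits, side: str, merge_gap: int = 0,
                          genome_length: int | None = None) -> ConservedRegionSet:
    """Project alignment hits onto one side and merge overlapping (or
    within-merge_gap) projections into strand-less conserved regions."""
    if side not in ("query", "target"):
        raise ValueError("side must be 'query' or 'target'")
    ivs = []
    for h in hits:
        if side == "query":
            ivs.append(GenomicInterval(h.query_id, h.query_start, h.query_end))
        else:
            ivs.append(GenomicInterval(h.target_id, h.target_start, h.target_end))
    if genome_length is None:
        genome_length = max((iv.end for iv in ivs), default=1)
    return ConservedRegionSet(ivs, genome_length, merge_gap)


def subtract_annotated(regions: ConservedRegionSet, ann: AnnotationSet,
                       excluded: Iterable[str] = DEFAULT_EXCLUDED,
                       min_length: int = 20) -> ConservedRegionSet:
    """Remove every base overlapping an excluded-category annotation; drop
    fragments shorter than min_length."""
    masks: dict[str, list[tuple[int, int]]] = {}
    for iv in ann.by_category(excluded):
        masks.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    masks = {c: _merge_sorted(v) for c, v in masks.items()}
    out: list[GenomicInterval] = []
    for iv in regions:
        pieces = [(iv.start, iv.end)]
        for ms, me in masks.get(iv.chromosome, ()):
            nxt = []
            for s, e in pieces:
                if me <= s or ms >= e:
                    nxt.append((s, e))
                    continue
                if s < ms:
                    nxt.append((s, ms))
                if me < e:
                    nxt.append((me, e))
            pieces = nxt
        for s, e in pieces:
            if e - s >= min_length:
                out.append(GenomicInterval(iv.chromosome, s, e))
    return ConservedRegionSet(out, regions.genome_length)


def reduction_factor(regions: ConservedRegionSet) -> float:
    """Search-space reduction: genome_length / conserved span (1/fraction)."""
    span = regions.total_span
    if span == 0:
        raise ValueError("conserved span is zero: reduction factor undefined")
    return regions.genome_length / span


def region_key(iv: GenomicInterval) -> str:
    return f"{iv.chromosome}:{iv.start}-{iv.end}"


def parse_region_key(key: str) -> GenomicInterval:
    chrom, rng = key.rsplit(":", 1)
    s, e = rng.split("-")
    return GenomicInterval(chrom, int(s), int(e))


def extract_region_sequences(regions: ConservedRegionSet,
                             genome: dict[str, str]) -> dict[str, str]:
    """Slice region sequences out of a genome, keyed 'chrom:start-end' so that
    hits against them can be mapped back to genome coordinates."""
    out: dict[str, str] = {}
    for iv in regions:
        if iv.chromosome not in genome:
            raise ValueError(f"region chromosome {iv.chromosome!r} not in genome")
        seq = genome[iv.chromosome]
        if iv.end > len(seq):
            raise ValueError(
                f"region {region_key(iv)} outside chromosome (length {len(seq)})")
        out[region_key(iv)] = seq[iv.start:iv.end]
    return out
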