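"""The discovery cascade: staged searches with search-space-aware E-values,
the dual acceptance rule (strict E-value, or relaxed E-value near homologous
genes), and the reversed-genome negative control.

The central bookkeeping principle: each hit's E-value uses the *actual*
search-space lengths -- the summed span of the conserved query regions and
the target length (doubled when both strands are searched).  Restricting
either side to a conserved subset therefore buys a proportional E-value
gain, which is what lets weak but genuine deep-homology signals clear the
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentHit, ScoringScheme, local_align
from .regions import (AnnotationSet, ConservedRegionSet, GenomicInterval,
                      extract_region_sequences, parse_region_key)
from .stats import GumbelParams, evalue

STRICT_EVALUE = 1e-4
RELAXED_EVALUE = 10.0


@dataclass
class SearchStage:
    """Search-space bookkeeping for one staged search."""

    query_description: str
    target_description: str
    n: int                      # query-side search length (bases)
    m: int                      # target-side search length (bases)
    both_strands: bool = True
    min_score: int = 0
    reduction_applied: float = 1.0
    n_hits: int = 0

    @property
    def m_effective(self) -> int:
        return 2 * self.m if self.both_strands else self.m

    def __post_init__(self):
        if self.n <= 0 or self.m <= 0:
            raise ValueError("search lengths must be positive")
        if self.reduction_applied < 1.0 - 1e-9:
            raise ValueError("reduction_applied must be >= 1")


class HomologyMap:
    """Symmetric lookup of homologous gene-ID pairs; genes may have several
    homologs (retained duplicates)."""

    def __init__(self, pairs):
        self._pairs: set[frozenset] = set()
        self._by_gene: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "HomologyMap":
        return cls(zip(df["query_gene_id"], df["target_gene_id"]))

    def add(self, a: str, b: str) -> None:
        self._pairs.add(frozenset((a, b)))
        self._by_gene.setdefault(a, set()).add(b)
        self._by_gene.setdefault(b, set()).add(a)

    def is_homolog(self, a: str | None, b: str | None) -> bool:
        if a is None or b is None:
            return False
        return frozenset((a, b)) in self._pairs

    def homologs_of(self, gene: str) -> set[str]:
        return set(self._by_gene.get(gene, ()))

    def __len__(self):
        return len(self._pairs)


@dataclass
class CandidateElement:
    """An accepted hit with its gene context; classification and geometry are
    filled in by the annotation layer."""

    hit: AlignmentHit
    query_nearest_gene: str | None
    query_gene_distance: int | None
    target_nearest_gene: str | None
    target_gene_distance: int | None
    acceptance_path: str        # "strict_evalue" | "homolog_proximity"
    element_class: str | None = None
    class_evidence: str | None = None
    position: str | None = None
    orientation: str | None = None
    motif_occurrences: list = field(default_factory=list)

    def __post_init__(self):
        if self.acceptance_path not in ("strict_evalue", "homolog_proximity"):
            raise ValueError(f"unknown acceptance path {self.acceptance_path!r}")


@dataclass
class NullReport:
    """Outcome of a reversed-target negative control."""

    threshold: float
    n_at_threshold: int
    min_evalue: float
    evalues: list[float]
    stage: SearchStage


def staged_search(query_regions: ConservedRegionSet, query_genome: dict[str, str],
                  target, scheme: ScoringScheme, gumbel: GumbelParams,
                  min_score: int, both_strands: bool = True, *,
                  target_genome_for_subset: dict[str, str] | None = None,
                  full_query_length: int | None = None,
                  full_target_length: int | None = None,
                  query_description: str = "query regions",
                  target_description: str = "target",
                  **engine) -> tuple[list[AlignmentHit], SearchStage]:
    """Search conserved query regions against a target genome (or a target
    that is itself a conserved-region subset), assigning E-values with the
    true search-space lengths and mapping hits back to genome coordinates.

    ``target`` is either a {chrom: seq} genome dict, or a ConservedRegionSet
    (with ``target_genome_for_subset`` supplying sequence).
    """
    if gumbel is None:
        raise ValueError("staged_search requires calibrated Gumbel parameters")
    if not query_regions.intervals or query_regions.total_span == 0:
        n = max(query_regions.total_span, 1) if query_regions.intervals else 1
        stage = SearchStage(query_description, target_description,
                            n=max(n, 1), m=1, both_strands=both_strands,
                            min_score=min_score)
        return [], stage

    qseqs = extract_region_sequences(query_regions, query_genome)
    n = query_regions.total_span

    target_is_subset = isinstance(target, ConservedRegionSet)
    if target_is_subset:
        if target_genome_for_subset is None:
            raise ValueError("target region set needs target_genome_for_subset")
        tseqs = extract_region_sequences(target, target_genome_for_subset)
        m = target.total_span
    else:
        tseqs = target
        m = sum(len(s) for s in target.values())

    fq = full_query_length if full_query_length is not None else n
    fm = full_target_length if full_target_length is not None else m
    reduction = max(1.0, (fq / n) * (fm / m))

    hits = local_align(qseqs, tseqs, scheme, min_score,
                       both_strands=both_strands, **engine)
    m_eff = 2 * m if both_strands else m
    mapped = []
    for h in hits:
        h.evalue = evalue(h.score, gumbel, m_eff, n)
        mapped.append(_map_hit_back(h, query_side=True,
                                    target_side=target_is_subset))
    mapped.sort(key=lambda h: (h.evalue, -h.score, h.target_id, h.target_start,
                               h.query_id, h.query_start))
    stage = SearchStage(query_description, target_description, n=n, m=m,
                        both_strands=both_strands, min_score=min_score,
                        reduction_applied=reduction, n_hits=len(mapped))
    return mapped, stage


def _map_hit_back(h: AlignmentHit, query_side: bool, target_side: bool) -> AlignmentHit:
    """Rewrite region-keyed coordinates ('chrom:start-end') back to genome
    coordinates.  Query-side blocks shift with the query offset; target-side
    '-' hits keep reverse-strand block coordinates, which stay valid only
    relative to the *region*, so the offset is folded in via the region end."""
    if query_side and ":" in h.query_id:
        iv = parse_region_key(h.query_id)
        off = iv.start
        h.query_id = iv.chromosome
        h.query_start += off
        h.query_end += off
        h.aligned_blocks = [(q + off, t, ln) for q, t, ln in h.aligned_blocks]
    if target_side and ":" in h.target_id:
        iv = parse_region_key(h.target_id)
        h.target_id = iv.chromosome
        if h.strand == "+":
            h.aligned_blocks = [(q, t + iv.start, ln) for q, t, ln in h.aligned_blocks]
        else:
            # rc-frame positions within the region; region end anchors them
            # on the chromosome's rc frame only if the chromosome length is
            # known, so keep them region-relative and shift forward coords.
            pass
        h.target_start += iv.start
        h.target_end += iv.start
    return h


def nearest_gene(interval: GenomicInterval, ann: AnnotationSet):
    """The gene minimising base distance to the interval (0 if overlapping).

    Returns (gene_id, signed_distance) with the sign giving the interval's
    position relative to the gene respecting its strand: negative = upstream
    (5' of the TSS), positive = downstream.  Ties break on smaller gene
    start, then gene id.  (None, None) if the chromosome has no genes.
    """
    genes = ann.genes_on(interval.chromosome)
    if not genes:
        return None, None
    best = None
    for g in genes:
        if interval.start < g.end and g.start < interval.end:
            dist = 0
        elif interval.end <= g.start:
            gap = g.start - interval.end
            dist = -gap if g.strand == "+" else gap
        else:
            gap = interval.start - g.end
            dist = gap if g.strand == "+" else -gap
        key = (abs(dist), g.start, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id, dist)
    return best[1], best[2]


def accept_candidates(hits, query_ann: AnnotationSet | None,
                      target_ann: AnnotationSet | None,
                      homology: HomologyMap | None,
                      strict: float = STRICT_EVALUE,
                      relaxed: float = RELAXED_EVALUE,
                      rejects: list | None = None) -> list[CandidateElement]:
    """Dual acceptance rule: keep a hit if E <= strict, or if E <= relaxed and
    its nearest genes on the two sides are homologs.  When both paths apply,
    the strict path is recorded."""
    if not strict < relaxed:
        raise ValueError("need strict < relaxed threshold")
    missing_ann = query_ann is None or target_ann is None or homology is None
    warned = False
    out: list[CandidateElement] = []
    for h in hits:
        if math.isnan(h.evalue):
            raise ValueError("hit without E-value: run staged_search first")
        qg = tg = None
        qd = td = None
        if not missing_ann:
            qg, qd = nearest_gene(
                GenomicInterval(h.query_id, h.query_start, h.query_end), query_ann)
            tg, td = nearest_gene(
                GenomicInterval(h.target_id, h.target_start, h.target_end), target_ann)
        if h.evalue <= strict:
            out.append(CandidateElement(h, qg, qd, tg, td, "strict_evalue"))
            continue
        if h.evalue <= relaxed:
            if missing_ann:
                if not warned:
                    warnings.warn(
                        "relaxed-path candidates present but annotations or "
                        "homology are missing; only the strict E-value path "
                        "applies", stacklevel=2)
                    warned = True
                reason = "no annotation for homolog-proximity path"
            elif homology.is_homolog(qg, tg):
                out.append(CandidateElement(h, qg, qd, tg, td, "homolog_proximity"))
                continue
            else:
                reason = "nearest genes not homologous"
        else:
            reason = f"E-value {h.evalue:.3g} above relaxed threshold"
        if rejects is not None:
            rejects.append((h, reason))
    return out


def reversed_control(query_regions: ConservedRegionSet, query_genome: dict[str, str],
                     target_genome: dict[str, str], scheme: ScoringScheme,
                     gumbel: GumbelParams, min_score: int,
                     threshold: float = RELAXED_EVALUE,
                     both_strands: bool = True, **engine) -> NullReport:
    """Negative control: reverse (do NOT complement) the target genome and
    repeat the search.  DNA does not evolve by reversal, so every hit against
    the reversed target is chance -- their count at E <= threshold gauges the
    calibration of the E-values."""
    reversed_target = {name: seq[::-1] for name, seq in target_genome.items()}
    hits, stage = staged_search(
        query_regions, query_genome, reversed_target, scheme, gumbel,
        min_score, both_strands,
        target_description="reversed target", **engine)
    evs = sorted(h.evalue for h in hits)
    n_at = sum(1 for e in evs if e <= threshold)
    return NullReport(threshold=threshold, n_at_threshold=n_at,
                      min_evalue=evs[0] if evs else math.inf,
                      evalues=evs, stage=stage)
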