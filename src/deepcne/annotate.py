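"""Classification of accepted elements, gene-relative geometry, and
conserved-box motif scanning over aligned segments.

Element labels follow the four observed categories: "promoter" for segments
at a transcription start site in the best-annotated reference genome,
"utr3" for segments in annotated 3' UTRs, "intron" for segments wholly
inside introns, and "enhancer" otherwise, with precedence
promoter > utr3 > intron > enhancer.

Box scanning matches short IUPAC consensus words (CCAAT box, its
reverse-strand reading ATTGG, the E-box CAnnTG, the Wnt response element
CTTTG, and the CArG box CC(A/T)6GG) across the columns of a multi-species
alignment, reporting perfect and near-perfect conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .regions import AnnotationSet, GeneModel, GenomicInterval

CLASS_LABELS = ("promoter", "enhancer", "intron", "utr3")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ElementClass:
    label: str
    evidence: str

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown element class {self.label!r}")


@dataclass(frozen=True)
class BoxMotif:
    """An IUPAC-degenerate consensus word.

    strand_mode: "forward" scans the pattern as given; "both" also scans its
    reverse complement (reported as strand '-'); "reverse_reported" scans the
    given (already reverse-complemented) text but reports strand '-' -- used
    for ATTGG, the reverse-strand reading of the CCAAT box.
    """

    name: str
    pattern: str
    strand_mode: str = "forward"

    def __post_init__(self):
        if len(self.pattern) < 4:
            raise ValueError("motif pattern must be at least 4 long")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        if self.strand_mode not in ("forward", "both", "reverse_reported"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")

    def variants(self) -> list[tuple[str, str]]:
        """(pattern, reported strand) pairs to scan on the forward text."""
        pat = self.pattern.upper()
        if self.strand_mode == "forward":
            return [(pat, "+")]
        if self.strand_mode == "reverse_reported":
            return [(pat, "-")]
        rc = revcomp_pattern(pat)
        if rc == pat:  # self-complementary: one scan suffices
            return [(pat, "+")]
        return [(pat, "+"), (rc, "-")]


def revcomp_pattern(pattern: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(pattern.upper()))


#: the built-in conserved boxes: CCAAT (forward and reverse-strand reading),
#: E-box, Wnt response element, CArG box.  CAnnTG and CC(A/T)6GG are their
#: own reverse complements; CTTTG is scanned on both strands.
BUILTIN_MOTIFS = (
    BoxMotif("CCAAT", "CCAAT", "forward"),
    BoxMotif("CCAAT", "ATTGG", "reverse_reported"),
    BoxMotif("E-box", "CANNTG", "both"),
    BoxMotif("WRE", "CTTTG", "both"),
    BoxMotif("CArG", "CCWWWWWWGG", "both"),
)


@dataclass
class MotifOccurrence:
    """A motif hit at a column window of a multi-species alignment."""

    name: str
    col_start: int
    col_end: int
    strand: str
    species_match: dict[str, bool]
    conservation: str            # "perfect" | "near_perfect(k)"

    @property
    def n_mismatching(self) -> int:
        return sum(not v for v in self.species_match.values())


def _matches(text: str, pattern: str) -> bool:
    if len(text) != len(pattern) or "-" in text:
        return False
    return all(c in IUPAC[p] for c, p in zip(text.upper(), pattern))


def scan_boxes(aligned: dict[str, str], motifs=BUILTIN_MOTIFS,
               max_mismatch_species: int = 0) -> list[MotifOccurrence]:
    """Scan aligned segments (one per species, equal column counts, '-' for
    gaps) for conserved boxes.  A window is reported when at least
    (n_species - max_mismatch_species) species match the pattern at those
    columns; a gap inside the window counts as a mismatch for that species."""
    if not aligned:
        return []
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned segments must have equal column counts")
    ncol = lengths.pop()
    species = sorted(aligned)
    out: list[MotifOccurrence] = []
    for motif in motifs:
        for pat, strand in motif.variants():
            plen = len(pat)
            for c in range(0, ncol - plen + 1):
                match = {sp: _matches(aligned[sp][c:c + plen], pat)
                         for sp in species}
                n_bad = sum(not v for v in match.values())
                if n_bad <= max_mismatch_species:
                    cons = "perfect" if n_bad == 0 else f"near_perfect({n_bad})"
                    out.append(MotifOccurrence(motif.name, c, c + plen, strand,
                                               match, cons))
    out.sort(key=lambda o: (o.col_start, o.name, o.strand))
    return out


def classify_element(interval: GenomicInterval, ann: AnnotationSet | None,
                     tss_window: int = 500) -> ElementClass:
    """Label an element by where it sits in the reference species:
    promoter if it overlaps [TSS - tss_window, TSS + tss_window) of any gene,
    else utr3 if it overlaps an annotated 3' UTR, else intron if wholly
    inside an intron, else enhancer."""
    if ann is None or not ann.genes:
        return ElementClass("enhancer", "no-annotation")
    genes = ann.genes_on(interval.chromosome)
    for g in genes:
        lo, hi = g.tss - tss_window, g.tss + tss_window
        if interval.start < hi and lo < interval.end:
            return ElementClass("promoter", f"TSS of {g.gene_id}")
    for g in genes:
        for s, e in g.utr3:
            if interval.start < e and s < interval.end:
                return ElementClass("utr3", f"3'UTR of {g.gene_id}")
    for g in genes:
        for s, e in g.introns():
            if s <= interval.start and interval.end <= e:
                return ElementClass("intron", f"intron of {g.gene_id}")
    return ElementClass("enhancer", "no overlapping feature")


def relative_geometry(interval: GenomicInterval, gene: GeneModel | None,
                      strand_chain: list[str] | None,
                      reference_orientation: str = "+"):
    """Position (upstream/downstream/internal) of an element relative to its
    nearest gene, and its orientation relative to an arbitrarily fixed
    reference segment.

    The element itself has no inherent orientation; once one segment's
    orientation is fixed, each homolog's orientation is the composition of
    the alignment strands linking it to the reference (strand_chain).
    """
    if gene is None:
        position = "unknown"
    elif interval.start < gene.end and gene.start < interval.end:
        position = "internal"
    elif interval.end <= gene.start:
        position = "upstream" if gene.strand == "+" else "downstream"
    else:
        position = "downstream" if gene.strand == "+" else "upstream"

    if strand_chain is None:
        orientation = "unknown"
    else:
        sign = 1 if reference_orientation == "+" else -1
        for s in strand_chain:
            if s not in "+-":
                orientation = "unknown"
                break
            sign *= 1 if s == "+" else -1
        else:
            orientation = "same" if sign > 0 else "opposite"
    return position, orientation
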