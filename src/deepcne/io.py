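"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 reading through gffutils (in-memory DB);
BED6, the orthology TSV and MAF blocks are simple enough to emit directly.
Internally everything is 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at this boundary only.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp
from .regions import AnnotationSet, GeneModel, GenomicInterval

#: GFF3 feature types / biotypes mapped onto the exclusion vocabulary
_RNA_TYPES = {"rRNA", "tRNA", "snRNA", "snoRNA", "miRNA"}


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {sequence_id: sequence} (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED (3-6 columns), 0-based half-open."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            out.append(GenomicInterval(chrom, s, e, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join([
                iv.chromosome, str(iv.start), str(iv.end),
                iv.label if iv.label is not None else ".",
                "0", iv.strand if iv.strand is not None else "."]) + "\n")


def read_orthology(path) -> pd.DataFrame:
    """Two-column TSV of homologous gene-ID pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"query_gene_id", "target_gene_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"orthology table must have columns {sorted(need)}")
    return df[["query_gene_id", "target_gene_id"]]


def write_gff3(ann: AnnotationSet, path) -> None:
    """Write an AnnotationSet as GFF3 (gene/mRNA/exon/CDS/UTR hierarchy plus
    standalone RNA genes and pseudogenes)."""
    lines = ["##gff-version 3"]

    def row(chrom, ftype, s, e, strand, attrs):
        return "\t".join([chrom, "deepcne", ftype, str(s + 1), str(e),
                          ".", strand or ".", ".", attrs])

    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        lines.append(row(g.chromosome, "gene", g.start, g.end, g.strand,
                         f"ID=gene:{gid}"))
        mid = f"mRNA:{gid}"
        lines.append(row(g.chromosome, "mRNA", g.start, g.end, g.strand,
                         f"ID={mid};Parent=gene:{gid}"))
        for j, (s, e) in enumerate(sorted(g.exons)):
            lines.append(row(g.chromosome, "exon", s, e, g.strand,
                             f"ID=exon:{gid}.{j};Parent={mid}"))
        for s, e in sorted(g.utr5):
            lines.append(row(g.chromosome, "five_prime_UTR", s, e, g.strand,
                             f"Parent={mid}"))
        for s, e in sorted(g.utr3):
            lines.append(row(g.chromosome, "three_prime_UTR", s, e, g.strand,
                             f"Parent={mid}"))
    cds_by_gene: dict[str, int] = {}
    gene_spans = {gid: (g.chromosome, g.start, g.end) for gid, g in ann.genes.items()}
    extra = []
    for iv in ann.intervals:
        if iv.label == "CDS":
            owner = next((gid for gid, (c, s, e) in gene_spans.items()
                          if c == iv.chromosome and s <= iv.start and iv.end <= e), None)
            if owner:
                j = cds_by_gene.get(owner, 0)
                cds_by_gene[owner] = j + 1
                extra.append(row(iv.chromosome, "CDS", iv.start, iv.end,
                                 iv.strand, f"ID=cds:{owner}.{j};Parent=mRNA:{owner}"))
            else:
                extra.append(row(iv.chromosome, "CDS", iv.start, iv.end,
                                 iv.strand, "ID=cds:orphan"))
        elif iv.label in _RNA_TYPES:
            extra.append(row(iv.chromosome, iv.label, iv.start, iv.end, iv.strand,
                             f"ID={iv.label}:{iv.start}"))
        elif iv.label == "pseudogene":
            extra.append(row(iv.chromosome, "pseudogene", iv.start, iv.end,
                             iv.strand, f"ID=pseudogene:{iv.start}"))
    lines.extend(sorted(extra))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> AnnotationSet:
    """Read GFF3 into an AnnotationSet.

    gene/mRNA/exon/CDS/UTR features build gene models; rRNA/tRNA/snRNA/
    snoRNA/miRNA features (by type or gene_biotype attribute) and pseudogenes
    map onto the exclusion vocabulary.  Unmapped feature types are ignored
    (retained DNA), matching the principle that only DNA whose conservation
    is otherwise explained gets excluded.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
    except EmptyInputError:
        return AnnotationSet()  # header-only file: no features
    ann = AnnotationSet()
    for gene in db.features_of_type("gene"):
        biotype = (gene.attributes.get("gene_biotype")
                   or gene.attributes.get("biotype") or [""])[0]
        gs, ge = gene.start - 1, gene.end
        if biotype in _RNA_TYPES:
            ann.add_interval(GenomicInterval(gene.seqid, gs, ge, gene.strand, biotype))
            continue
        if biotype == "pseudogene":
            ann.add_interval(GenomicInterval(gene.seqid, gs, ge, gene.strand,
                                             "pseudogene"))
            continue
        exons, utr3, utr5, has_cds = [], [], [], False
        for child in db.children(gene, level=None):
            cs, ce = child.start - 1, child.end
            if child.featuretype == "exon":
                exons.append((cs, ce))
            elif child.featuretype == "CDS":
                has_cds = True
                ann.add_interval(GenomicInterval(child.seqid, cs, ce,
                                                 child.strand, "CDS"))
            elif child.featuretype == "three_prime_UTR":
                utr3.append((cs, ce))
                ann.add_interval(GenomicInterval(child.seqid, cs, ce,
                                                 child.strand, "three_prime_UTR"))
            elif child.featuretype == "five_prime_UTR":
                utr5.append((cs, ce))
                ann.add_interval(GenomicInterval(child.seqid, cs, ce,
                                                 child.strand, "five_prime_UTR"))
        gid = gene.id.split(":", 1)[-1]
        ann.add_gene(GeneModel(gene_id=gid, chromosome=gene.seqid,
                               start=gs, end=ge, strand=gene.strand,
                               exons=sorted(exons), utr3=sorted(utr3),
                               utr5=sorted(utr5)))
        ann.add_interval(GenomicInterval(gene.seqid, gs, ge, gene.strand, "gene"))
        for s, e in sorted(exons):
            ann.add_interval(GenomicInterval(gene.seqid, s, e, gene.strand, "exon"))
    for ftype in _RNA_TYPES | {"pseudogene"}:
        for feat in db.features_of_type(ftype):
            ann.add_interval(GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                             feat.strand, ftype))
    return ann


def _aligned_texts(hit, qseq: str, tseq: str) -> tuple[str, str]:
    """Reconstruct gapped alignment texts from a hit's gap-free blocks.

    qseq is the forward query; tseq must be the target sequence on the strand
    the hit matched (i.e. reverse-complemented for '-' hits), matching the
    coordinate frame of aligned_blocks.
    """
    qs_txt, ts_txt = [], []
    blocks = hit.aligned_blocks
    for b, (qb, tb, ln) in enumerate(blocks):
        if b > 0:
            pq, pt, pl = blocks[b - 1]
            dq = qb - (pq + pl)
            dt = tb - (pt + pl)
            if dq > 0:
                qs_txt.append(qseq[pq + pl:qb])
                ts_txt.append("-" * dq)
            if dt > 0:
                qs_txt.append("-" * dt)
                ts_txt.append(tseq[pt + pl:tb])
        qs_txt.append(qseq[qb:qb + ln])
        ts_txt.append(tseq[tb:tb + ln])
    return "".join(qs_txt), "".join(ts_txt)


def write_maf(hits, query_seqs: dict[str, str], target_seqs: dict[str, str],
              path, score_label: str = "score") -> None:
    """Write alignment hits as MAF blocks.

    '-' strand hits follow the MAF convention: coordinates count on the
    reverse-complemented target, with srcSize allowing conversion back.
    """
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=deepcne\n")
        for h in hits:
            if not h.aligned_blocks:
                continue
            qseq = query_seqs[h.query_id]
            tsrc = target_seqs[h.target_id]
            tseq = tsrc if h.strand == "+" else revcomp(tsrc)
            qtxt, ttxt = _aligned_texts(h, qseq, tseq)
            q_start = h.aligned_blocks[0][0]
            t_start = h.aligned_blocks[0][1]
            q_size = len(qtxt) - qtxt.count("-")
            t_size = len(ttxt) - ttxt.count("-")
            fh.write(f"a {score_label}={h.score}\n")
            fh.write(f"s {h.query_id} {q_start} {q_size} + {len(qseq)} {qtxt}\n")
            fh.write(f"s {h.target_id} {t_start} {t_size} {h.strand} "
                     f"{len(tsrc)} {ttxt}\n")
            fh.write("\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
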