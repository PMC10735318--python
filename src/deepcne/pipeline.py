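"""End-to-end orchestration: calibrate -> stage-1 genome alignment -> merge ->
annotation masking -> staged search per plan -> dual-rule acceptance ->
reversed-genome control -> classification / geometry / box scanning ->
element report.

Every stage logs its search-space sizes (n, m) and cumulative reduction
factor, making the sensitivity accounting an explicit, auditable artifact.
All randomness derives from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from ._seq import revcomp
from .align import ScoringScheme, default_scheme
from .annotate import classify_element, relative_geometry, scan_boxes
from .cascade import (CandidateElement, HomologyMap, NullReport, SearchStage,
                      accept_candidates, reversed_control, staged_search)
from .regions import (ConservedRegionSet, DEFAULT_EXCLUDED, GenomicInterval,
                      merge_hits_to_regions, reduction_factor,
                      subtract_annotated)
from .stats import calibrate_gumbel, score_threshold
from .synthetic import Fixture, FixtureConfig, build_truth_set, write_fixture

log = logging.getLogger("deepcne")

REPORT_COLUMNS = [
    "query_species", "target_species", "query_chrom", "query_start",
    "query_end", "target_chrom", "target_start", "target_end", "strand",
    "score", "evalue", "acceptance_path", "query_nearest_gene",
    "query_gene_distance", "target_nearest_gene", "target_gene_distance",
    "element_class", "class_evidence", "position", "orientation", "motifs",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a YAML key-value file."""

    seed: int = 0
    fixture: dict | None = None
    species_files: dict[str, dict[str, str]] = field(default_factory=dict)
    orthology_path: str | None = None
    reference: str | None = None          # best-annotated species
    stage1_query: str | None = None       # slowly evolving stage-1 partner
    stage1_target: str | None = None      # the reference
    stage1_evalue: float = 1.0
    searches: list[dict] = field(default_factory=list)
    scoring: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    strict_evalue: float = 1e-4
    relaxed_evalue: float = 10.0
    merge_gap: int = 0
    min_fragment: int = 20
    tss_window: int = 500
    min_score_margin: float = 10.0
    engine: dict = field(default_factory=dict)
    mask: bool = True
    run_controls: bool = True

    def __post_init__(self):
        for name, v in (("strict_evalue", self.strict_evalue),
                        ("relaxed_evalue", self.relaxed_evalue),
                        ("stage1_evalue", self.stage1_evalue)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.strict_evalue < self.relaxed_evalue:
            raise ValueError("strict_evalue must be below relaxed_evalue")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        thresholds = d.pop("thresholds", {}) or {}
        stage1 = d.pop("stage1", {}) or {}
        return cls(
            seed=int(d.pop("seed", 0)),
            fixture=d.pop("fixture", None),
            species_files=d.pop("species", {}) or {},
            orthology_path=d.pop("orthology", None),
            reference=d.pop("reference", None),
            stage1_query=stage1.get("query"),
            stage1_target=stage1.get("target"),
            stage1_evalue=float(stage1.get("evalue",
                                           thresholds.get("stage1_evalue", 1.0))),
            searches=d.pop("searches", []) or [],
            scoring=d.pop("scoring", {}) or {},
            calibration=d.pop("calibration", {}) or {},
            engine=d.pop("engine", {}) or {},
            mask=bool(d.pop("mask", True)),
            run_controls=bool(d.pop("controls", True)),
            **{k: v for k, v in thresholds.items()
               if k in ("strict_evalue", "relaxed_evalue", "merge_gap",
                        "min_fragment", "tss_window", "min_score_margin")},
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def scheme(self) -> ScoringScheme:
        if not self.scoring:
            return default_scheme()
        s = self.scoring
        return ScoringScheme.from_rates(
            int(s.get("match", 10)), int(s.get("transition", -7)),
            int(s.get("transversion", -13)), s.get("gap_open", -17),
            s.get("gap_extend", -11),
            composition=s.get("composition", (0.30, 0.20, 0.20, 0.30)))


@dataclass
class PipelineResult:
    report: pd.DataFrame
    candidates: list[CandidateElement]
    null_reports: dict[str, NullReport]
    stages: list[dict]
    gumbel: object
    regions_premask: ConservedRegionSet | None
    regions: ConservedRegionSet | None
    fixture: Fixture | None
    out_dir: str | None


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _load_inputs(cfg: PipelineConfig, out_dir: str | None):
    if cfg.fixture is not None:
        fx_conf = dict(cfg.fixture)
        fx_conf.setdefault("seed", cfg.seed)
        if "species_names" in fx_conf:
            fx_conf["species_names"] = tuple(fx_conf["species_names"])
        if "element_length_range" in fx_conf:
            fx_conf["element_length_range"] = tuple(fx_conf["element_length_range"])
        fixture = build_truth_set(FixtureConfig(**fx_conf))
        if out_dir:
            write_fixture(fixture, os.path.join(out_dir, "fixture"))
        genomes = fixture.genomes
        annotations = fixture.annotations
        homology = HomologyMap.from_table(fixture.orthology)
        return genomes, annotations, homology, fixture
    genomes, annotations = {}, {}
    for sp, files in cfg.species_files.items():
        genomes[sp] = dio.read_fasta(files["fasta"])
        annotations[sp] = (dio.read_gff3(files["gff3"])
                           if files.get("gff3") else None)
    homology = None
    if cfg.orthology_path:
        homology = HomologyMap.from_table(dio.read_orthology(cfg.orthology_path))
    return genomes, annotations, homology, None


def _whole_genome_regions(genome: dict[str, str]) -> ConservedRegionSet:
    total = sum(len(s) for s in genome.values())
    ivs = [GenomicInterval(c, 0, len(s)) for c, s in genome.items()]
    return ConservedRegionSet(ivs, total)


def _species_roles(cfg: PipelineConfig, genomes: dict) -> tuple[str, str, list[str]]:
    names = list(genomes)
    ref = cfg.reference or cfg.stage1_target or names[0]
    s1q = cfg.stage1_query or (names[1] if len(names) > 1 else names[0])
    targets = [s["target"] for s in cfg.searches] if cfg.searches else names[2:]
    for sp in [ref, s1q, *targets]:
        if sp not in genomes:
            raise ValueError(f"stage plan references unknown species {sp!r}")
    return ref, s1q, targets


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> PipelineResult:
    """Execute the full cascade; see the module docstring for the stages.
    Deterministic given the config seed.  A stage failure aborts with the
    stage name and cause; partial outputs under out_dir are removed."""
    created_out = False
    if out_dir:
        created_out = not os.path.isdir(out_dir)
        os.makedirs(out_dir, exist_ok=True)
    try:
        return _run_pipeline(cfg, out_dir)
    except Exception:
        if out_dir:
            import shutil
            if created_out:
                shutil.rmtree(out_dir, ignore_errors=True)
            else:
                for name in ("fixture", "report.tsv", "report.txt",
                             "stages.json", "null_reports.json",
                             "calibration.json", "rejects.tsv",
                             "alignments.maf"):
                    path = os.path.join(out_dir, name)
                    if os.path.isdir(path):
                        shutil.rmtree(path, ignore_errors=True)
                    elif os.path.exists(path):
                        os.remove(path)
        raise


def _run_pipeline(cfg: PipelineConfig, out_dir: str | None) -> PipelineResult:
    t_start = time.time()
    genomes, annotations, homology, fixture = _load_inputs(cfg, out_dir)
    ref, s1q, targets = _species_roles(cfg, genomes)
    scheme = cfg.scheme()
    engine = {k: v for k, v in cfg.engine.items()
              if k in ("seed_len", "xdrop", "gap_trigger", "xdrop_ungapped")
              and v is not None}
    seeds = _child_seeds(cfg.seed, 4)

    cal = cfg.calibration
    gc = float(cal.get("gc", 0.40))
    log.info("calibrating E-value statistics (gc=%.2f)", gc)
    gumbel = calibrate_gumbel(
        scheme, gc, seq_len=int(cal.get("seq_len", 20000)),
        n_sim=int(cal.get("n_sim", 150)), seed=seeds[0],
        seed_len=engine.get("seed_len"), xdrop=engine.get("xdrop"),
        gap_trigger=engine.get("gap_trigger"))
    log.info("calibrated: lambda=%.5f K=%.4f", gumbel.lam, gumbel.K)

    stages: list[dict] = []

    # stage 1: find DNA conserved between the stage-1 pair of genomes
    g_ref, g_s1q = genomes[ref], genomes[s1q]
    len_ref = sum(len(s) for s in g_ref.values())
    len_s1q = sum(len(s) for s in g_s1q.values())
    ms1 = score_threshold(gumbel, 2 * len_ref, len_s1q, cfg.stage1_evalue)
    s1_hits, s1_stage = staged_search(
        _whole_genome_regions(g_s1q), g_s1q, g_ref, scheme, gumbel, ms1,
        query_description=f"{s1q} genome", target_description=f"{ref} genome",
        **engine)
    s1_hits = [h for h in s1_hits if h.evalue <= cfg.stage1_evalue]
    stages.append(_stage_record("stage1", s1_stage, note=f"E<={cfg.stage1_evalue}"))
    log.info("stage1 %s vs %s: %d conserved segments", s1q, ref, len(s1_hits))

    regions_premask = merge_hits_to_regions(
        s1_hits, "query", cfg.merge_gap, genome_length=len_s1q)
    if cfg.mask and annotations.get(s1q) is not None:
        regions = subtract_annotated(regions_premask, annotations[s1q],
                                     DEFAULT_EXCLUDED, cfg.min_fragment)
    else:
        regions = regions_premask
    red = reduction_factor(regions) if regions.total_span else math.inf
    log.info("conserved regions on %s: %d regions, %d bp (1/%.0f of genome)",
             s1q, len(regions), regions.total_span, red)
    stages.append(dict(stage="mask", regions=len(regions),
                       span=regions.total_span, genome_length=len_s1q,
                       reduction=red))

    candidates: list[CandidateElement] = []
    rejects: list = []
    null_reports: dict[str, NullReport] = {}
    report_rows = []
    maf_hits = []

    for sp in targets:
        g_t = genomes[sp]
        len_t = sum(len(s) for s in g_t.values())
        if regions.total_span == 0:
            log.warning("no conserved regions left to search against %s", sp)
            continue
        ms2 = score_threshold(gumbel, 2 * len_t, regions.total_span,
                              cfg.relaxed_evalue * cfg.min_score_margin)
        hits, stage = staged_search(
            regions, g_s1q, g_t, scheme, gumbel, ms2,
            full_query_length=len_s1q,
            query_description=f"{s1q} conserved regions",
            target_description=f"{sp} genome", **engine)
        stages.append(_stage_record(f"search:{sp}", stage))
        log.info("search vs %s: n=%d m=%d reduction=%.0f-fold, %d hits",
                 sp, stage.n, stage.m, stage.reduction_applied, len(hits))

        if cfg.run_controls:
            nr = reversed_control(regions, g_s1q, g_t, scheme, gumbel, ms2,
                                  threshold=cfg.relaxed_evalue, **engine)
            null_reports[sp] = nr
            log.info("reversed-genome control vs %s: %d hits at E<=%g "
                     "(min E %.3g)", sp, nr.n_at_threshold, nr.threshold,
                     nr.min_evalue)

        accepted = accept_candidates(hits, annotations.get(s1q),
                                     annotations.get(sp), homology,
                                     cfg.strict_evalue, cfg.relaxed_evalue,
                                     rejects=rejects)
        _annotate_candidates(accepted, s1_hits, genomes, annotations,
                             ref, s1q, sp, cfg.tss_window)
        candidates.extend(accepted)
        maf_hits.extend((h.hit, s1q, sp) for h in accepted)
        for c in accepted:
            report_rows.append(_report_row(c, s1q, sp))

    report = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)
    report = report.sort_values(
        ["evalue", "query_chrom", "query_start", "target_species"],
        kind="mergesort").reset_index(drop=True)

    result = PipelineResult(report, candidates, null_reports, stages, gumbel,
                            regions_premask, regions, fixture, out_dir)
    if out_dir:
        _write_outputs(result, cfg, genomes, s1q, rejects)
    log.info("pipeline finished in %.1fs: %d elements", time.time() - t_start,
             len(report))
    return result


def _stage_record(name: str, stage: SearchStage, **extra) -> dict:
    rec = dict(stage=name, query=stage.query_description,
               target=stage.target_description, n=stage.n, m=stage.m,
               m_effective=stage.m_effective, min_score=stage.min_score,
               reduction_applied=stage.reduction_applied, n_hits=stage.n_hits)
    rec.update(extra)
    return rec


def _project_through(hit, positions, target_len):
    """Map query-side positions through a hit's blocks to target-side
    (position, on_reverse_strand) or None."""
    out = {}
    for qb, tb, ln in hit.aligned_blocks:
        for p in positions:
            if qb <= p < qb + ln:
                tpos = tb + (p - qb)
                if hit.strand == "-":
                    out[p] = (target_len - 1 - tpos, True)
                else:
                    out[p] = (tpos, False)
    return out


def _annotate_candidates(accepted, s1_hits, genomes, annotations, ref, s1q,
                         target_sp, tss_window):
    """Fill classification, geometry and motif scans for accepted elements."""
    ann_ref = annotations.get(ref)
    ann_t = annotations.get(target_sp)
    ref_genome = genomes[ref]
    t_genome = genomes[target_sp]
    q_genome = genomes[s1q]
    for c in accepted:
        h = c.hit
        # the stage-1 alignment that carried this region: best overlap
        best, best_ov = None, 0
        for s1 in s1_hits:
            if s1.query_id != h.query_id:
                continue
            ov = min(s1.query_end, h.query_end) - max(s1.query_start, h.query_start)
            if ov > best_ov:
                best, best_ov = s1, ov
        ref_interval = None
        chain = None
        if best is not None:
            chain = [best.strand, h.strand]
            tlen = len(ref_genome[best.target_id])
            pts = [p for p in (max(h.query_start, best.query_start),
                               min(h.query_end, best.query_end) - 1)]
            proj = _project_through(best, pts, tlen)
            if len(proj) == 2:
                (a, _), (b, _) = proj[pts[0]], proj[pts[1]]
                lo, hi = min(a, b), max(a, b) + 1
                ref_interval = GenomicInterval(best.target_id, lo, hi)
        else:
            chain = [h.strand]  # no reference link; orientation vs query side

        cls = classify_element(ref_interval, ann_ref, tss_window) \
            if ref_interval is not None else classify_element(
                GenomicInterval(h.query_id, h.query_start, h.query_end), None)
        c.element_class = cls.label
        c.class_evidence = cls.evidence

        gene = None
        if ann_t is not None and c.target_nearest_gene is not None:
            gene = ann_t.genes.get(c.target_nearest_gene)
        pos, orient = relative_geometry(
            GenomicInterval(h.target_id, h.target_start, h.target_end),
            gene, chain)
        c.position = pos
        c.orientation = orient

        aligned = _aligned_segments(c, best, q_genome, ref_genome, t_genome,
                                    ref, s1q, target_sp)
        if aligned:
            c.motif_occurrences = scan_boxes(aligned, max_mismatch_species=1)


def _aligned_segments(c, s1_hit, q_genome, ref_genome, t_genome,
                      ref, s1q, target_sp):
    """Alignment columns over the hub (stage-1 query) species' positions."""
    h = c.hit
    qseq = q_genome[h.query_id]
    positions = range(h.query_start, h.query_end)
    cols_hub, cols_ref, cols_t = [], [], []
    tlen = len(t_genome[h.target_id])
    proj_t = _project_through(h, positions, tlen)
    proj_r = {}
    if s1_hit is not None:
        rlen = len(ref_genome[s1_hit.target_id])
        proj_r = _project_through(s1_hit, positions, rlen)
    tseq = t_genome[h.target_id]
    rseq = ref_genome[s1_hit.target_id] if s1_hit is not None else ""
    for p in positions:
        cols_hub.append(qseq[p])
        pt = proj_t.get(p)
        if pt is None:
            cols_t.append("-")
        else:
            tp, rc = pt
            cols_t.append(revcomp(tseq[tp]) if rc else tseq[tp])
        pr = proj_r.get(p)
        if pr is None:
            cols_ref.append("-")
        else:
            rp, rc = pr
            cols_ref.append(revcomp(rseq[rp]) if rc else rseq[rp])
    out = {s1q: "".join(cols_hub), target_sp: "".join(cols_t)}
    if s1_hit is not None:
        out[ref] = "".join(cols_ref)
    return out


def _report_row(c: CandidateElement, s1q: str, target_sp: str) -> list:
    h = c.hit
    motifs = ";".join(
        f"{m.name}@{m.col_start}{m.strand}:{m.conservation}"
        for m in c.motif_occurrences)
    return [s1q, target_sp, h.query_id, h.query_start, h.query_end,
            h.target_id, h.target_start, h.target_end, h.strand, h.score,
            h.evalue, c.acceptance_path, c.query_nearest_gene,
            c.query_gene_distance, c.target_nearest_gene,
            c.target_gene_distance, c.element_class, c.class_evidence,
            c.position, c.orientation, motifs]


def _write_outputs(result: PipelineResult, cfg: PipelineConfig, genomes,
                   s1q: str, rejects) -> None:
    out = result.out_dir
    result.report.to_csv(os.path.join(out, "report.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(_human_summary(result))
    with open(os.path.join(out, "stages.json"), "w") as fh:
        json.dump(result.stages, fh, indent=2, default=float)
    nulls = {sp: dict(threshold=nr.threshold, n_at_threshold=nr.n_at_threshold,
                      min_evalue=nr.min_evalue, evalues=nr.evalues)
             for sp, nr in result.null_reports.items()}
    with open(os.path.join(out, "null_reports.json"), "w") as fh:
        json.dump(nulls, fh, indent=2, default=float)
    with open(os.path.join(out, "calibration.json"), "w") as fh:
        json.dump(dict(**{"lambda": result.gumbel.lam}, K=result.gumbel.K,
                       calibration_mode=result.gumbel.calibration_mode,
                       n_sim=result.gumbel.n_sim, sim_seed=result.gumbel.sim_seed,
                       fit=result.gumbel.fit), fh, indent=2)
    rej_rows = [dict(query_chrom=h.query_id, query_start=h.query_start,
                     query_end=h.query_end, target_chrom=h.target_id,
                     target_start=h.target_start, target_end=h.target_end,
                     strand=h.strand, score=h.score, evalue=h.evalue,
                     reason=reason) for h, reason in rejects]
    pd.DataFrame(rej_rows).to_csv(os.path.join(out, "rejects.tsv"),
                                  sep="\t", index=False)
    maf_path = os.path.join(out, "alignments.maf")
    hits = [c.hit for c in result.candidates]
    if hits:
        tsp = {sp: g for sp, g in genomes.items()}
        # all hits share the hub species on the query side; pool targets
        qseqs = genomes[s1q]
        targets = {}
        for c in result.candidates:
            for sp, g in genomes.items():
                if c.hit.target_id in g and sp != s1q:
                    targets.update(g)
        dio.write_maf(hits, qseqs, targets, maf_path)
    else:
        with open(maf_path, "w") as fh:
            fh.write("##maf version=1 scoring=deepcne\n")


def _human_summary(result: PipelineResult) -> str:
    lines = ["deepcne element report (coordinates 1-based inclusive)", ""]
    for _, r in result.report.iterrows():
        lines.append(
            f"{r.query_species}:{r.query_chrom}:{r.query_start + 1}-{r.query_end}"
            f" ~ {r.target_species}:{r.target_chrom}:{r.target_start + 1}-"
            f"{r.target_end} ({r.strand}) score={r.score} E={r.evalue:.3g} "
            f"[{r.acceptance_path}] class={r.element_class} "
            f"pos={r.position} orient={r.orientation} "
            f"genes={r.query_nearest_gene}/{r.target_nearest_gene}")
    lines.append("")
    for sp, nr in result.null_reports.items():
        lines.append(f"reversed-genome control vs {sp}: "
                     f"{nr.n_at_threshold} hits at E<={nr.threshold:g} "
                     f"(min E {nr.min_evalue:.3g})")
    return "\n".join(lines) + "\n"
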