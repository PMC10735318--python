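"""Score a pipeline report against the synthetic generator's truth table.

An element counts as recovered when some accepted row overlaps its planted
interval in the query species AND its planted interval in the target species.
Accepted rows overlapping planted coding/RNA/pseudogene DNA on either side
are confounder leaks (the masking stage should have removed them); rows
matching no planted feature at all are background false positives.
"""

from __future__ import annotations

import json

import pandas as pd

#: placement -> expected element class in the reference species
PLACEMENT_TO_CLASS = {"tss": "promoter", "upstream": "enhancer",
                      "downstream": "enhancer", "intron": "intron",
                      "utr3": "utr3"}


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def _rows_overlapping(truth: pd.DataFrame, species, chrom, start, end):
    t = truth[(truth.species == species) & (truth.chromosome == chrom)]
    return t[(t.start < end) & (start < t.end)]


def score_report(report: pd.DataFrame, truth: pd.DataFrame,
                 query_species: str, target_species: str) -> dict:
    """Recall/precision-style metrics for one species-pair search."""
    reg = truth[(truth.element_class == "regulatory")]
    planted = sorted(set(reg[reg.species == query_species].element_id)
                     & set(reg[reg.species == target_species].element_id))
    rep = report[(report.query_species == query_species)
                 & (report.target_species == target_species)]

    recovered = []
    flips = []
    class_ok = 0
    class_known = 0
    for eid in planted:
        q = reg[(reg.element_id == eid) & (reg.species == query_species)].iloc[0]
        t = reg[(reg.element_id == eid) & (reg.species == target_species)].iloc[0]
        m = rep[(rep.query_chrom == q.chromosome)
                & (rep.query_start < q.end) & (q.start < rep.query_end)
                & (rep.target_chrom == t.chromosome)
                & (rep.target_start < t.end) & (t.start < rep.target_end)]
        if len(m) == 0:
            continue
        recovered.append(eid)
        # orientation: planted strands differ across the pair -> expect a flip
        expect_flip = q.strand != t.strand
        reported_flip = bool((m.orientation == "opposite").any())
        if reported_flip:
            flips.append(eid)
        row = m.iloc[0]
        expected_class = PLACEMENT_TO_CLASS.get(q.placement)
        if expected_class is not None and row.element_class is not None:
            class_known += 1
            if row.element_class == expected_class:
                class_ok += 1

    # classify accepted rows: regulatory / confounder / background
    confounder_rows = 0
    background_rows = 0
    background_strict = 0
    for _, r in rep.iterrows():
        qhits = _rows_overlapping(truth, query_species, r.query_chrom,
                                  r.query_start, r.query_end)
        thits = _rows_overlapping(truth, target_species, r.target_chrom,
                                  r.target_start, r.target_end)
        classes = set(qhits.element_class) | set(thits.element_class)
        if classes & {"coding", "rna_gene", "pseudogene"}:
            confounder_rows += 1
        elif "regulatory" not in classes:
            background_rows += 1
            if r.acceptance_path == "strict_evalue":
                background_strict += 1

    n_planted = len(planted)
    return dict(
        n_planted=n_planted,
        n_recovered=len(recovered),
        recall=len(recovered) / n_planted if n_planted else float("nan"),
        missed=sorted(set(planted) - set(recovered)),
        orientation_flips=flips,
        n_orientation_flips=len(flips),
        confounder_rows=confounder_rows,
        background_rows=background_rows,
        background_rows_strict=background_strict,
        class_agreement=class_ok / class_known if class_known else float("nan"),
        n_report_rows=int(len(rep)),
    )


def score_report_files(report_path, truth_path, query_species, target_species,
                       out_json=None) -> dict:
    report = pd.read_csv(report_path, sep="\t")
    truth = pd.read_csv(truth_path, sep="\t")
    metrics = score_report(report, truth, query_species, target_species)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(metrics, fh, indent=2, default=str)
    return metrics
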