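# Methods

`deepcne` reimplements, at desk scale, a cascade for discovering gene-regulatory
DNA conserved across very distantly related animals (e.g. across the
deuterostome–protostome split).  The cascade rests on one statistical idea and
three procedural ones:

1. **Calibrated E-values.** Every local-alignment similarity is assigned
   E = K·m·n·exp(−λ·S): the expected number of equally good chance alignments
   between random sequences of the same composition and the same search-space
   lengths m (target side) and n (query side).
2. **Masking.** Conserved DNA that encodes protein, rRNA, tRNA, snRNA, snoRNA
   or miRNA — or that is a pseudogene of such — is removed before the deep
   searches, because its conservation is already explained by its (former)
   product.
3. **Search-space reduction.** Restricting the query side to the pre-identified
   conserved non-coding fraction of a genome (and optionally the target side to
   a conserved subset, e.g. oyster DNA conserved in scallop) shrinks m·n, so
   the same alignment score receives a proportionally smaller E-value:
   a region set covering 1/174 of a genome buys a 174-fold gain.
4. **Reversed-genome control.** Repeating each search against the target
   *reversed base-by-base without complementation* gives a target that is
   biologically impossible as a homolog but compositionally identical; the
   number of control hits with E ≤ t directly audits the E-value calibration
   (it should be ≈ t) and the false-discovery risk of the real search.

Acceptance of a hit follows a dual rule: E ≤ 10⁻⁴ unconditionally
(`strict_evalue` path), or E ≤ 10 when the nearest gene on the query side and
the nearest gene on the target side are a pair in the homology table
(`homolog_proximity` path).  "Near homologous genes" is operationalised as
*nearest gene on each side*; when both rules apply the strict path is
recorded.  Accepted elements are then labelled in the best-annotated reference
species — promoter if they overlap TSS ± `tss_window` (default ±500 bp; a
finite window is needed to make "at the transcription start site" operational),
else 3′-UTR, else intron (whole containment), else enhancer, with exactly that
precedence — and their position (upstream/downstream/internal) and orientation
relative to the nearby gene are reported.  Orientation is meaningful only
relative to an arbitrarily fixed reference segment: each homolog's orientation
is the product of the strands of the pairwise alignments linking it to the
reference.

## Alignment engine

`local_align` is a seed-and-extend aligner: exact-match seeds (default 6 bp)
from a sorted k-mer index, ungapped X-drop extension around each seed (X-drop
40), and gapped X-drop extension (X-drop 100, affine gaps open −17 / extend
−11 per base) for seeds whose ungapped extension reaches the trigger score
(90).  A per-diagonal skip avoids re-extending one island from each of its
seeds; overlapping hits that survive are collapsed onto the best-scoring one
(ties: smaller target start, then query start).  N bases score as the worst
mismatch and can never start a seed.  Gap-free blocks of final hits are
re-derived by an exact affine-gap DP over the hit's span, which can only
confirm or improve the extension score.

**Default substitution scores** are match +10, transition −7, transversion
−13.  Two properties drove this choice:

* *Mildness.* A transversion costs only 1.3 matches, so alignments down to
  ~60% identity can score positively — appropriate for DNA conserved over
  hundreds of millions of years, where surviving signal is short and degraded.
* *Dense score lattice.* The five cost parameters share no common divisor and
  are not integer multiples of the match score.  With "round" matrices
  (e.g. ratios 6:−9:−18), attainable alignment scores at the relevant tail
  clump at intervals comparable to 1/λ, making the E-value a step function:
  the count of hits with E ≤ t then systematically misses t by tens of
  percent no matter how well λ and K are estimated.  We measured this
  directly on simulated islands; the mild incommensurate matrix keeps
  λ·(attainable-score spacing) ≈ 0.1, small enough for threshold counts to
  behave like their expectations.

**Exactness.**  With default settings the engine is a heuristic.  At
exhaustive-sensitivity settings (short seeds, large X-drop, `gap_trigger=0`,
which also disables the diagonal skip), the best reported score provably
equals the Smith–Waterman optimum whenever the optimal alignment contains one
exact seed match: extension from an anchor on the optimal path recovers the
optimum because any internal score dip of an optimal local alignment is
bounded by its own score (a larger dip would split it into two better
alignments), hence never exceeds an X-drop ≥ that score.  For stringent
matrices a 3-bp seed suffices in practice (an optimum without any 3-bp exact
run would need an extremely improbable repeat structure); for ±1 scoring a
2-bp seed makes the guarantee unconditional for any optimum scoring above a
few matches, since a positive-scoring alignment of isolated single matches is
impossible.  The Smith–Waterman oracle used in tests is Biopython's
`PairwiseAligner` — an independent exact implementation, never the engine
itself.

## Gumbel calibration

For ungapped scoring, λ is the unique positive root of
Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1 (`solve_lambda_ungapped`, Brent's method to relative
tolerance 10⁻¹²).  Gapped statistics have no closed form, so
`calibrate_gumbel` simulates pairs of independent random sequences at the
target composition (default 40% g+c), runs the *same* engine configuration the
searches will use, and fits the law to the scores of all distinct alignment
islands above an automatically chosen floor.  The island-score tail is the
Poisson-process representation of the Gumbel law for per-pair maxima:
P(S ≥ s₀+j·d | S ≥ s₀) = e^(−λjd) on the score lattice d, fitted by maximum
likelihood (geometric ML on the excess), with K anchored at the island count
at the fit threshold.  This uses every island rather than only each pair's
maximum, which is what makes ~1–3% calibration error reachable in tens of CPU
seconds.  Two calibration choices matter:

* *Pair length* (default 30 kb) is chosen so that the fitted score range
  brackets the scores at which E-values of 10⁻⁴…10 live for the megabase-scale
  searches the pipeline runs — the fit then interpolates rather than
  extrapolates.
* *Fit floor*: islands just above the detection floor show a short-alignment
  excess over the asymptotic law, so the fit starts two match-scores above the
  floor.

Calibration is deterministic given its seed and records mode
(`simulated`), fit (`island_ml`), n_sim and seed in `GumbelParams`.  A
held-out self-consistency check (the fraction of simulated pairs whose best
score has fitted E ≤ 1 must be ≈ 1−e⁻¹ ≈ 0.632) is part of the test suite.
When both strands are searched the E-value uses m_eff = 2m; calibration is
single-strand, so the doubling is exact bookkeeping, not an approximation.

## Synthetic data generator

`build_truth_set` emulates the input structure the cascade assumes, with a
star phylogeny (ancestor → each species directly; the pipeline only runs
pairwise searches, so a deeper tree would add parameters without test power).
Defaults — chosen once from detectability arithmetic at desk-scale search
spaces, not adjusted afterwards:

| parameter | default | why |
|---|---|---|
| species | refvert, slowfish, mollusc | annotated reference, slowly evolving stage-1 partner, deep-divergence target |
| genome_length | 200 kb / species | large enough for realistic E-value bookkeeping, small enough for seconds-scale runs |
| n_gene_loci | 12 | one element per placement class with repeats |
| element_length_range | 120–200 bp | typical conserved-element scale |
| regulatory_divergence | 0.08 subs/site/branch | deep conservation: pairwise identity ≈ 1−2d ≈ 84%; leaves a ≥3σ score margin over every threshold in the default cascade |
| background_divergence | "independent" | at these distances most DNA shares no detectable similarity; also keeps truth coordinates exact |
| coding_fraction | 0.03 | two CDS chunks of ~250 bp per locus |
| rna_gene_count / pseudogene_count | 2 / 2 | conserved confounders |
| gc_content | 0.40 | matches the null composition used for calibration |
| indel_rate | 0 | keeps planted coordinates exact; `evolve_sequence` itself supports Poisson indels with geometric lengths |

Each locus carries a gene model (5′UTR, CDS, intron, CDS, 3′UTR; strand
alternating) and one regulatory element whose placement cycles through
tss / upstream / intron / utr3 / downstream, so every classification branch is
exercised.  Elements and confounders evolve at the slow (regulatory) rate from
a common ancestral sequence; per-site substitution probability d gives
pairwise identity (1−d)² + d²/3, within the stated 1−2d approximation's
tolerance at these rates.  Exactly one element (the last locus') is planted
reverse-complemented in the last species, so the orientation-flip machinery
has a single known positive.  Confounders evolve as slowly as elements —
deliberately, so the masking stage is load-bearing: with masking disabled they
are found conserved at E ≤ 10⁻⁴ (a test asserts this).

**What the generator does not model:** codon structure, splice signals,
repeat families, rearrangements, lineage-specific element loss, and rate
variation among elements.  Passing tests therefore demonstrate the machinery
(calibration, masking, cascading, acceptance, classification) under the
stated statistical assumptions — not sensitivity on real genomes, where
divergence is deeper and heterogeneous.

## Pipeline defaults and numerical choices

* Stage-1 conserved segments: whole genome vs whole genome, kept at E ≤ 1
  (config `stage1.evalue`); overlapping projections merged with
  `merge_gap` 0 (how stage-1 hits are consolidated is an open choice; 0 is
  the most conservative).
* Masking: categories {CDS, rRNA, tRNA, snRNA, snoRNA, miRNA, pseudogene};
  fragments < 20 bp dropped (`min_fragment`).
* Stage-2 minimum score: the score whose E-value is `relaxed_evalue ×
  min_score_margin` (default 10 × 10), so every hit relevant to either
  acceptance path is found while junk stays bounded.
* All child seeds derive from the single config seed via
  `numpy.random.SeedSequence`; identical config+seed gives byte-identical
  outputs.
* Multi-species alignment columns for box scanning are projected through the
  stage-1 query species (the hub present in both pairwise alignments);
  insertions relative to the hub are dropped, gaps appear as '-' and count as
  mismatches.  With the default (indel-free) generator the projections are
  column-exact.
* Box motifs: CCAAT (forward), ATTGG reported as reverse-strand CCAAT, E-box
  CAnnTG, Wnt response element CTTTG, CArG CC(A/T)₆GG.  CAnnTG and CCW₆GG are
  their own reverse complements and are reported on the forward strand only.
  "Near-perfect" conservation defaults to one deviating species.

## Known limitations

* Position-weight-matrix (e.g. JASPAR) scanning is deliberately out of scope;
  only consensus boxes are reported.
* The engine's sensitivity at default settings is ~0.92–1.0 at the E ≤ 10
  score range (measured against shorter seeds); because calibration runs the
  same engine, E-values describe the pipeline as run.
* `reduction_applied` compounds only the reductions explicitly configured;
  it does not attempt to infer reductions applied upstream of the inputs.
* GFF3 reading maps unknown biotypes to "retained" (not masked) and relies on
  gene/child hierarchy; deeply nonstandard annotation files may need
  pre-processing.
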