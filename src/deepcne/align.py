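"""Local alignment between sequence sets.

`local_align` is a seed-and-extend aligner (exact-match seeds, X-drop
ungapped triage, gapped X-drop extension) returning maximal-scoring local
alignments as :class:`AlignmentHit` objects.  Overlapping hits that belong to
the same alignment island are collapsed onto the best-scoring one.

Default engine settings (6-bp seeds, X-drop 100 in the default score units,
gapped-extension trigger 90) give near-full sensitivity at the score range
where the E-value thresholds of the discovery cascade operate, on
megabase-scale inputs, at desk speed.  For exactness-critical small inputs,
pass seed_len=3, a large X-drop and gap_trigger=0: the best reported score
then equals the Smith-Waterman optimum (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._seq import CODE_N, composition_from_gc, encode, revcomp_codes

TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T

#: Default substitution/gap scores.  Deliberately mild (a transversion costs
#: only 1.3 matches) because the pipeline hunts DNA conserved across very
#: deep divergences, and deliberately incommensurate (no common divisor, and
#: event costs that are not integer multiples of the match score) so that
#: attainable alignment scores form a dense lattice and E-values vary
#: smoothly with score -- a prerequisite for threshold counts ("hits with
#: E <= t") to behave like their expectation t.
DEFAULT_MATCH = 10
DEFAULT_TRANSITION = -7
DEFAULT_TRANSVERSION = -13
DEFAULT_GAP_OPEN = -17
DEFAULT_GAP_EXTEND = -11

DEFAULT_SEED_LEN = 6
DEFAULT_XDROP = 100
DEFAULT_XDROP_UNGAPPED = 40
#: gapped X-drop extension is run only for seeds whose ungapped extension
#: reaches min(GAP_TRIGGER, min_score); 90 = nine net matches.
DEFAULT_GAP_TRIGGER = 90


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution/gap scores plus the background base composition.

    matrix is a 4x4 integer array over (A,C,G,T).  A gap of length L costs
    gap_open + L*gap_extend; gap_open=None disables gapped extension
    (ungapped alignment).  The background composition (default A=T=0.30,
    C=G=0.20) is what E-value calibration simulates.
    """

    matrix: np.ndarray
    gap_open: int | None = DEFAULT_GAP_OPEN
    gap_extend: int | None = DEFAULT_GAP_EXTEND
    background_composition: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.20, 0.20, 0.30])
    )

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=np.int64)
        if mat.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        object.__setattr__(self, "matrix", mat)
        comp = np.asarray(self.background_composition, dtype=float)
        if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("background composition must be frequencies summing to 1")
        object.__setattr__(self, "background_composition", comp)
        if mat.max() <= 0:
            raise ValueError("scoring scheme needs at least one positive substitution score")
        if self.expected_score() >= 0:
            raise ValueError(
                "expected substitution score under the background composition "
                "must be negative for local-alignment statistics to exist"
            )
        if self.gap_open is not None:
            if self.gap_open > 0:
                raise ValueError("gap_open must be nonpositive")
            if self.gap_extend is None or self.gap_extend >= 0:
                raise ValueError("gap_extend must be negative")

    def expected_score(self) -> float:
        p = self.background_composition
        return float(p @ self.matrix @ p)

    @property
    def gapped(self) -> bool:
        return self.gap_open is not None

    def matrix5(self) -> np.ndarray:
        """5x5 matrix with N scoring as the worst mismatch on every pairing."""
        worst = int(self.matrix.min())
        m5 = np.full((5, 5), worst, dtype=np.int64)
        m5[:4, :4] = self.matrix
        return m5

    @classmethod
    def from_match_mismatch(cls, match: int, mismatch: int, gap_open: int | None = None,
                            gap_extend: int | None = None,
                            composition=(0.25, 0.25, 0.25, 0.25)) -> "ScoringScheme":
        mat = np.full((4, 4), mismatch, dtype=np.int64)
        np.fill_diagonal(mat, match)
        return cls(mat, gap_open, gap_extend, np.asarray(composition, float))

    @classmethod
    def from_rates(cls, match: int, transition: int, transversion: int,
                   gap_open: int | None, gap_extend: int | None,
                   composition=(0.30, 0.20, 0.20, 0.30)) -> "ScoringScheme":
        mat = np.full((4, 4), transversion, dtype=np.int64)
        np.fill_diagonal(mat, match)
        for i, j in TRANSITIONS:
            mat[i, j] = transition
        return cls(mat, gap_open, gap_extend, np.asarray(composition, float))


def default_scheme() -> ScoringScheme:
    return ScoringScheme.from_rates(
        DEFAULT_MATCH, DEFAULT_TRANSITION, DEFAULT_TRANSVERSION,
        DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND,
    )


@dataclass
class AlignmentHit:
    """A scored local alignment between a query region and a target sequence.

    Coordinates are 0-based half-open.  For strand '-', query coordinates stay
    on the forward query strand while target_start/target_end give the
    matched interval on the forward target strand; aligned_blocks, however,
    are (q_start, t_start, length) triples with the target positions expressed
    on the reverse-complemented target (MAF convention), ascending in both
    coordinates.
    """

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    score: int
    evalue: float = math.nan
    aligned_blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not (self.query_start < self.query_end and self.target_start < self.target_end):
            raise ValueError("hit intervals must satisfy start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    val = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        val = val * 4 + np.minimum(c, 3).astype(np.int64)
        ok &= c != CODE_N
    val[~ok] = -1
    return val


def _target_index(tcodes: np.ndarray, k: int):
    kc = _kmer_codes(tcodes, k)
    valid = kc >= 0
    pos = np.flatnonzero(valid).astype(np.int64)
    codes = kc[valid]
    order = np.argsort(codes, kind="stable")
    tpos = pos[order]
    counts = np.bincount(codes, minlength=4 ** k)
    starts = np.zeros(4 ** k + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    return starts, tpos


def _search_pair(qcodes, tcodes, tindex, scheme: ScoringScheme, min_score: int,
                 seed_len: int, xdrop: int, gap_trigger: int,
                 xdrop_ungapped: int = DEFAULT_XDROP_UNGAPPED,
                 diag_skip: bool = True) -> np.ndarray:
    """Run the engine on one (query, target) code-array pair; returns deduped
    (n,5) int64 rows (qs, qe, ts, te, score) sorted by (ts, qs)."""
    starts, tpos = tindex
    qk = _kmer_codes(qcodes, seed_len)
    qvalid = qk >= 0
    qpos = np.flatnonzero(qvalid).astype(np.int64)
    qcode = qk[qvalid]
    mat5 = scheme.matrix5()
    if scheme.gapped:
        go, ge, gapped = scheme.gap_open, scheme.gap_extend, True
        wcap = 4 * xdrop // (-ge) + 32
    else:
        go, ge, gapped = -(2**40), -(2**20), False
        wcap = 8
    trigger = min(gap_trigger, min_score)
    bufsize = 1 << 14
    while True:
        out = np.empty((bufsize, 5), dtype=np.int64)
        xu = xdrop if not gapped else min(xdrop, xdrop_ungapped)
        if trigger == 0 and gapped:
            # exhaustive mode: triage must not truncate, and one island must
            # never mask another island's seeds on a shared diagonal
            xu = xdrop
            diag_skip = False
        cnt = _kernels.seed_search(
            qcodes, tcodes, qpos, qcode, starts, tpos, seed_len, mat5,
            go, ge, xdrop, xu, min_score, trigger, gapped, diag_skip, wcap, out,
        )
        if cnt <= bufsize:
            rows = out[:cnt]
            break
        bufsize = int(cnt) + 1024
    if len(rows) == 0:
        return rows
    # collapse islands: greedy by descending score, ties by t_start then q_start
    order = np.lexsort((rows[:, 0], rows[:, 2], -rows[:, 4]))
    keep = np.zeros(len(rows), dtype=np.bool_)
    _kernels.dedup_hits(rows, order, keep)
    rows = rows[keep]
    final = np.lexsort((rows[:, 0], rows[:, 2]))
    return rows[final]


def _hit_blocks(qcodes, tcodes, row, scheme: ScoringScheme) -> tuple[int, list]:
    qs, qe, ts, te, score = (int(x) for x in row)
    if (qe - qs + 1) * (te - ts + 1) > 8_000_000:
        # pathological extension; report a single approximate block
        return score, [(qs, ts, min(qe - qs, te - ts))]
    go = scheme.gap_open if scheme.gapped else -(2**40)
    ge = scheme.gap_extend if scheme.gapped else -(2**20)
    gscore, blocks = _kernels.affine_global(qcodes[qs:qe], tcodes[ts:te], scheme.matrix5(), go, ge)
    blocks = [(qs + int(b[0]), ts + int(b[1]), int(b[2])) for b in blocks]
    return max(score, int(gscore)), blocks


def local_align(queries: dict[str, str], targets: dict[str, str], scheme: ScoringScheme,
                min_score: int, both_strands: bool = True, *,
                seed_len: int = DEFAULT_SEED_LEN, xdrop: int = DEFAULT_XDROP,
                gap_trigger: int = DEFAULT_GAP_TRIGGER,
                xdrop_ungapped: int = DEFAULT_XDROP_UNGAPPED,
                diag_skip: bool = True,
                with_blocks: bool = True) -> list[AlignmentHit]:
    """All maximal local alignments with score >= min_score between every
    query and every target sequence.  Empty inputs give an empty result."""
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    hits: list[AlignmentHit] = []
    q_enc = {name: encode(seq) for name, seq in queries.items()}
    for t_name in targets:
        t_fwd = encode(targets[t_name])
        if len(t_fwd) < seed_len:
            continue
        frames = [("+", t_fwd)]
        if both_strands:
            frames.append(("-", revcomp_codes(t_fwd)))
        nt = len(t_fwd)
        for strand, tcodes in frames:
            tindex = _target_index(tcodes, seed_len)
            for q_name, qcodes in q_enc.items():
                if len(qcodes) < seed_len:
                    continue
                rows = _search_pair(qcodes, tcodes, tindex, scheme, min_score,
                                    seed_len, xdrop, gap_trigger, xdrop_ungapped,
                                    diag_skip)
                for row in rows:
                    qs, qe, ts, te, score = (int(x) for x in row)
                    if with_blocks:
                        score, blocks = _hit_blocks(qcodes, tcodes, row, scheme)
                    else:
                        blocks = []
                    if strand == "+":
                        t0, t1 = ts, te
                    else:
                        t0, t1 = nt - te, nt - ts
                    hits.append(AlignmentHit(
                        query_id=q_name, query_start=qs, query_end=qe,
                        target_id=t_name, target_start=t0, target_end=t1,
                        strand=strand, score=score, aligned_blocks=blocks,
                    ))
    hits.sort(key=lambda h: (-h.score, h.target_id, h.target_start,
                             h.query_id, h.query_start, h.strand))
    return hits
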