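"""Extreme-value statistics for local alignment scores.

Optimal local alignment scores between long random sequences follow the
Karlin-Altschul / Gumbel law: the expected number of distinct alignments
("islands") scoring at least S between random sequences of lengths m and n is

    E(S) = K * m * n * exp(-lambda * S).

For ungapped scoring, lambda is the unique positive root of
sum_ij p_i p_j exp(lambda * s_ij) = 1 (``solve_lambda_ungapped``).  For gapped
scoring no closed form exists, so ``calibrate_gumbel`` estimates (lambda, K)
by simulation: it searches many pairs of random sequences with the same
seed-and-extend engine the pipeline uses, and fits the island-score tail by
maximum likelihood (the Poisson-process representation of the Gumbel law,
which uses every island rather than only each pair's maximum and therefore
reaches usefully small standard errors at desk-scale CPU budgets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._seq import composition_from_gc, random_codes
from .align import ScoringScheme, _search_pair, _target_index


@dataclass(frozen=True)
class GumbelParams:
    """Gumbel/Karlin-Altschul parameters: E(S) = K * m * n * exp(-lam * S)."""

    lam: float
    K: float
    calibration_mode: str  # "analytic_ungapped" or "simulated"
    n_sim: int = 0
    sim_seed: int = 0
    fit: str = ""

    def __post_init__(self):
        if not (self.lam > 0 and self.K > 0):
            raise ValueError("lambda and K must be positive")


def solve_lambda_ungapped(scheme: ScoringScheme, composition=None) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1.

    Gap scores are ignored.  Raises if the expected score is nonnegative
    (no root exists) or no score is positive.
    """
    p = scheme.background_composition if composition is None else np.asarray(composition, float)
    s = scheme.matrix.astype(float)
    w = np.outer(p, p)
    if float((w * s).sum()) >= 0:
        raise ValueError("expected score must be negative: no positive lambda exists")
    if s.max() <= 0:
        raise ValueError("at least one substitution score must be positive")

    def f(lam: float) -> float:
        return float((w * np.exp(lam * s)).sum()) - 1.0

    hi = 1.0 / s.max()
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-15, rtol=1e-12))


def evalue(score: float, params: GumbelParams, m: float, n: float) -> float:
    """Expected number of chance alignments scoring >= score between random
    sequences of search lengths m (target) and n (query)."""
    if m <= 0 or n <= 0:
        raise ValueError("search lengths m and n must be positive")
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    x = math.log(params.K) + math.log(m) + math.log(n) - params.lam * score
    return math.exp(min(x, 700.0))


def score_threshold(params: GumbelParams, m: float, n: float, emax: float) -> int:
    """Smallest integer score whose E-value is <= emax in an (m x n) search."""
    s = (math.log(params.K) + math.log(m) + math.log(n) - math.log(emax)) / params.lam
    return max(1, int(math.ceil(s - 1e-9)))


def _lattice(values: np.ndarray) -> int:
    diffs = values - values.min()
    d = int(np.gcd.reduce(diffs.astype(np.int64)))
    return d


def calibrate_gumbel(scheme: ScoringScheme, gc_content: float, seq_len: int = 30000,
                     n_sim: int = 200, seed: int = 0, *,
                     seed_len: int = None, xdrop: int = None, gap_trigger: int = None,
                     islands_per_pair: float = 25.0) -> GumbelParams:
    """Estimate (lambda, K) for a scoring scheme at a given g+c composition.

    Simulates ``n_sim`` independent pairs of random sequences of length
    ``seq_len``, records the score of every distinct local-alignment island
    above an automatically chosen floor, and fits the island-score tail by
    maximum likelihood (lattice-aware geometric fit -- the Poisson-process
    representation of the Gumbel law for per-pair maxima); K follows from the
    island count at the fitted threshold.  Deterministic given ``seed``.

    Calibration runs the *same* seed-and-extend engine the searches use
    (pass the engine parameters you will search with), so the fitted
    parameters describe the pipeline as run.  ``seq_len`` should be chosen so
    that the simulated score range brackets the E-value thresholds of the
    intended searches; the 30 kb default puts the fitted tail at the scores
    where E-values of order 0.0001..10 live for megabase-scale searches.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    from .align import DEFAULT_GAP_TRIGGER, DEFAULT_SEED_LEN, DEFAULT_XDROP

    if seed_len is None:
        seed_len = DEFAULT_SEED_LEN
    if xdrop is None:
        xdrop = DEFAULT_XDROP if scheme.gapped else max(DEFAULT_XDROP, 8 * int(scheme.matrix.max()))
    if gap_trigger is None:
        gap_trigger = DEFAULT_GAP_TRIGGER
    comp = composition_from_gc(gc_content)
    lam0 = solve_lambda_ungapped(scheme, comp)
    # score floor aimed at ~islands_per_pair islands per simulated pair;
    # 0.8*lam0 pads for the gapped lambda sitting below the ungapped root
    mn = float(seq_len) * float(seq_len)
    floor = int(math.log(0.1 * mn / islands_per_pair) / (0.8 * lam0))
    floor = max(floor, int(seed_len * scheme.matrix.max()) + 1)

    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_sim):
        a = random_codes(rng, seq_len, comp)
        b = random_codes(rng, seq_len, comp)
        tindex = _target_index(b, seed_len)
        rows = _search_pair(a, b, tindex, scheme, floor, seed_len, xdrop, gap_trigger)
        if len(rows):
            scores.append(rows[:, 4].copy())
    if not scores:
        raise RuntimeError(
            "degenerate calibration: no alignment islands found; increase "
            "seq_len or n_sim")
    all_scores = np.concatenate(scores)
    if all_scores.max() == all_scores.min():
        raise RuntimeError(
            "degenerate calibration: island scores have zero variance; "
            "inputs too short or scheme too coarse for a Gumbel fit")
    d = max(_lattice(all_scores), 1)
    # fit clear of the floor (short-island excess sits just above it)
    s_fit = floor + 2 * int(scheme.matrix.max())
    tail = all_scores[all_scores >= s_fit]
    if len(tail) < 50 or tail.max() == s_fit:
        s_fit = floor + d
        tail = all_scores[all_scores >= s_fit]
    excess = tail - s_fit
    mean_j = float(excess.sum()) / (d * len(tail))
    if mean_j <= 0:
        raise RuntimeError("degenerate calibration: no score spread above the fit threshold")
    lam = math.log1p(1.0 / mean_j) / d
    K = len(tail) * math.exp(lam * s_fit) / (n_sim * mn)
    return GumbelParams(lam=lam, K=K, calibration_mode="simulated",
                        n_sim=n_sim, sim_seed=seed, fit="island_ml")
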