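"""Shared fixtures: a calibrated default scoring scheme, the default synthetic
fixture, one full pipeline run (reused by several tests), and a
Smith-Waterman oracle built on Biopython's exact pairwise DP."""

from __future__ import annotations

import numpy as np
import pytest

from deepcne.align import ScoringScheme, default_scheme
from deepcne.pipeline import PipelineConfig, run_pipeline
from deepcne.stats import calibrate_gumbel
from deepcne.synthetic import FixtureConfig, build_truth_set


def make_sw_oracle(scheme: ScoringScheme):
    """Exact local-alignment score via Biopython's PairwiseAligner: the
    independent quadratic-DP oracle for the seed-and-extend engine."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    M = substitution_matrices.Array("ACGT", 2)
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            M[a, b] = int(scheme.matrix[i, j])
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = M
    if scheme.gapped:
        al.open_gap_score = scheme.gap_open + scheme.gap_extend
        al.extend_gap_score = scheme.gap_extend
    else:
        al.open_gap_score = al.extend_gap_score = -(10**6)
    return lambda q, t: int(al.score(q, t))


@pytest.fixture(scope="session")
def sw_oracle_factory():
    return make_sw_oracle


@pytest.fixture(scope="session")
def default_gumbel():
    """Calibrated Gumbel parameters for the default scheme at 40% g+c."""
    return calibrate_gumbel(default_scheme(), 0.40, seq_len=30000, n_sim=200,
                            seed=11)


@pytest.fixture(scope="session")
def default_fixture():
    return build_truth_set(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-fixture pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig.from_dict({"seed": 1, "fixture": {}})
    result = run_pipeline(cfg, out_dir=str(out))
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
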