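import numpy as np
import pandas as pd
import pytest

from saetx.model import AlignmentSet, Gene, GenomeAnnotation, ExpressionMatrix
from saetx.simulate import (
    SimulationConfig,
    make_annotation,
    simulate_expression,
    simulate_reads,
)


@pytest.fixture
def two_gene_annotation():
    """Two genes 10 kb apart: one 2-exon (+), one 3-exon (-)."""
    genes = {
        "GA": Gene("GA", "chr1", "+", [(1000, 1200), (1500, 1800)]),
        "GB": Gene("GB", "chr1", "-", [(11800, 12000), (12500, 12700), (13000, 13400)]),
    }
    return GenomeAnnotation(genes)


@pytest.fixture
def small_matrix():
    """Deterministic 6-gene, 5+6-subject expression matrix."""
    rng = np.random.default_rng(123)
    subjects = [f"ns{i}" for i in range(1, 6)] + [f"sm{i}" for i in range(1, 7)]
    groups = {s: ("nonsmoker" if s.startswith("ns") else "smoker") for s in subjects}
    base = np.array([0.05, 0.5, 2.0, 8.0, 40.0, 900.0])
    values = base[:, None] * rng.lognormal(0, 0.2, (6, 11))
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(6)], columns=subjects)
    return ExpressionMatrix(df, groups)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-level tests."""
    cfg = SimulationConfig(n_genes=60, depth=1_000_000, seed=5)
    annotation = make_annotation(cfg)
    truth = simulate_expression(cfg, annotation, seed=6)
    reads = simulate_reads(truth, annotation, cfg.depth, seed=7)
    return cfg, annotation, truth, reads


def make_alignments(intervals, subject="s1", chrom="chr1", total=None):
    """AlignmentSet from a list of (start, end) pairs."""
    df = pd.DataFrame(
        {
            "chrom": [chrom] * len(intervals),
            "start": [s for s, _ in intervals],
            "end": [e for _, e in intervals],
            "strand": ["+"] * len(intervals),
        }
    )
    return AlignmentSet(subject, df, total_mapped=total or len(df))
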