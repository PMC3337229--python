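"""Gene-family clustering by pairwise mRNA sequence identity.

Two genes are linked when the best local alignment of their mRNA
sequences has >= 90% identity and covers >= 50% of BOTH sequences;
families are the connected components (single linkage) of the link graph
with at least two members.  Alignment is forward-strand only with
BLASTN-like scoring (match +1, mismatch -2, gap open -5, extend -2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 90.0  # percent
COVERAGE_THRESHOLD = 50.0  # percent of each sequence

_ALPHABET = set("ACGTN")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Best-local-alignment identity and per-sequence coverage, in percent.

    Identity is matches over alignment columns (gap columns included);
    coverage of each sequence is the aligned span over its length.
    Sequences must be >= 50 nt over {A,C,G,T,N}; > 10% N draws a warning.
    """
    out = []
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        seq = seq.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has invalid characters {sorted(bad)}")
        if len(seq) < 50:
            raise ValueError(f"sequence {name} shorter than 50 nt")
        if seq.count("N") / len(seq) > 0.10:
            log.warning("sequence %s is more than 10%% N", name)
        out.append(seq)
    seq_a, seq_b = out
    aligner = _make_aligner()
    alignments = aligner.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0, 0.0
    identity = 100.0 * counts.identities / columns
    a_blocks, b_blocks = aln.aligned
    span_a = int(a_blocks[-1][1] - a_blocks[0][0])
    span_b = int(b_blocks[-1][1] - b_blocks[0][0])
    return identity, 100.0 * span_a / len(seq_a), 100.0 * span_b / len(seq_b)


@dataclass
class FamilyCluster:
    """A connected component of the >= 90% identity / >= 50% coverage graph."""

    family_id: str
    members: list[str]
    links: pd.DataFrame = field(default_factory=pd.DataFrame)
    # links columns: member_a, member_b, identity, coverage_a, coverage_b


def build_families(
    sequences: dict[str, str],
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> list[FamilyCluster]:
    """Cluster sequences into families by pairwise local-alignment identity.

    A pair is linked iff identity >= ``identity_threshold`` and the
    alignment covers >= ``coverage_threshold`` percent of both sequences.
    Families are connected components with >= 2 members, ordered (and
    their members ordered) lexicographically for determinism.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to cluster")
    names = sorted(sequences)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    link_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            identity, cov_a, cov_b = pairwise_identity(sequences[a], sequences[b])
            if identity >= identity_threshold and min(cov_a, cov_b) >= coverage_threshold:
                graph.add_edge(a, b)
                link_rows.append(
                    {
                        "member_a": a,
                        "member_b": b,
                        "identity": identity,
                        "coverage_a": cov_a,
                        "coverage_b": cov_b,
                    }
                )
    links = pd.DataFrame(link_rows)
    families = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
    )
    for idx, members in enumerate(components, 1):
        member_set = set(members)
        fam_links = (
            links[
                links["member_a"].isin(member_set)
                & links["member_b"].isin(member_set)
            ].reset_index(drop=True)
            if len(links)
            else links
        )
        families.append(
            FamilyCluster(family_id=f"F{idx}", members=members, links=fam_links)
        )
    return families


def family_expression(
    families: list[FamilyCluster], medians: pd.Series
) -> pd.DataFrame:
    """Per-family expression table, members sorted by median RPKM descending."""
    rows = []
    for fam in families:
        ranked = sorted(
            fam.members,
            key=lambda m: (-float(medians.get(m, 0.0)), m),
        )
        for rank, member in enumerate(ranked, 1):
            rows.append(
                {
                    "family_id": fam.family_id,
                    "member": member,
                    "rank_in_family": rank,
                    "median_rpkm": float(medians.get(member, float("nan"))),
                }
            )
    return pd.DataFrame(rows)
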