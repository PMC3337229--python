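"""Exon-junction usage quantification and smoker/nonsmoker testing.

A junction joins two consecutive exons of one gene.  A read supports a
junction when it spans the boundary with at least ``min_overlap`` (k)
nucleotides on each exon, so a read of length R has

    L_j = R - 2k + 1

valid start positions (the effective junction length).  Raw spliced
counts are normalised to a usage value comparable across genes:

    U = count / (L_j/1000 x M/1e6 x E_neighbor)

with M the subject's mapped-library size and E_neighbor the mean RPKM of
the two flanking exons.  Junctions are filtered (host-gene expression,
minimum spliced reads, gene RPKM standard error) before a two-sample
t-test per junction, summarised by a Q-Q comparison of observed p-values
against the uniform expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, GenomeAnnotation, NONSMOKER, SMOKER
from .differential import welch_or_pooled_ttest

FILTER_GENE_RPKM = "gene-rpkm"
FILTER_MIN_READS = "min-reads"
FILTER_GENE_SE = "gene-SE"


@dataclass(frozen=True)
class Junction:
    """One exon-exon boundary of a gene model."""

    junction_id: str
    gene: str
    donor_index: int  # index of the upstream exon in the merged model
    donor_end: int  # genomic end of the donor exon (half-open)
    acceptor_start: int  # genomic start of the acceptor exon
    effective_length: int  # L_j = R - 2k + 1

    def __post_init__(self) -> None:
        if self.effective_length < 1:
            raise ValueError("effective junction length must be >= 1")


def build_junction_db(
    annotation: GenomeAnnotation, read_length: int = 43, min_overlap: int = 3
) -> list[Junction]:
    """One junction per consecutive exon pair of each multi-exon gene."""
    if read_length < 2 * min_overlap:
        raise ValueError(
            f"read length {read_length} cannot overlap both exons by "
            f"{min_overlap} nt"
        )
    l_eff = read_length - 2 * min_overlap + 1
    out = []
    for sym in annotation.gene_symbols():
        gene = annotation.genes[sym]
        for i, ((_, left_end), (right_start, _)) in enumerate(
            zip(gene.exons, gene.exons[1:])
        ):
            out.append(
                Junction(
                    junction_id=f"{sym}:j{i + 1}",
                    gene=sym,
                    donor_index=i,
                    donor_end=left_end,
                    acceptor_start=right_start,
                    effective_length=l_eff,
                )
            )
    return out


def count_junction_reads(
    reads: pd.DataFrame,
    junctions: list[Junction],
    read_length: int = 43,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Spliced read counts per junction per subject.

    ``reads`` has columns subject/junction_id/start with start the read's
    position relative to the boundary (negative: read begins on the donor
    side).  A read counts iff it covers >= ``min_overlap`` nt of each
    exon: start in [-(R - k), -k].  Returns a junction x subject count
    table including all-zero rows for unsupported junctions.
    """
    ids = [j.junction_id for j in junctions]
    subjects = sorted(reads["subject"].unique()) if len(reads) else []
    counts = pd.DataFrame(0, index=pd.Index(ids, name="junction_id"),
                          columns=subjects, dtype=np.int64)
    if len(reads):
        lo, hi = -(read_length - min_overlap), -min_overlap
        valid = reads[(reads["start"] >= lo) & (reads["start"] <= hi)]
        valid = valid[valid["junction_id"].isin(counts.index)]
        tally = valid.groupby(["junction_id", "subject"]).size()
        for (jid, subject), n in tally.items():
            counts.at[jid, subject] = n
    return counts


def junction_usage(
    count: float, effective_length: float, total_mapped: float, e_neighbor: float
) -> float:
    """Normalised junction usage U; NaN (undefined) when E_neighbor is zero."""
    if effective_length <= 0 or total_mapped <= 0:
        raise ValueError("effective length and library size must be positive")
    if e_neighbor == 0:
        return np.nan
    return count / (
        (effective_length / 1000.0) * (total_mapped / 1e6) * e_neighbor
    )


def usage_table(
    counts: pd.DataFrame,
    junctions: list[Junction],
    total_mapped: dict[str, float] | pd.Series,
    matrix: ExpressionMatrix,
) -> pd.DataFrame:
    """Per-junction, per-subject raw counts and normalised usage (long form).

    The flanking-exon expression E_neighbor is the mean RPKM of the two
    exons adjacent to the boundary; under a uniform-coverage gene model
    both flanks carry the gene's RPKM, so the subject's gene RPKM is
    used.  Usage is NaN-flagged where E_neighbor is zero.
    """
    total_mapped = pd.Series(total_mapped)
    by_id = {j.junction_id: j for j in junctions}
    rows = []
    for jid in counts.index:
        j = by_id[jid]
        for subject in counts.columns:
            e_flank = float(matrix.values.at[j.gene, subject])
            rows.append(
                {
                    "junction_id": jid,
                    "gene": j.gene,
                    "subject": subject,
                    "count": int(counts.at[jid, subject]),
                    "usage": junction_usage(
                        counts.at[jid, subject],
                        j.effective_length,
                        total_mapped[subject],
                        e_flank,
                    ),
                }
            )
    return pd.DataFrame(rows)


def filter_junctions(
    usage: pd.DataFrame,
    matrix: ExpressionMatrix,
    min_gene_rpkm: float = 0.125,
    min_spliced_reads: int = 2,
    max_gene_se: float = 0.5,
) -> pd.DataFrame:
    """Apply the three exclusion rules; the filters are independent predicates.

    Per junction: (1) host-gene nonsmoker-median RPKM must not fall below
    ``min_gene_rpkm``; (2) at least one group must total
    ``min_spliced_reads`` spliced reads (a junction fails only when BOTH
    group totals are below the minimum); (3) the host gene's RPKM
    standard error across all subjects must not exceed ``max_gene_se``.
    Returns one row per junction with ``retained`` and ``reason``
    (comma-joined failed filters, empty when retained).
    """
    gene_median = matrix.group_median(NONSMOKER)
    n = matrix.values.shape[1]
    gene_se = matrix.values.std(axis=1, ddof=1) / np.sqrt(n)
    groups = matrix.groups
    ns_subjects = [s for s in groups.index if groups[s] == NONSMOKER]
    sm_subjects = [s for s in groups.index if groups[s] == SMOKER]

    rows = []
    for jid, sub in usage.groupby("junction_id", sort=True):
        gene = sub["gene"].iloc[0]
        reasons = []
        if gene_median.get(gene, 0.0) < min_gene_rpkm:
            reasons.append(FILTER_GENE_RPKM)
        ns_reads = sub.loc[sub["subject"].isin(ns_subjects), "count"].sum()
        sm_reads = sub.loc[sub["subject"].isin(sm_subjects), "count"].sum()
        if ns_reads < min_spliced_reads and sm_reads < min_spliced_reads:
            reasons.append(FILTER_MIN_READS)
        if gene_se.get(gene, 0.0) > max_gene_se:
            reasons.append(FILTER_GENE_SE)
        rows.append(
            {
                "junction_id": jid,
                "gene": gene,
                "retained": not reasons,
                "reason": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def junction_test(
    usage: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test on normalised usage per junction, plus Q-Q columns.

    Output is sorted by ascending p and carries the uniform-order-
    statistic expectation for a Q-Q plot: ``expected_neglog10_p`` for the
    i-th smallest of n p-values is -log10((i - 0.5)/n).  Benjamini-
    Hochberg q-values are reported alongside but do not enter the Q-Q
    axes.
    """
    groups = pd.Series(groups)
    ns = [s for s in groups.index if groups[s] == NONSMOKER]
    sm = [s for s in groups.index if groups[s] == SMOKER]
    if len(ns) < 2 or len(sm) < 2:
        raise ValueError("each group needs at least 2 subjects")
    wide = usage.pivot_table(index="junction_id", columns="subject",
                             values="usage", sort=True)
    wide = wide.dropna(axis=0)  # undefined usage (zero flank expression)
    if wide.empty:
        raise ValueError("no junctions with defined usage in both groups")
    pvals = welch_or_pooled_ttest(
        wide[ns].to_numpy(), wide[sm].to_numpy(), equal_var=equal_var
    )
    out = pd.DataFrame({"junction_id": wide.index, "p": pvals})
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    n = len(out)
    ranks = np.arange(1, n + 1)
    out["neglog10_p"] = -np.log10(np.clip(out["p"], 1e-300, None))
    out["expected_neglog10_p"] = -np.log10((ranks - 0.5) / n)
    out["q_bh"] = np.minimum.accumulate(
        (out["p"] * n / ranks).to_numpy()[::-1]
    )[::-1].clip(max=1.0)
    return out


def qq_inflation(test_table: pd.DataFrame) -> float:
    """Median observed / median expected -log10 p: 1 under the null."""
    return float(
        np.median(test_table["neglog10_p"])
        / np.median(test_table["expected_neglog10_p"])
    )
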