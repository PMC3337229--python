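"""RPKM quantification of aligned reads over genomic features.

RPKM (reads per kilobase of feature per million mapped reads) is the
expression unit throughout:

    RPKM = count * 1e9 / (length_nt * total_mapped)

A read counts for a feature when its interval overlaps the feature by at
least one nucleotide; strand is ignored (the library protocol is assumed
unstranded).  A read overlapping both exon and intron of the same gene
is credited once to the gene and once to whichever feature class holds
the larger overlap (ties go to the exon).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    AlignmentSet,
    ExpressionMatrix,
    GenomeAnnotation,
    GenomicRegion,
)

MRNA_PER_CELL_PER_RPKM = 1.0  # calibration: 1 RPKM ~ one mRNA copy per cell


def rpkm(count: float, length_nt: float, total_mapped: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (length_nt * total_mapped)


def rpkm_to_mrna_per_cell(value: float) -> tuple[float, float]:
    """Convert RPKM to (mRNA copies per cell, cells per mRNA copy)."""
    copies = value * MRNA_PER_CELL_PER_RPKM
    cells_per_mrna = np.inf if copies == 0 else 1.0 / copies
    return copies, cells_per_mrna


def _region_trees(regions: Sequence[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree())[r.start: r.end] = idx
    return trees


def count_reads(alignments: AlignmentSet, regions: Sequence[GenomicRegion]) -> np.ndarray:
    """Raw read counts per region (>= 1 nt overlap; <= 1 count per read/region)."""
    counts = np.zeros(len(regions), dtype=np.int64)
    if not len(regions) or not len(alignments.records):
        return counts
    trees = _region_trees(regions)
    recs = alignments.records
    for chrom, start, end in zip(recs["chrom"], recs["start"], recs["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(start, end):
            counts[hit.data] += 1
    return counts


def count_features(
    alignments: AlignmentSet, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Counts over exon, intron and intergenic regions with the class rule.

    When a read overlaps both exon and intron regions of one gene, only
    the class with the larger overlap (tie: exon) receives the count for
    that gene; regions of other genes and intergenic regions are counted
    independently.  Returns one row per region with columns
    chrom/start/end/kind/gene/length/count.
    """
    regions = (
        annotation.exon_regions() + annotation.introns + list(annotation.intergenic)
    )
    counts = np.zeros(len(regions), dtype=np.int64)
    trees = _region_trees(regions)
    recs = alignments.records
    for chrom, start, end in zip(recs["chrom"], recs["start"], recs["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree.overlap(start, end)
        # per-gene best class: gene -> {kind: max overlap}
        per_gene: dict[str, dict[str, int]] = {}
        gene_hits: dict[str, list[tuple[int, str]]] = {}
        for hit in hits:
            idx = hit.data
            r = regions[idx]
            if r.kind == "intergenic":
                counts[idx] += 1
                continue
            ov = min(end, r.end) - max(start, r.start)
            cls = per_gene.setdefault(r.parent_gene, {})
            cls[r.kind] = max(cls.get(r.kind, 0), ov)
            gene_hits.setdefault(r.parent_gene, []).append((idx, r.kind))
        for gene, cls in per_gene.items():
            if len(cls) == 1:
                winner = next(iter(cls))
            else:
                winner = "exon" if cls["exon"] >= cls["intron"] else "intron"
            for idx, kind in gene_hits[gene]:
                if kind == winner:
                    counts[idx] += 1
    out = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "kind": [r.kind for r in regions],
            "gene": [r.parent_gene for r in regions],
            "length": [r.length for r in regions],
            "count": counts,
        }
    )
    return out


def feature_density(
    alignments: AlignmentSet, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Per-region read density table (FeatureDensityTable): adds RPKM."""
    table = count_features(alignments, annotation)
    table["rpkm"] = table["count"] * 1e9 / (table["length"] * alignments.total_mapped)
    return table


def gene_rpkm(alignments: AlignmentSet, annotation: GenomeAnnotation) -> pd.Series:
    """Gene-level RPKM over the union exon model, one value per gene.

    Genes with zero exon length are excluded.  A read overlapping the
    exon model by >= 1 nt counts once for the gene, regardless of how it
    splits across that gene's individual exons.
    """
    genes = [g for g in annotation.genes.values() if g.exon_length > 0]
    recs = alignments.records
    widths = (recs["end"] - recs["start"]).unique() if len(recs) else []
    if len(widths) == 1:
        counts = _gene_counts_fixed_length(recs, genes, int(widths[0]))
    else:
        counts = _gene_counts_tree(recs, genes)
    values = {
        g.symbol: rpkm(counts[g.symbol], g.exon_length, alignments.total_mapped)
        for g in genes
    }
    return pd.Series(values, dtype=float).sort_index()


def _gene_counts_tree(recs: pd.DataFrame, genes) -> dict[str, int]:
    regions = [r for g in genes for r in g.exon_regions()]
    counts: dict[str, int] = {g.symbol: 0 for g in genes}
    trees = _region_trees(regions)
    for chrom, start, end in zip(recs["chrom"], recs["start"], recs["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        genes_hit = {regions[hit.data].parent_gene for hit in tree.overlap(start, end)}
        for sym in genes_hit:
            counts[sym] += 1
    return counts


def _gene_counts_fixed_length(recs: pd.DataFrame, genes, read_length: int) -> dict[str, int]:
    """Vectorised per-gene counting for constant-length reads.

    A read overlaps a gene's exon union iff it overlaps the gene span and
    is not wholly inside one intron: counted as (# starts in
    [span_start - L + 1, span_end)) minus (# starts in
    [intron_start, intron_end - L]) summed over introns.  Equivalent to
    the interval-tree scan; cross-checked against it in the test suite.
    """
    counts: dict[str, int] = {g.symbol: 0 for g in genes}
    for chrom, sub in recs.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy())
        for g in genes:
            if g.chrom != chrom:
                continue
            span_start, span_end = g.span
            n = int(
                np.searchsorted(starts, span_end, side="left")
                - np.searchsorted(starts, span_start - read_length + 1, side="left")
            )
            for (_, left_end), (right_start, _) in zip(g.exons, g.exons[1:]):
                n -= int(
                    np.searchsorted(starts, right_start - read_length, side="right")
                    - np.searchsorted(starts, left_end, side="left")
                )
            counts[g.symbol] += n
    return counts


def expression_matrix(
    alignment_sets: Sequence[AlignmentSet],
    annotation: GenomeAnnotation,
    groups: dict[str, str] | pd.Series,
) -> ExpressionMatrix:
    """Quantify each subject and assemble the gene x subject RPKM matrix."""
    cols = {
        aln.subject_id: gene_rpkm(aln, annotation) for aln in alignment_sets
    }
    values = pd.DataFrame(cols)
    return ExpressionMatrix(values, pd.Series(groups).loc[list(values.columns)])


def matched_size_regions(
    template_regions: Sequence[GenomicRegion],
    candidate_regions: Sequence[GenomicRegion],
    seed: int | np.random.Generator,
) -> list[GenomicRegion]:
    """Sample candidate sub-intervals matching the template size distribution.

    For each template region a sub-interval of identical length is drawn
    uniformly from the remaining candidate space, without replacement of
    genomic positions, so the output length multiset equals the template
    length multiset exactly.  Raises ``ValueError`` listing the deficit
    when the candidates cannot host all templates.
    """
    rng = np.random.default_rng(seed)
    free: list[GenomicRegion] = list(candidate_regions)
    out: list[GenomicRegion] = []
    # place longest first so feasibility does not depend on draw order
    order = sorted(range(len(template_regions)),
                   key=lambda i: -template_regions[i].length)
    placed: dict[int, GenomicRegion] = {}
    for i in order:
        length = template_regions[i].length
        fits = [j for j, seg in enumerate(free) if seg.length >= length]
        if not fits:
            deficit = sum(
                1 for k in order if k not in placed
            )
            raise ValueError(
                f"insufficient candidate space: {deficit} template regions of "
                f"length >= {length} nt cannot be placed"
            )
        weights = np.array([free[j].length - length + 1 for j in fits], dtype=float)
        j = fits[rng.choice(len(fits), p=weights / weights.sum())]
        seg = free[j]
        offset = int(rng.integers(0, seg.length - length + 1))
        start = seg.start + offset
        placed[i] = GenomicRegion(seg.chrom, start, start + length, seg.strand, seg.kind)
        # split the remaining free space around the sampled sub-interval
        rest = []
        if start > seg.start:
            rest.append(GenomicRegion(seg.chrom, seg.start, start, seg.strand, seg.kind))
        if start + length < seg.end:
            rest.append(
                GenomicRegion(seg.chrom, start + length, seg.end, seg.strand, seg.kind)
            )
        free[j: j + 1] = rest
    return [placed[i] for i in range(len(template_regions))]
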