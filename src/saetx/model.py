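"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based half-open throughout the package;
GTF (1-based closed) is converted at the I/O boundary.  A gene is a set
of union-merged exons on one chromosome; introns are the gaps between
consecutive merged exons; intergenic regions are the gaps between gene
spans on a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NONSMOKER = "nonsmoker"
SMOKER = "smoker"
GROUPS = (NONSMOKER, SMOKER)

REGION_KINDS = ("exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval with a feature classification."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "exon"
    parent_gene: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge a collection of half-open intervals.

    Abutting intervals ([a,b) and [b,c)) are merged, so the result is the
    minimal set of disjoint, non-abutting intervals covering the input.
    Idempotent: merging an already-merged list returns it unchanged.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if end <= start:
            raise ValueError(f"degenerate interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class Gene:
    """A gene model: the union of its annotated exons."""

    symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # union-merged, sorted, half-open

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_regions(self) -> list[GenomicRegion]:
        return [
            GenomicRegion(self.chrom, s, e, self.strand, "exon", self.symbol)
            for s, e in self.exons
        ]

    def intron_regions(self) -> list[GenomicRegion]:
        out = []
        for (_, left_end), (right_start, _) in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicRegion(
                    self.chrom, left_end, right_start, self.strand, "intron", self.symbol
                )
            )
        return out


@dataclass
class GenomeAnnotation:
    """Genes plus the intron and intergenic regions derived from them.

    ``intergenic_buffer`` nucleotides on each side of a gene span are
    excluded from intergenic regions (default 0).  Only interior gaps
    between genes on the same chromosome are called intergenic, since
    chromosome ends are unknown without a sequence dictionary.
    """

    genes: dict[str, Gene]
    intergenic_buffer: int = 0
    introns: list[GenomicRegion] = field(default_factory=list)
    intergenic: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty annotation: no genes")
        if not self.introns:
            self.introns = [
                r for g in self.genes.values() for r in g.intron_regions()
            ]
        if not self.intergenic:
            self.intergenic = self._derive_intergenic()

    def _derive_intergenic(self) -> list[GenomicRegion]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g.span)
        out: list[GenomicRegion] = []
        buf = self.intergenic_buffer
        for chrom, spans in sorted(by_chrom.items()):
            merged = merge_intervals(spans)
            for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
                start, end = left_end + buf, right_start - buf
                if end > start:
                    out.append(GenomicRegion(chrom, start, end, ".", "intergenic"))
        return out

    def exon_regions(self) -> list[GenomicRegion]:
        return [r for g in self.genes.values() for r in g.exon_regions()]

    def gene_symbols(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class AlignmentSet:
    """Mapped single-end read placements for one subject.

    ``total_mapped`` is the per-million denominator M of RPKM: the size of
    the subject's mapped library.  It may exceed ``len(records)`` when the
    record set covers only part of the genome (e.g. simulated loci).
    """

    subject_id: str
    records: pd.DataFrame  # columns: chrom, start, end, strand
    total_mapped: int
    read_length: int = 43

    REQUIRED = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"alignment records missing columns {missing}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.total_mapped < len(self.records):
            raise ValueError(
                f"total_mapped ({self.total_mapped}) < number of records "
                f"({len(self.records)})"
            )

    def __len__(self) -> int:
        return len(self.records)


class ExpressionMatrix:
    """Gene x subject RPKM values with smoking-group labels.

    ``values`` is a DataFrame indexed by gene symbol with one column per
    subject; ``groups`` maps subject id to 'nonsmoker' or 'smoker'.
    """

    def __init__(self, values: pd.DataFrame, groups: pd.Series | dict):
        groups = pd.Series(groups)
        bad = set(groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValueError(f"subjects without group label: {missing}")
        if (values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        self.values = values.sort_index()
        self.groups = groups.loc[values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def subjects(self) -> pd.Index:
        return self.values.columns

    def subjects_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.subjects_in(group)]

    def group_median(self, group: str) -> pd.Series:
        cols = self.subjects_in(group)
        if not cols:
            raise ValueError(f"no subjects in group {group!r}")
        return self.values[cols].median(axis=1)

    def median_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nonsmoker_median": self.group_median(NONSMOKER),
                "smoker_median": self.group_median(SMOKER),
            }
        )


@dataclass
class SubjectTable:
    """Subject metadata: id, smoking group, ignored covariates."""

    table: pd.DataFrame  # columns: subject_id, group, ...

    def __post_init__(self) -> None:
        for col in ("subject_id", "group"):
            if col not in self.table.columns:
                raise ValueError(f"subject table missing column {col!r}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")

    def groups(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]


def regions_to_frame(regions: Sequence[GenomicRegion]) -> pd.DataFrame:
    """Tabulate regions for vectorised overlap work."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": np.array([r.start for r in regions], dtype=np.int64),
            "end": np.array([r.end for r in regions], dtype=np.int64),
            "kind": [r.kind for r in regions],
            "gene": [r.parent_gene for r in regions],
        }
    )
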