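"""Readers and writers for the standard formats the pipeline touches.

Annotation comes in as GTF/GFF (1-based closed coordinates) or BED6
(0-based half-open, one exon per line, name = gene symbol); alignments
as SAM (via pysam) or BED6.  Internally everything is 0-based half-open.
Tabular outputs are TSV with a deterministic column and row order.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
import pysam

from .model import AlignmentSet, Gene, GenomeAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')

FLOAT_FORMAT = "%.6f"


class AnnotationParseError(ValueError):
    pass


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_annotation(path: str | Path, intergenic_buffer: int = 0) -> GenomeAnnotation:
    """Read a GTF/GFF or BED gene annotation.

    Exons are union-merged per gene; introns and intergenic regions are
    derived deterministically.  Raises :class:`AnnotationParseError` with
    the offending line number on malformed input, and ``ValueError`` if
    the file yields zero genes.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        exons = _read_bed_exons(path)
    else:
        exons = _read_gtf_exons(path)
    if not exons:
        raise ValueError(f"empty annotation: no gene features in {path}")
    genes = {
        sym: Gene(sym, chrom, strand, ivs)
        for sym, (chrom, strand, ivs) in sorted(exons.items())
    }
    return GenomeAnnotation(genes, intergenic_buffer=intergenic_buffer)


def _read_gtf_exons(path: Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    exons: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            try:
                # GTF is 1-based closed; internal is 0-based half-open.
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            attr = _parse_gtf_attributes(attrs)
            sym = attr.get("gene_id") or attr.get("gene_name")
            if not sym:
                raise AnnotationParseError(
                    f"{path}:{lineno}: exon feature without gene_id"
                )
            rec = exons.setdefault(sym, (chrom, strand, []))
            if rec[0] != chrom:
                raise AnnotationParseError(
                    f"{path}:{lineno}: gene {sym} spans multiple chromosomes"
                )
            rec[2].append(iv)
    return exons


def _read_bed_exons(path: Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    exons: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED exon line needs at least 4 fields"
                )
            chrom, start, end, sym = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = (int(start), int(end))
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            rec = exons.setdefault(sym, (chrom, strand, []))
            rec[2].append(iv)
    return exons


def write_annotation_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as GTF exon features (1-based closed)."""
    with open(path, "w") as fh:
        for sym in sorted(annotation.genes):
            g = annotation.genes[sym]
            for start, end in g.exons:
                fh.write(
                    f"{g.chrom}\tsaetx\texon\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{sym}";\n'
                )


def write_annotation_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as BED6, one exon per line."""
    with open(path, "w") as fh:
        for sym in sorted(annotation.genes):
            g = annotation.genes[sym]
            for start, end in g.exons:
                fh.write(f"{g.chrom}\t{start}\t{end}\t{sym}\t0\t{g.strand}\n")


def read_alignments(
    path: str | Path,
    subject_id: str,
    read_length: int = 43,
    known_chroms: set[str] | None = None,
) -> AlignmentSet:
    """Read single-end read placements from SAM or BED6.

    Only mapped records are retained; ``total_mapped`` counts them.
    Records on chromosomes absent from ``known_chroms`` (when given) are
    skipped with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        records = _read_sam(path)
    else:
        records = _read_bed_reads(path)
    if known_chroms is not None:
        keep = records["chrom"].isin(known_chroms)
        skipped = int((~keep).sum())
        if skipped:
            log.warning(
                "%s: skipped %d records on unknown chromosomes", path, skipped
            )
            records = records[keep].reset_index(drop=True)
    return AlignmentSet(
        subject_id=subject_id,
        records=records,
        total_mapped=len(records),
        read_length=read_length,
    )


def _read_sam(path: Path) -> pd.DataFrame:
    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "strand": strands}
    )


def _read_bed_reads(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "strand": str},
    )
    return df


def write_sam(alignments: AlignmentSet, path: str | Path, chrom_sizes: dict[str, int]) -> None:
    """Write read placements as a headered SAM file (dual encoding of BED)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_sizes.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = {c: i for i, (c, _) in enumerate(sorted(chrom_sizes.items()))}
        for i, row in enumerate(alignments.records.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{alignments.subject_id}.{i}"
            a.reference_id = refs[row.chrom]
            a.reference_start = int(row.start)
            length = int(row.end - row.start)
            a.cigarstring = f"{length}M"
            a.query_sequence = "N" * length
            a.mapping_quality = 255
            a.flag = 16 if row.strand == "-" else 0
            out.write(a)


def write_reads_bed(alignments: AlignmentSet, path: str | Path) -> None:
    df = alignments.records
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"{alignments.subject_id}.{i}" for i in range(len(df))],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_table(table: pd.DataFrame, path: str | Path, sort_by: str | None = None) -> None:
    """Write a TSV with header, deterministic row order and fixed float precision.

    Rows are sorted by ``sort_by`` (default: the first column) so output
    does not depend on input ordering.  Floats are written at 6 decimal
    places.
    """
    table = table.copy()
    if sort_by is None and len(table.columns):
        sort_by = table.columns[0]
    if sort_by is not None and len(table):
        table = table.sort_values(sort_by, kind="mergesort")
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Serialize an expression matrix as TSV: gene, group-tagged subject columns."""
    df = matrix.values.copy()
    df.columns = [f"{s}:{matrix.groups[s]}" for s in df.columns]
    df.insert(0, "gene", df.index)
    write_table(df, path, sort_by="gene")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t").set_index("gene").rename_axis(None)
    groups = {}
    cols = {}
    for col in df.columns:
        subject, group = col.rsplit(":", 1)
        groups[subject] = group
        cols[col] = subject
    df = df.rename(columns=cols)
    return ExpressionMatrix(df, groups)
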