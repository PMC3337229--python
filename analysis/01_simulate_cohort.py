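#!/usr/bin/env python
"""Generate the synthetic study cohort: annotation, truth, reads.

Creates a 500-gene annotation on one synthetic chromosome, draws true
per-subject RPKM for 5 nonsmokers and 6 smokers (between-subject CV
0.25, 10% of genes smoking-responsive), places exonic and background
reads at 5 M reads per subject, and generates junction-spanning reads.
Writes the annotation (GTF), per-subject reads (BED), truth tables and
subject metadata under results/cohort/.
"""

from pathlib import Path

import pandas as pd

from saetx.io import write_annotation_gtf, write_reads_bed, write_table
from saetx.simulate import (
    SimulationConfig,
    make_annotation,
    simulate_expression,
    simulate_junction_reads,
    simulate_reads,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20120229


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_genes=500, depth=5_000_000, seed=SEED)
    annotation = make_annotation(cfg)
    truth = simulate_expression(cfg, annotation, seed=SEED + 1)
    reads = simulate_reads(truth, annotation, cfg.depth, seed=SEED + 2)
    junction_reads = simulate_junction_reads(
        truth, annotation, cfg.depth, seed=SEED + 3
    )

    write_annotation_gtf(annotation, OUT / "annotation.gtf")
    for aln in reads:
        write_reads_bed(aln, OUT / f"reads_{aln.subject_id}.bed")
    truth_table = truth.rpkm.copy()
    truth_table.insert(0, "gene", truth_table.index)
    write_table(truth_table, OUT / "truth_rpkm.tsv", sort_by="gene")
    write_table(
        pd.DataFrame(
            {"gene": truth.effects.index, "effect": truth.effects.to_numpy()}
        ),
        OUT / "truth_effects.tsv",
        sort_by="gene",
    )
    junction_reads.to_csv(OUT / "junction_reads.tsv", sep="\t", index=False)
    subjects = pd.DataFrame(
        {"subject_id": list(truth.groups), "group": list(truth.groups.values())}
    )
    write_table(subjects, OUT / "subjects.tsv", sort_by="subject_id")

    n_reads = sum(len(a) for a in reads)
    print(f"cohort: {cfg.n_genes} genes, {len(reads)} subjects")
    print(f"  {n_reads} genomic reads placed ({cfg.depth} library size/subject)")
    print(f"  {len(junction_reads)} junction-spanning reads")
    print(f"  {len(truth.responsive_genes)} genes carry a smoking effect")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
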