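"""End-to-end orchestration of the analysis stages on a synthetic cohort.

``run_all`` executes the stages in dependency order — simulate,
quantify, detection threshold, composition, gene families, differential
expression, splicing — writing each stage's tables (TSV) plus a JSON
summary and a plain-text log to the output directory.  Re-running with
the same configuration and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, differential, families, quantify, splicing, threshold
from .io import write_expression_matrix, write_table
from .model import ExpressionMatrix
from .simulate import (
    SimulationConfig,
    make_annotation,
    simulate_expression,
    simulate_family_sequences,
    simulate_junction_reads,
    simulate_reads,
    threshold_mixture,
)

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "quantify",
    "threshold",
    "composition",
    "families",
    "differential",
    "splicing",
)


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    detection_threshold: float = 0.125
    n_threshold_exons: int = 4000
    family_n: int = 6
    family_members: int = 3
    family_identity: float = 92.0
    seed: int = 0


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("saetx")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        summary = _run_stages(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run_stages(config: PipelineConfig, outdir: Path) -> dict:
    sim = config.simulation
    seed = config.seed
    summary: dict = {"seed": seed}

    log.info("stage simulate: %d genes, %d+%d subjects", sim.n_genes,
             sim.n_nonsmokers, sim.n_smokers)
    annotation = make_annotation(sim, seed=seed)
    truth = simulate_expression(sim, annotation, seed=seed + 1)
    reads = simulate_reads(
        truth, annotation, sim.depth, seed=seed + 2,
        read_length=sim.read_length,
        background_relative_density=sim.background_relative_density,
    )
    junction_reads = simulate_junction_reads(
        truth, annotation, sim.depth, seed=seed + 3,
        read_length=sim.read_length, min_overlap=sim.min_overlap,
    )
    truth_table = truth.rpkm.copy()
    truth_table.insert(0, "gene", truth_table.index)
    write_table(truth_table, outdir / "truth_rpkm.tsv", sort_by="gene")
    summary["simulate"] = {
        "n_genes": sim.n_genes,
        "n_reads": int(sum(len(a) for a in reads)),
        "n_junction_reads": int(len(junction_reads)),
    }

    log.info("stage quantify")
    matrix = quantify.expression_matrix(reads, annotation, truth.groups)
    write_expression_matrix(matrix, outdir / "expression_matrix.tsv")
    summary["quantify"] = {"n_genes": int(matrix.values.shape[0])}

    log.info("stage threshold")
    exon_vals, intergenic_vals = threshold_mixture(
        n_exons=config.n_threshold_exons,
        n_intergenic=config.n_threshold_exons,
        seed=seed + 4,
        cross_at=config.detection_threshold,
    )
    curves = threshold.estimate_threshold(exon_vals, intergenic_vals)
    write_table(
        pd.DataFrame({"level": curves.grid, "fdr": curves.fdr, "fnr": curves.fnr}),
        outdir / "threshold_curves.tsv",
        sort_by="level",
    )
    n_expressed = threshold.expressed_count_at(matrix, curves.threshold)
    summary["threshold"] = {
        "threshold": curves.threshold,
        "non_crossing": curves.non_crossing,
        "n_expressed": n_expressed,
    }

    log.info("stage composition")
    medians = matrix.group_median("nonsmoker")
    reference = [g for i, g in enumerate(sorted(truth.base_rpkm.index)) if i % 2 == 0]
    partition = composition.classify_ubiquitous(
        medians, reference, threshold=config.detection_threshold
    )
    write_table(partition, outdir / "partition.tsv", sort_by="gene")
    profile = composition.abundance_profile(medians)
    summary["composition"] = composition.partition_summary(partition) | {
        "top_gene_fraction": float(profile.fractions[0]),
    }

    log.info("stage families")
    seqs, membership = simulate_family_sequences(
        n_families=config.family_n,
        members=config.family_members,
        target_identity=config.family_identity,
        seed=seed + 5,
    )
    clusters = families.build_families(seqs)
    fam_medians = pd.Series(
        np.round(10.0 ** np.random.default_rng(seed + 6).normal(1, 1, len(seqs)), 4),
        index=sorted(seqs),
    )
    write_table(
        families.family_expression(clusters, fam_medians),
        outdir / "families.tsv",
        sort_by="family_id",
    )
    summary["families"] = {"n_families": len(clusters)}

    log.info("stage differential")
    records = differential.differential_table(
        matrix, alpha=config.alpha,
        expressed_threshold=config.detection_threshold,
    )
    write_table(records, outdir / "differential.tsv", sort_by="gene")
    write_table(
        differential.volcano_table(records), outdir / "volcano.tsv", sort_by="gene"
    )
    true_resp = set(truth.responsive_genes)
    called = set(records.loc[records["responsive"], "gene"])
    summary["differential"] = {
        "n_tested": int(len(records)),
        "n_responsive": int(records["responsive"].sum()),
        "n_true_responsive_recovered": len(true_resp & called),
    }

    log.info("stage splicing")
    junctions = splicing.build_junction_db(
        annotation, sim.read_length, sim.min_overlap
    )
    counts = splicing.count_junction_reads(
        junction_reads, junctions, sim.read_length, sim.min_overlap
    )
    depths = {a.subject_id: a.total_mapped for a in reads}
    usage = splicing.usage_table(counts, junctions, depths, matrix)
    write_table(usage, outdir / "junction_usage.tsv", sort_by="junction_id")
    flt = splicing.filter_junctions(usage, matrix)
    write_table(flt, outdir / "junction_filters.tsv", sort_by="junction_id")
    retained = usage[usage["junction_id"].isin(flt.loc[flt["retained"], "junction_id"])]
    test = splicing.junction_test(retained, truth.groups)
    write_table(test, outdir / "junction_test.tsv", sort_by="junction_id")
    summary["splicing"] = {
        "n_junctions": len(junctions),
        "n_retained": int(flt["retained"].sum()),
        "qq_inflation": splicing.qq_inflation(test),
    }
    return summary


# Published group medians (RPKM) for the genes with the largest smoking
# effects; used as the worked example for the effect-size arithmetic.
# Columns: gene, nonsmoker median, smoker median.
REFERENCE_SMOKING_MEDIANS = pd.DataFrame(
    [
        ("MSMB", 333.1, 3112.7),
        ("ALDH3A1", 226.9, 2077.9),
        ("TFF3", 149.4, 697.9),
        ("NQO1", 38.3, 198.7),
        ("SCGB1A1", 38675.4, 17244.0),
        ("SCGB3A1", 7838.2, 2947.3),
    ],
    columns=["gene", "nonsmoker_median", "smoker_median"],
)


def replicate_smoking_table(medians: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute absolute change and signed fold-change from group medians.

    ``medians`` needs gene/nonsmoker_median/smoker_median columns and
    defaults to the published worked-example rows.  The derived columns
    are rounded to one decimal, the precision of the source table.
    """
    if medians is None:
        medians = REFERENCE_SMOKING_MEDIANS
    out = medians.copy()
    out["absolute_change"] = [
        round(differential.absolute_change(ns, s), 1)
        for ns, s in zip(out["nonsmoker_median"], out["smoker_median"])
    ]
    out["fold_change"] = [
        round(differential.signed_fold_change(ns, s), 1)
        for ns, s in zip(out["nonsmoker_median"], out["smoker_median"])
    ]
    return out
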