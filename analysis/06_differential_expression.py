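#!/usr/bin/env python
"""Smoking differential expression on the quantified cohort.

Tests every expressed gene (Welch t-test, uncorrected p < 0.05),
reports absolute change and signed fold-change, emits the modified
volcano table (absolute change vs -log10 p), stratifies responsiveness
by partition x tier, checks recovery of the simulated smoking effects,
and reproduces the published worked-example effect sizes from their
printed group medians.
Writes results/differential/{records.tsv,volcano.tsv,strata.tsv,...}.
"""

import json
from pathlib import Path

from saetx.differential import (
    concordance,
    differential_table,
    responsive_by_stratum,
    signed_fold_change,
    volcano_table,
)
from saetx.io import read_expression_matrix, read_table, write_table
from saetx.pipeline import replicate_smoking_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_matrix(ROOT / "expression" / "expression_matrix.tsv")
    records = differential_table(matrix, alpha=0.05)
    write_table(records, out / "records.tsv", sort_by="gene")
    write_table(volcano_table(records), out / "volcano.tsv", sort_by="gene")

    partition = read_table(ROOT / "composition" / "partition.tsv")
    strata = responsive_by_stratum(records, partition)
    write_table(strata, out / "strata.tsv", sort_by="label")

    # recovery of the simulated smoking effects
    effects = read_table(ROOT / "cohort" / "truth_effects.tsv").set_index("gene")
    truth_fc = effects.loc[effects["effect"] != 1.0, "effect"]
    called = set(records.loc[records["responsive"], "gene"])
    recovered = len(called & set(truth_fc.index))

    # concordance of estimated vs true fold-changes on responsive genes
    est_fc = records.set_index("gene").loc[
        records.set_index("gene").index.intersection(truth_fc.index)
    ]["fold_change"]
    true_signed = truth_fc.apply(
        lambda e: e if e >= 1 else -1.0 / e
    )
    conc = concordance(est_fc, true_signed)

    table7 = replicate_smoking_table()
    write_table(table7, out / "worked_examples.tsv", sort_by="gene")

    summary = {
        "n_tested": int(len(records)),
        "n_responsive": int(records["responsive"].sum()),
        "n_true_effects": int(len(truth_fc)),
        "n_true_effects_called": recovered,
        "fc_concordance_r2": conc["r2"],
        "fc_sign_agreement": conc["sign_agreement"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"tested {summary['n_tested']} expressed genes; "
          f"{summary['n_responsive']} responsive at p < 0.05")
    print(f"  true effects called: {recovered}/{len(truth_fc)}; "
          f"fold-change r2 vs truth {conc['r2']:.3f}, "
          f"sign agreement {conc['sign_agreement']:.2f}")
    print("  worked examples (printed medians -> delta, fold-change):")
    for r in table7.itertuples():
        print(f"    {r.gene:8s} {r.nonsmoker_median:9.1f} {r.smoker_median:9.1f}"
              f" -> {r.absolute_change:9.1f} {r.fold_change:6.1f}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
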