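"""Junction database, usage normalisation, filter cascade and testing."""

import numpy as np
import pandas as pd
import pytest

from saetx.model import ExpressionMatrix, Gene, GenomeAnnotation
from saetx.simulate import (
    SimulationConfig,
    make_annotation,
    simulate_expression,
    simulate_junction_reads,
)
from saetx.splicing import (
    FILTER_GENE_RPKM,
    FILTER_GENE_SE,
    FILTER_MIN_READS,
    build_junction_db,
    count_junction_reads,
    filter_junctions,
    junction_test,
    junction_usage,
    qq_inflation,
    usage_table,
)


@pytest.fixture
def multi_exon_annotation():
    return GenomeAnnotation(
        {
            "G5": Gene("G5", "chr1", "+", [(i * 1000, i * 1000 + 200) for i in range(5)]),
            "G1": Gene("G1", "chr1", "+", [(10_000, 10_500)]),
        }
    )


class TestJunctionDb:
    def test_effective_length_and_counts(self, multi_exon_annotation):
        db = build_junction_db(multi_exon_annotation, read_length=43, min_overlap=3)
        assert all(j.effective_length == 38 for j in db)  # 43 - 6 + 1
        assert len(db) == 4  # 5-exon gene; single-exon gene contributes none
        assert {j.gene for j in db} == {"G5"}

    def test_read_too_short_rejected(self, multi_exon_annotation):
        with pytest.raises(ValueError):
            build_junction_db(multi_exon_annotation, read_length=5, min_overlap=3)


class TestCountJunctionReads:
    def test_overlap_rule(self, multi_exon_annotation):
        db = build_junction_db(multi_exon_annotation)
        jid = db[0].junction_id
        reads = pd.DataFrame(
            {
                "subject": ["s1"] * 3,
                "junction_id": [jid] * 3,
                "start": [-41, -21, -2],  # 2 nt acceptor / centered / 2 nt donor
            }
        )
        counts = count_junction_reads(reads, db)
        assert counts.at[jid, "s1"] == 1  # only the centered read qualifies

    def test_matches_brute_force_offset_enumeration(self, multi_exon_annotation):
        rng = np.random.default_rng(5)
        db = build_junction_db(multi_exon_annotation)
        ids = [j.junction_id for j in db]
        reads = pd.DataFrame(
            {
                "subject": rng.choice(["s1", "s2"], 500),
                "junction_id": rng.choice(ids, 500),
                "start": rng.integers(-60, 20, 500),
            }
        )
        counts = count_junction_reads(reads, db)
        for jid in ids:
            for s in ("s1", "s2"):
                brute = sum(
                    1
                    for _, row in reads.iterrows()
                    if row["junction_id"] == jid
                    and row["subject"] == s
                    and -row["start"] >= 3  # donor overlap
                    and 43 + row["start"] >= 3  # acceptor overlap
                )
                assert counts.at[jid, s] == brute


class TestUsage:
    def test_direct_formula(self):
        assert junction_usage(19, 38, 1_000_000, 100.0) == pytest.approx(5.0)
        assert junction_usage(0, 38, 1_000_000, 100.0) == 0.0

    def test_undefined_when_flank_silent(self):
        assert np.isnan(junction_usage(3, 38, 1_000_000, 0.0))

    def test_homogeneity_count_and_depth_scale_together(self):
        u1 = junction_usage(7, 38, 1_000_000, 12.0)
        u2 = junction_usage(70, 38, 10_000_000, 12.0)
        assert u1 == pytest.approx(u2)

    def test_recovers_true_usage_ranks(self):
        cfg = SimulationConfig(
            n_genes=150, depth=10_000_000, responsive_fraction=0.0,
            junction_usage_log10_sd=0.4, seed=33,
        )
        ann = make_annotation(cfg)
        truth = simulate_expression(cfg, ann, seed=34)
        reads = simulate_junction_reads(truth, ann, cfg.depth, seed=35)
        db = build_junction_db(ann)
        counts = count_junction_reads(reads, db)
        matrix = ExpressionMatrix(truth.rpkm, truth.groups)
        depths = {s: cfg.depth for s in truth.rpkm.columns}
        usage = usage_table(counts, db, depths, matrix)
        mean_u = usage.groupby("junction_id")["usage"].mean()
        # keep junctions with enough signal for a stable mean
        total = usage.groupby("junction_id")["count"].sum()
        keep = total[total >= 20].index
        truth_u = truth.junction_usage.loc[keep]
        rho = pd.Series(mean_u.loc[keep]).corr(truth_u, method="spearman")
        assert rho > 0.95


class TestFilterCascade:
    def _toy(self):
        """10 junctions exercising every exclusion reason and combination."""
        subjects = [f"ns{i}" for i in range(2)] + [f"sm{i}" for i in range(2)]
        groups = {s: ("nonsmoker" if s.startswith("ns") else "smoker")
                  for s in subjects}
        # gene -> (nonsmoker medians level, cross-subject spread)
        gene_values = {
            "OK": [5.0, 5.2, 5.1, 5.3],
            "DIM": [0.05, 0.06, 0.05, 0.07],  # below 0.125
            "WOBBLY": [2.0, 4.5, 1.0, 4.0],  # SE > 0.5
            "QUIET": [5.0, 5.1, 5.0, 5.2],  # expressed, but no spliced reads
            "DIMWOBBLY": [0.02, 0.03, 3.0, 5.0],  # fails rpkm and SE
        }
        values = pd.DataFrame(gene_values, index=subjects).T
        matrix = ExpressionMatrix(values, groups)
        rows = []

        def add(jid, gene, ns_counts, sm_counts):
            for s, c in zip(subjects, ns_counts + sm_counts):
                rows.append(
                    {"junction_id": jid, "gene": gene, "subject": s,
                     "count": c, "usage": float(c)}
                )

        add("j01", "OK", [5, 4], [6, 3])          # retained
        add("j02", "OK", [2, 0], [0, 0])          # retained: one group >= 2
        add("j03", "OK", [1, 0], [0, 1])          # min-reads (totals 1 and 1)
        add("j04", "DIM", [9, 9], [9, 9])         # gene-rpkm
        add("j05", "WOBBLY", [9, 9], [9, 9])      # gene-SE
        add("j06", "DIM", [1, 0], [1, 0])         # gene-rpkm + min-reads
        add("j07", "WOBBLY", [0, 1], [0, 0])      # gene-SE + min-reads
        add("j08", "DIMWOBBLY", [8, 8], [8, 8])   # gene-rpkm + gene-SE
        add("j09", "DIMWOBBLY", [0, 0], [1, 0])   # all three
        add("j10", "QUIET", [0, 2], [5, 5])       # retained
        return pd.DataFrame(rows), matrix, groups

    def test_each_exclusion_reason(self):
        usage, matrix, _ = self._toy()
        out = filter_junctions(usage, matrix).set_index("junction_id")
        assert set(out.index[out["retained"]]) == {"j01", "j02", "j10"}
        assert out.at["j03", "reason"] == FILTER_MIN_READS
        assert out.at["j04", "reason"] == FILTER_GENE_RPKM
        assert out.at["j05", "reason"] == FILTER_GENE_SE
        assert set(out.at["j06", "reason"].split(",")) == {
            FILTER_GENE_RPKM, FILTER_MIN_READS,
        }
        assert set(out.at["j09", "reason"].split(",")) == {
            FILTER_GENE_RPKM, FILTER_MIN_READS, FILTER_GENE_SE,
        }

    def test_order_independence_under_row_permutation(self):
        usage, matrix, _ = self._toy()
        base = filter_junctions(usage, matrix)
        rng = np.random.default_rng(3)
        shuffled = usage.sample(frac=1.0, random_state=7).reset_index(drop=True)
        again = filter_junctions(shuffled, matrix)
        pd.testing.assert_frame_equal(base, again)

    def test_all_pass_fixture_retains_everything(self):
        usage, matrix, _ = self._toy()
        sub = usage[usage["junction_id"].isin(["j01", "j02", "j10"])]
        out = filter_junctions(sub, matrix)
        assert out["retained"].all()

    def test_published_se_example(self):
        # a gene with RPKM standard error 0.6 across subjects is excluded
        subjects = [f"s{i}" for i in range(11)]
        groups = {s: ("nonsmoker" if i < 5 else "smoker")
                  for i, s in enumerate(subjects)}
        target_sd = 0.6 * np.sqrt(11)
        vals = np.array([1.0, 3.0] * 5 + [2.0])
        vals = 5.0 + (vals - vals.mean()) * target_sd / vals.std(ddof=1)
        matrix = ExpressionMatrix(
            pd.DataFrame([vals], index=["G"], columns=subjects), groups
        )
        usage = pd.DataFrame(
            {"junction_id": ["j1"] * 11, "gene": ["G"] * 11,
             "subject": subjects, "count": [5] * 11, "usage": [1.0] * 11}
        )
        out = filter_junctions(usage, matrix)
        assert not out["retained"].iloc[0]
        assert out["reason"].iloc[0] == FILTER_GENE_SE


class TestJunctionTest:
    def test_identical_usage_p_one(self):
        subjects = [f"ns{i}" for i in range(3)] + [f"sm{i}" for i in range(3)]
        groups = {s: ("nonsmoker" if s.startswith("ns") else "smoker")
                  for s in subjects}
        usage = pd.DataFrame(
            {"junction_id": ["j1"] * 6, "gene": ["G"] * 6, "subject": subjects,
             "count": [3] * 6, "usage": [2.0] * 6}
        )
        out = junction_test(usage, groups)
        assert out["p"].iloc[0] == 1.0

    def test_too_few_subjects_rejected(self):
        groups = {"ns1": "nonsmoker", "sm1": "smoker", "sm2": "smoker"}
        usage = pd.DataFrame(
            {"junction_id": ["j1"] * 3, "gene": ["G"] * 3,
             "subject": list(groups), "count": [1] * 3, "usage": [1.0] * 3}
        )
        with pytest.raises(ValueError, match="at least 2"):
            junction_test(usage, groups)

    def test_qq_columns_and_bh_are_coherent(self):
        rng = np.random.default_rng(41)
        subjects = [f"ns{i}" for i in range(5)] + [f"sm{i}" for i in range(6)]
        groups = {s: ("nonsmoker" if s.startswith("ns") else "smoker")
                  for s in subjects}
        rows = []
        for j in range(50):
            for s in subjects:
                rows.append(
                    {"junction_id": f"j{j:02d}", "gene": "G", "subject": s,
                     "count": 5, "usage": rng.lognormal(0, 0.3)}
                )
        out = junction_test(pd.DataFrame(rows), groups)
        assert (np.diff(out["p"]) >= 0).all()  # sorted ascending
        assert np.allclose(
            out["expected_neglog10_p"],
            -np.log10((np.arange(1, 51) - 0.5) / 50),
        )
        assert ((out["q_bh"] >= out["p"] - 1e-12) & (out["q_bh"] <= 1.0)).all()

    def test_null_inflation_near_unity(self):
        cfg = SimulationConfig(
            n_genes=400, depth=16_500_000, responsive_fraction=0.0, seed=51
        )
        ann = make_annotation(cfg)
        truth = simulate_expression(cfg, ann, seed=52)
        reads = simulate_junction_reads(truth, ann, cfg.depth, seed=53)
        db = build_junction_db(ann)
        counts = count_junction_reads(reads, db)
        matrix = ExpressionMatrix(truth.rpkm, truth.groups)
        depths = {s: cfg.depth for s in truth.rpkm.columns}
        usage = usage_table(counts, db, depths, matrix)
        flt = filter_junctions(usage, matrix)
        retained = usage[
            usage["junction_id"].isin(flt.loc[flt["retained"], "junction_id"])
        ]
        out = junction_test(retained, truth.groups)
        assert qq_inflation(out) == pytest.approx(1.0, abs=0.15)

    def test_injected_usage_shift_detected(self):
        # a 5-fold junction-usage shift in smokers should reach small p
        rng = np.random.default_rng(61)
        subjects = [f"ns{i}" for i in range(5)] + [f"sm{i}" for i in range(6)]
        groups = {s: ("nonsmoker" if s.startswith("ns") else "smoker")
                  for s in subjects}
        hits = 0
        for rep in range(20):
            rows = []
            for s in subjects:
                lam = 20.0 * (5.0 if s.startswith("sm") else 1.0)
                count = rng.poisson(lam)
                rows.append(
                    {"junction_id": "j1", "gene": "G", "subject": s,
                     "count": count, "usage": count / 20.0}
                )
            out = junction_test(pd.DataFrame(rows), groups)
            hits += out["p"].iloc[0] < 0.01
        assert hits >= 18  # >= 90% power
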