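"""Transcriptome composition: ranking, partitioning, binning, cross-tabs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from saetx.composition import (
    AbundanceProfile,
    abundance_profile,
    category_summary,
    celltype_cumulative,
    classify_ubiquitous,
    compare_profiles,
    detection_crosstab,
    fisher_exact_2xc,
    halflog_histogram,
    partition_summary,
    tier_assign,
)

# Reference rank-abundance fractions for liver: the most expressed gene
# carries 10% of all transcripts and the top ten 37%; the remaining bins
# are a synthetic split of the remainder for use as a comparison profile.
LIVER_PROFILE = AbundanceProfile(
    np.array([0.10, 0.27, 0.25, 0.20, 0.18]), source="liver"
)


class TestAbundanceProfile:
    def test_top_gene_fraction(self):
        med = pd.Series({"a": 50.0, "b": 30.0, "c": 20.0})
        prof = abundance_profile(med)
        assert prof.fractions[0] == pytest.approx(0.5)
        assert prof.fractions[1] == pytest.approx(0.5)  # ranks 2-10

    def test_matches_cumsum_oracle_on_1000_genes(self):
        rng = np.random.default_rng(2)
        med = pd.Series(10 ** rng.normal(0, 1, 1000),
                        index=[f"g{i:04d}" for i in range(1000)])
        prof = abundance_profile(med)
        ranked = np.sort(med.to_numpy())[::-1]
        total = ranked.sum()
        brute = [
            ranked[0] / total,
            ranked[1:10].sum() / total,
            ranked[10:100].sum() / total,
            ranked[100:1000].sum() / total,
            ranked[1000:].sum() / total,
        ]
        assert np.allclose(prof.fractions, brute)
        assert prof.fractions.sum() == pytest.approx(1.0)

    def test_invariant_under_uniform_rescaling(self):
        med = pd.Series({"a": 5.0, "b": 3.0, "c": 2.0})
        a = abundance_profile(med)
        b = abundance_profile(med * 7.5)
        assert np.allclose(a.fractions, b.fractions)


class TestCompareProfiles:
    def test_identical_profiles_p_one(self):
        assert compare_profiles(LIVER_PROFILE, LIVER_PROFILE) == pytest.approx(1.0)

    def test_disjoint_extremes_vanishing_p(self):
        a = AbundanceProfile(np.array([1.0, 0, 0, 0, 0]))
        b = AbundanceProfile(np.array([0, 0, 0, 0, 1.0]))
        assert compare_profiles(a, b, pseudo_total=100) < 1e-20

    @pytest.mark.parametrize(
        "table",
        [[[3, 7], [5, 2]], [[10, 2], [3, 9]], [[1, 0], [0, 1]], [[8, 8], [8, 8]]],
    )
    def test_2x2_matches_scipy_hypergeometric(self, table):
        got = fisher_exact_2xc(np.array(table))
        assert got == pytest.approx(fisher_exact(np.array(table))[1], rel=1e-9)

    def test_matches_frozen_network_algorithm_reference(self):
        # values computed once with R's fisher.test (network algorithm)
        got3 = fisher_exact_2xc(np.array([[13, 11, 20], [10, 27, 37]]))
        assert got3 == pytest.approx(0.0971928284905, rel=1e-8)
        got5 = fisher_exact_2xc(np.array([[5, 1, 9, 2, 8], [4, 3, 7, 1, 6]]))
        assert got5 == pytest.approx(0.831479680702, rel=1e-8)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xc(np.zeros((2, 5), dtype=int))


class TestPartition:
    def test_published_ubiquitous_share(self):
        expressed = pd.Series(1.0, index=[f"g{i:05d}" for i in range(15_877)])
        reference = list(expressed.index[:7_607]) + [
            f"x{i}" for i in range(290)  # reference genes not expressed here
        ]
        part = classify_ubiquitous(expressed, reference)
        summary = partition_summary(part)
        assert summary["n_ubiquitous"] == 7_607
        assert round(summary["pct_ubiquitous"]) == 48

    def test_disjoint_reference_all_enriched(self):
        expressed = pd.Series([1.0, 2.0], index=["a", "b"])
        part = classify_ubiquitous(expressed, ["zzz"])
        assert (part["label"] == "enriched").all()

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(4)
        expressed = pd.Series(
            10 ** rng.normal(0.5, 1, 300), index=[f"g{i}" for i in range(300)]
        )
        expressed = expressed[expressed > 0.125]
        ref = [f"G{i}" for i in range(0, 300, 3)]  # case-insensitive match
        part = classify_ubiquitous(expressed, ref)
        assert len(part) == len(expressed)
        assert set(part["label"]) <= {"ubiquitous", "enriched"}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_ubiquitous(pd.Series({"a": 1.0}), [])


class TestTiers:
    @pytest.mark.parametrize(
        "value,tier",
        [(0.5, "low"), (5.0, "medium"), (50.0, "high"), (1.0, "low"),
         (10.0, "medium"), (0.125, None), (0.1, None)],
    )
    def test_boundaries(self, value, tier):
        assert tier_assign(value) == tier


class TestHalfLogBinning:
    def test_single_bin(self):
        edges, counts = halflog_histogram(np.array([0.2, 0.3, 0.25]))
        assert counts.sum() == 3
        assert (counts > 0).sum() == 1

    def test_conservation_and_edges_match_direct_log10(self):
        rng = np.random.default_rng(6)
        values = 10 ** rng.uniform(-0.9, 3.5, 1000)
        edges, counts = halflog_histogram(values)
        assert counts.sum() == 1000
        k = np.floor((np.log10(values) + 0.9) / 0.5).astype(int)
        brute = np.bincount(k - min(0, k.min()), minlength=len(counts))
        assert np.array_equal(counts, brute)
        assert np.allclose(np.log10(edges[1:] / edges[:-1]), 0.5)

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            halflog_histogram(np.array([0.0, 1.0]))


class TestCelltypeCumulative:
    def test_point_mass_is_step_function(self):
        med = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        curve = celltype_cumulative(med, ["a", "b", "c"])
        assert curve["cumulative_frequency"].iloc[-1] == pytest.approx(1.0)
        assert (curve["cumulative_frequency"] > 0).sum() == 1 or len(curve) == 1

    def test_matches_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        med = pd.Series(10 ** rng.normal(0.5, 1, 400),
                        index=[f"g{i}" for i in range(400)])
        subset = [f"g{i}" for i in range(0, 400, 7)]
        curve = celltype_cumulative(med, subset)
        vals = np.sort(med.loc[subset].to_numpy())
        for level, cf in zip(curve["level"], curve["cumulative_frequency"]):
            assert cf == pytest.approx((vals < level).mean())
        assert (np.diff(curve["cumulative_frequency"]) >= 0).all()

    def test_empty_intersection_names_missing(self):
        med = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="missing.*ZZZ"):
            celltype_cumulative(med, ["ZZZ"])


class TestCategorySummary:
    def _partition(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "median_rpkm": [2.0, 8.0, 0.5, 30.0],
                "label": ["ubiquitous", "ubiquitous", "enriched", "enriched"],
                "tier": ["medium", "medium", "low", "high"],
            }
        )

    def test_single_gene_category_median(self):
        cmap = pd.DataFrame({"gene": ["a"], "category": ["transcription"]})
        out = category_summary(self._partition(), cmap)
        assert len(out) == 1
        assert out["median_rpkm"].iloc[0] == pytest.approx(2.0)
        assert out["pct_of_category"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100_within_category(self):
        cmap = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"], "category": ["x", "x", "x", "x"]}
        )
        out = category_summary(self._partition(), cmap)
        assert out["pct_of_category"].sum() == pytest.approx(100.0)

    def test_medians_match_direct_computation(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(50)]
        part = pd.DataFrame(
            {
                "gene": genes,
                "median_rpkm": 10 ** rng.normal(0.5, 1, 50),
                "label": ["ubiquitous" if i % 2 else "enriched" for i in range(50)],
                "tier": ["low"] * 50,
            }
        )
        cmap = pd.DataFrame({"gene": genes, "category": ["c"] * 50})
        out = category_summary(part, cmap).set_index("label")
        for label in ("ubiquitous", "enriched"):
            expected = part.loc[part["label"] == label, "median_rpkm"].median()
            assert out.loc[label, "median_rpkm"] == pytest.approx(expected)


class TestDetectionCrosstab:
    def test_all_present_everywhere(self):
        part = pd.DataFrame(
            {"gene": ["a", "b"], "median_rpkm": [1, 2],
             "label": ["ubiquitous"] * 2, "tier": ["medium"] * 2}
        )
        pcalls = pd.DataFrame({"gene": ["a", "b"], "percent_present": [100, 100]})
        out = detection_crosstab(part, pcalls).set_index("class")
        assert out.loc["present_gt50", "pct"] == pytest.approx(100.0)

    def test_missing_gene_lands_in_no_probe(self):
        part = pd.DataFrame(
            {"gene": ["a"], "median_rpkm": [1], "label": ["enriched"],
             "tier": ["low"]}
        )
        out = detection_crosstab(part, pd.DataFrame({"gene": [], "percent_present": []}))
        assert out.set_index("class").loc["no_probe", "n_genes"] == 1

    def test_matches_tally_oracle_on_30_gene_fixture(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(30)]
        part = pd.DataFrame(
            {"gene": genes, "median_rpkm": rng.uniform(0.2, 50, 30),
             "label": ["ubiquitous"] * 30,
             "tier": [("low", "medium", "high")[i % 3] for i in range(30)]}
        )
        pcalls = pd.DataFrame(
            {"gene": genes[:20], "percent_present": rng.uniform(0, 100, 20)}
        )
        out = detection_crosstab(part, pcalls)
        pp = pcalls.set_index("gene")["percent_present"]
        for tier in ("low", "medium", "high"):
            sub = part[part["tier"] == tier]
            hi = sum(1 for g in sub["gene"] if g in pp.index and pp[g] > 50)
            lo = sum(1 for g in sub["gene"] if g in pp.index and pp[g] <= 50)
            absent = len(sub) - hi - lo
            pivot = out[out["tier"] == tier].set_index("class")["n_genes"]
            assert (pivot["present_gt50"], pivot["present_le50"], pivot["no_probe"]) == (hi, lo, absent)
            assert out[out["tier"] == tier]["pct"].sum() == pytest.approx(100.0)
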