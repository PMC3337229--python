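"""Two-group differential expression on the RPKM scale.

Smoking-responsive genes are called by an uncorrected two-sample t-test
(Welch by default) on raw RPKM, 5 nonsmokers vs 6 smokers, p < 0.05 with
no fold-change cutoff.  Effect sizes are reported two ways:

* absolute change  Δ = smoker median - nonsmoker median (RPKM units),
  the axis of the "modified volcano" plot (Δ vs -log10 p);
* signed fold-change  FC = s/ns when s >= ns, else -(ns/s), so the
  magnitude is always >= 1 and the sign carries the direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, NONSMOKER, SMOKER


def welch_or_pooled_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> np.ndarray:
    """Row-wise two-sample t-test p-values with degenerate rows resolved.

    Rows where both groups have zero variance get p = 1 when the means
    agree (no evidence of difference) and p = 0 when they differ (an
    infinite t statistic in the limit).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows are resolved explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    return p


def smoking_test(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    expressed_threshold: float = 0.125,
    equal_var: bool = False,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test p-values and responsive calls.

    Only genes expressed (group median above ``expressed_threshold`` in
    at least one group) are tested.  ``log_scale`` applies the test to
    log10(RPKM + 1e-3) instead of raw RPKM.
    """
    ns = matrix.group_values(NONSMOKER)
    sm = matrix.group_values(SMOKER)
    if ns.shape[1] < 2 or sm.shape[1] < 2:
        raise ValueError("each group needs at least 2 subjects")
    expressed = (
        (ns.median(axis=1) > expressed_threshold)
        | (sm.median(axis=1) > expressed_threshold)
    )
    ns, sm = ns[expressed], sm[expressed]
    a, b = ns.to_numpy(), sm.to_numpy()
    if log_scale:
        a, b = np.log10(a + 1e-3), np.log10(b + 1e-3)
    p = welch_or_pooled_ttest(a, b, equal_var=equal_var)
    return pd.DataFrame(
        {"gene": ns.index, "p": p, "responsive": p < alpha}
    ).set_index("gene")


def signed_fold_change(ns_median: float, s_median: float) -> float:
    """Ratio of group medians with sign for direction; NaN when undefined.

    FC = s/ns when s >= ns, else -(ns/s): the magnitude is always >= 1.
    A zero (or negative) median leaves the ratio undefined.
    """
    if ns_median <= 0 or s_median <= 0:
        return np.nan
    if s_median >= ns_median:
        return s_median / ns_median
    return -(ns_median / s_median)


def absolute_change(ns_median: float, s_median: float) -> float:
    """Δ = smoker median - nonsmoker median, in RPKM."""
    return s_median - ns_median


def differential_table(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    expressed_threshold: float = 0.125,
    equal_var: bool = False,
) -> pd.DataFrame:
    """One record per expressed gene: medians, Δ, FC, p, -log10 p, call."""
    test = smoking_test(
        matrix, alpha=alpha, expressed_threshold=expressed_threshold,
        equal_var=equal_var,
    )
    ns_med = matrix.group_median(NONSMOKER).loc[test.index]
    s_med = matrix.group_median(SMOKER).loc[test.index]
    fc = [signed_fold_change(a, b) for a, b in zip(ns_med, s_med)]
    out = pd.DataFrame(
        {
            "gene": test.index,
            "nonsmoker_median": ns_med.to_numpy(),
            "smoker_median": s_med.to_numpy(),
            "absolute_change": (s_med - ns_med).to_numpy(),
            "fold_change": fc,
            "p": test["p"].to_numpy(),
            "neglog10_p": -np.log10(np.clip(test["p"].to_numpy(), 1e-300, None)),
            "responsive": test["responsive"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """(gene, Δ, -log10 p) triples for the modified volcano plot."""
    return records[["gene", "absolute_change", "neglog10_p"]].copy()


def responsive_by_stratum(
    records: pd.DataFrame, partition: pd.DataFrame
) -> pd.DataFrame:
    """Percent responsive per (ubiquitous/enriched x low/medium/high) stratum.

    ``partition`` must carry gene/label/tier columns (see
    :func:`saetx.composition.classify_ubiquitous` and ``tier_assign``).
    """
    merged = records.merge(partition[["gene", "label", "tier"]], on="gene")
    rows = []
    for (label, tier), sub in merged.groupby(["label", "tier"], sort=True):
        n = len(sub)
        k = int(sub["responsive"].sum())
        rows.append(
            {
                "label": label,
                "tier": tier,
                "n_genes": n,
                "n_responsive": k,
                "pct_responsive": 100.0 * k / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def direction_by_category(
    records: pd.DataFrame, category_map: pd.DataFrame
) -> pd.DataFrame:
    """Induced/repressed responsive genes per category, ordered by |Δ|.

    ``category_map`` has columns gene/category.  Induced means Δ > 0.
    Adds log10 |Δ| for the magnitude display; genes with Δ = 0 are
    listed as unchanged and carry NaN magnitude.
    """
    resp = records[records["responsive"]]
    merged = resp.merge(category_map, on="gene")
    delta = merged["absolute_change"]
    merged = merged.assign(
        direction=np.select([delta > 0, delta < 0], ["induced", "repressed"],
                            default="unchanged"),
        abs_change=delta.abs(),
        log10_abs_change=np.where(delta != 0, np.log10(delta.abs()), np.nan),
    )
    merged = merged.sort_values(
        ["category", "direction", "abs_change"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    return merged[
        ["category", "direction", "gene", "absolute_change", "log10_abs_change"]
    ].reset_index(drop=True)


def concordance(fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Cross-platform fold-change agreement on the shared gene set.

    Returns Pearson r^2 on signed fold-changes, the fraction of genes
    whose direction agrees, and the per-gene pairs.  r^2 and sign
    agreement are deliberately separate: perfectly anti-correlated
    fold-changes give r^2 = 1 with sign agreement 0.
    """
    shared = fc_a.index.intersection(fc_b.index)
    a, b = fc_a.loc[shared].astype(float), fc_b.loc[shared].astype(float)
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 shared genes with defined fold-changes")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero variance in one fold-change vector")
    r, _ = stats.pearsonr(a, b)
    pairs = pd.DataFrame({"gene": a.index, "fc_a": a.to_numpy(), "fc_b": b.to_numpy()})
    return {
        "r2": float(r**2),
        "sign_agreement": float((np.sign(a) == np.sign(b)).mean()),
        "n": int(len(a)),
        "pairs": pairs,
    }
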