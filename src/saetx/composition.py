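"""Composition of the expressed transcriptome.

Given per-gene nonsmoker median RPKM this module ranks genes by
abundance, partitions the expressed set into ubiquitous versus
tissue-enriched genes against a reference list, assigns expression tiers
(low/medium/high), bins expression on a half-log10 grid anchored at the
detection limit, summarises functional categories and cell-type gene
sets, and cross-tabulates detection against microarray present calls.

Rank-abundance profiles from two tissues are compared with an exact
Fisher test on a 2 x 5 contingency table; because the profiles are
fractions, they are first converted to integer counts out of a common
pseudo-total (largest-remainder rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import ExpressionMatrix, NONSMOKER

RANK_BINS = ((1, 1), (2, 10), (11, 100), (101, 1000), (1001, None))
RANK_BIN_LABELS = ("1", "2-10", "11-100", "101-1000", ">1000")

TIER_LOW = "low"
TIER_MEDIUM = "medium"
TIER_HIGH = "high"

UBIQUITOUS = "ubiquitous"
ENRICHED = "enriched"

HALF_LOG_START = -0.9  # log10 of the detection limit, 0.125 ~ 10^-0.9


@dataclass
class AbundanceProfile:
    """Fraction of total mRNA contributed by gene-rank bins."""

    fractions: np.ndarray  # one fraction per RANK_BINS entry
    source: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(RANK_BINS),):
            raise ValueError(f"profile needs {len(RANK_BINS)} bin fractions")
        if (self.fractions < 0).any():
            raise ValueError("bin fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("bin fractions must sum to 1")


def abundance_profile(
    medians: pd.Series | ExpressionMatrix,
    group: str = NONSMOKER,
    source: str = "SAE",
) -> AbundanceProfile:
    """Rank genes by median RPKM (descending, ties by symbol) and bin them."""
    if isinstance(medians, ExpressionMatrix):
        medians = medians.group_median(group)
    medians = medians[medians > 0]
    if medians.empty:
        raise ValueError("no expressed genes to profile")
    ranked = medians.sort_index().sort_values(ascending=False, kind="mergesort")
    total = float(ranked.sum())
    fractions = []
    for lo, hi in RANK_BINS:
        hi = len(ranked) if hi is None else hi
        fractions.append(float(ranked.iloc[lo - 1: hi].sum()) / total)
    return AbundanceProfile(np.array(fractions), source=source)


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total``, proportional to fractions."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    counts[order[:short]] += 1
    return counts


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2 x C contingency table.

    Enumerates all tables with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table (two-sided, conditional-probability ordering — the
    convention of the classical network algorithm).  Matches the 2 x 2
    hypergeometric test exactly when C = 2.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x C")
    if table.sum() == 0:
        raise ValueError("degenerate all-zero table")
    col = table.sum(axis=0)
    keep = col > 0
    table, col = table[:, keep], col[keep]
    r1 = int(table[0].sum())
    n = int(table.sum())
    c = len(col)
    lchoose_cols = [
        gammaln(cj + 1) - gammaln(np.arange(cj + 1) + 1) - gammaln(cj - np.arange(cj + 1) + 1)
        for cj in col
    ]
    denom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
    # work with the numerator log-weights; divide by the denominator at the end
    logp_obs = sum(lchoose_cols[j][table[0, j]] for j in range(c))
    tol = logp_obs + 1e-7  # relative tie tolerance on the log scale

    suffix_max = np.concatenate([np.cumsum(col[::-1])[::-1], [0]])

    total = 0.0

    def recurse(j: int, remaining: int, logp: float) -> None:
        nonlocal total
        if j == c - 1:
            if 0 <= remaining <= col[j]:
                lp = logp + lchoose_cols[j][remaining]
                if lp <= tol:
                    total += np.exp(lp - denom)
            return
        if j == c - 2:
            # vectorise the last two columns
            lo = max(0, remaining - int(col[j + 1]))
            hi = min(int(col[j]), remaining)
            if lo > hi:
                return
            a = np.arange(lo, hi + 1)
            lp = logp + lchoose_cols[j][a] + lchoose_cols[j + 1][remaining - a]
            total += np.exp(lp[lp <= tol] - denom).sum()
            return
        lo = max(0, remaining - int(suffix_max[j + 1]))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, logp + lchoose_cols[j][a])

    recurse(0, r1, 0.0)
    return float(min(total, 1.0))


def compare_profiles(
    a: AbundanceProfile, b: AbundanceProfile, pseudo_total: int = 100
) -> float:
    """Fisher's exact test p-value comparing two rank-abundance profiles.

    Each profile is expressed as integer percentages of ``pseudo_total``
    before the exact test, since the test requires counts.
    """
    table = np.vstack(
        [
            _largest_remainder_counts(a.fractions, pseudo_total),
            _largest_remainder_counts(b.fractions, pseudo_total),
        ]
    )
    return fisher_exact_2xc(table)


def tier_assign(median_rpkm: float, threshold: float = 0.125) -> str | None:
    """Expression tier: low (T, 1], medium (1, 10], high (10, inf).

    Returns None for values at or below the detection threshold (not
    expressed; the expressed call is a strict inequality).
    """
    if median_rpkm <= threshold:
        return None
    if median_rpkm <= 1.0:
        return TIER_LOW
    if median_rpkm <= 10.0:
        return TIER_MEDIUM
    return TIER_HIGH


def classify_ubiquitous(
    expressed_medians: pd.Series,
    reference: list[str] | set[str],
    threshold: float = 0.125,
) -> pd.DataFrame:
    """Partition expressed genes into ubiquitous vs tissue-enriched.

    Genes whose (case-insensitive) symbol appears in the reference
    ubiquitous list are labelled ubiquitous; the remainder are enriched.
    Returns one row per expressed gene: gene/median/label/tier.
    """
    if not reference:
        raise ValueError("empty ubiquitous reference list")
    ref = {str(s).upper() for s in reference}
    expressed = expressed_medians[expressed_medians > threshold]
    labels = [
        UBIQUITOUS if str(g).upper() in ref else ENRICHED for g in expressed.index
    ]
    return pd.DataFrame(
        {
            "gene": expressed.index,
            "median_rpkm": expressed.to_numpy(),
            "label": labels,
            "tier": [tier_assign(v, threshold) for v in expressed.to_numpy()],
        }
    ).reset_index(drop=True)


def partition_summary(partition: pd.DataFrame) -> dict:
    """Counts and percent shares of the ubiquitous/enriched partition."""
    n = len(partition)
    n_ubi = int((partition["label"] == UBIQUITOUS).sum())
    return {
        "n_expressed": n,
        "n_ubiquitous": n_ubi,
        "n_enriched": n - n_ubi,
        "pct_ubiquitous": 100.0 * n_ubi / n if n else 0.0,
        "pct_enriched": 100.0 * (n - n_ubi) / n if n else 0.0,
    }


def halflog_histogram(
    values: np.ndarray, start: float = HALF_LOG_START
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of positive values in half-log10 bins anchored at ``start``.

    Bin k covers [10^(start + k/2), 10^(start + (k+1)/2)).  The grid is
    extended downward when values fall below the anchor, so the counts
    always conserve the number of input values.  Returns (edges, counts)
    with len(edges) = len(counts) + 1.
    """
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("half-log binning requires positive values")
    if values.size == 0:
        return 10.0 ** np.array([start, start + 0.5]), np.array([0])
    k = np.floor((np.log10(values) - start) / 0.5).astype(int)
    kmin, kmax = min(0, int(k.min())), int(k.max())
    counts = np.bincount(k - kmin, minlength=kmax - kmin + 1)
    edges = 10.0 ** (start + 0.5 * np.arange(kmin, kmax + 2))
    return edges, counts


def celltype_cumulative(
    medians: pd.Series, gene_set: list[str] | set[str], start: float = HALF_LOG_START
) -> pd.DataFrame:
    """Cumulative frequency of a gene set's expression over half-log bins.

    Restricted to set members present among the (positive-median) genes;
    raises naming the missing symbols when the intersection is empty.
    Returns level (bin upper edge) and cumulative_frequency columns; the
    curve is non-decreasing from 0 to 1.
    """
    lookup = {str(g).upper(): g for g in medians.index}
    hits = [lookup[str(g).upper()] for g in gene_set if str(g).upper() in lookup]
    if not hits:
        missing = sorted(str(g) for g in gene_set)
        raise ValueError(
            f"no gene-set members among expressed genes; missing: {missing}"
        )
    values = medians.loc[sorted(set(hits))].to_numpy()
    edges, counts = halflog_histogram(values, start=start)
    cum = np.cumsum(counts) / counts.sum()
    return pd.DataFrame({"level": edges[1:], "cumulative_frequency": cum})


def category_summary(
    partition: pd.DataFrame, category_map: pd.DataFrame
) -> pd.DataFrame:
    """Per (category x label): gene count, % of category, median RPKM.

    ``category_map`` has gene/category columns; matching on symbols is
    case-insensitive.  Percentages sum to 100 within each category.
    """
    part = partition.assign(_key=partition["gene"].str.upper())
    cmap = category_map.assign(_key=category_map["gene"].str.upper())
    merged = part.merge(cmap[["_key", "category"]], on="_key")
    rows = []
    for cat, sub in merged.groupby("category", sort=True):
        for label, lab_sub in sub.groupby("label", sort=True):
            rows.append(
                {
                    "category": cat,
                    "label": label,
                    "n_genes": len(lab_sub),
                    "pct_of_category": 100.0 * len(lab_sub) / len(sub),
                    "median_rpkm": float(lab_sub["median_rpkm"].median()),
                }
            )
    return pd.DataFrame(rows)


DETECTED_HIGH = "present_gt50"
DETECTED_LOW = "present_le50"
NO_PROBE = "no_probe"


def detection_crosstab(
    partition: pd.DataFrame, pcalls: pd.DataFrame
) -> pd.DataFrame:
    """Microarray detection classes per expression tier.

    ``pcalls`` has gene/percent_present columns (percent of arrays with a
    present call).  Each expressed gene falls in exactly one class:
    present in > 50% of arrays, present in <= 50%, or absent from the
    array (no probe).  Percentages sum to 100 within each tier.
    """
    pp = pcalls.assign(_key=pcalls["gene"].astype(str).str.upper()).set_index(
        "_key"
    )["percent_present"]
    rows = []
    for tier, sub in partition.groupby("tier", sort=True):
        classes = {DETECTED_HIGH: 0, DETECTED_LOW: 0, NO_PROBE: 0}
        for g in sub["gene"]:
            key = str(g).upper()
            if key not in pp.index:
                classes[NO_PROBE] += 1
            elif pp[key] > 50.0:
                classes[DETECTED_HIGH] += 1
            else:
                classes[DETECTED_LOW] += 1
        n = len(sub)
        for cls, count in classes.items():
            rows.append(
                {
                    "tier": tier,
                    "class": cls,
                    "n_genes": count,
                    "pct": 100.0 * count / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
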