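"""Detection-limit estimation from exon versus intergenic read densities.

The minimum reliable expression level is taken where the false discovery
rate (FDR) and false negative rate (FNR) curves intersect.  With exon
RPKM values E and size-matched intergenic RPKM values I evaluated on an
ascending grid of levels x:

    FDR(x) = [#\{I >= x\} / N_I] / [#\{E >= x\} / N_E]   (clipped to [0, 1])
    TP(x)  = #\{E >= x\} * (1 - FDR(x))
    FNR(x) = 1 - TP(x) / TP(x_min)

where x_min is the lowest grid level, anchoring FNR(x_min) = 0.  The
threshold is the grid level minimising |FDR - FNR| (ties: smallest x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ExpressionMatrix, NONSMOKER


def default_grid() -> np.ndarray:
    """Half-log10-spaced RPKM levels from 1e-3 to 1e3."""
    return 10.0 ** np.arange(-3, 3.01, 0.5)


@dataclass
class ThresholdCurves:
    """Paired FDR(x)/FNR(x) curves and their intersection threshold."""

    grid: np.ndarray
    fdr: np.ndarray  # NaN where #exons >= x is zero (FDR undefined)
    fnr: np.ndarray
    threshold: float = field(default=np.nan)
    n_exons: int = 0
    n_intergenic: int = 0
    non_crossing: bool = False


def _survival_counts(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """#{values >= x} for each grid level x (values need not be sorted)."""
    v = np.sort(np.asarray(values, dtype=float))
    return len(v) - np.searchsorted(v, grid, side="left")


def fdr_curve(
    exon_rpkm: np.ndarray, intergenic_rpkm: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """FDR(x) on the grid; NaN at levels where no exon reaches x."""
    exon_rpkm = np.asarray(exon_rpkm, dtype=float)
    intergenic_rpkm = np.asarray(intergenic_rpkm, dtype=float)
    if exon_rpkm.size == 0 or intergenic_rpkm.size == 0:
        raise ValueError("both exon and intergenic samples must be non-empty")
    e = _survival_counts(exon_rpkm, grid)
    i = _survival_counts(intergenic_rpkm, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = (i / intergenic_rpkm.size) / (e / exon_rpkm.size)
    fdr = np.where(e == 0, np.nan, np.clip(fdr, 0.0, 1.0))
    return fdr


def fnr_curve(
    exon_rpkm: np.ndarray, fdr: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """FNR(x) anchored at the lowest grid level; 1 where no exon reaches x."""
    exon_rpkm = np.asarray(exon_rpkm, dtype=float)
    e = _survival_counts(exon_rpkm, grid)
    tp = np.where(np.isnan(fdr), 0.0, e * (1.0 - np.nan_to_num(fdr)))
    if tp[0] == 0:
        raise ValueError("no true positives at the lowest grid level; "
                         "cannot anchor the FNR curve")
    fnr = 1.0 - tp / tp[0]
    return np.clip(fnr, 0.0, 1.0)


def estimate_threshold(
    exon_rpkm: np.ndarray,
    intergenic_rpkm: np.ndarray,
    grid: np.ndarray | None = None,
) -> ThresholdCurves:
    """Build both curves on a shared grid and locate their intersection."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    fdr = fdr_curve(exon_rpkm, intergenic_rpkm, grid)
    fnr = fnr_curve(exon_rpkm, fdr, grid)
    curves = ThresholdCurves(
        grid=grid,
        fdr=fdr,
        fnr=fnr,
        n_exons=int(np.asarray(exon_rpkm).size),
        n_intergenic=int(np.asarray(intergenic_rpkm).size),
    )
    find_threshold(curves)
    return curves


def find_threshold(curves: ThresholdCurves) -> float:
    """Grid level minimising |FDR - FNR|; ties resolved to the smallest level.

    When the curves never cross (the sign of FDR - FNR is constant over
    the evaluable grid) the boundary minimiser is still returned but the
    result is flagged ``non_crossing`` and a warning is emitted.
    """
    ok = ~np.isnan(curves.fdr)
    if not ok.any():
        raise ValueError("FDR undefined at every grid level")
    diff = curves.fdr[ok] - curves.fnr[ok]
    gap = np.abs(diff)
    idx = int(np.argmin(gap))  # argmin returns the first (smallest x) tie
    curves.threshold = float(curves.grid[ok][idx])
    signs = np.sign(diff[np.abs(diff) > 0])
    curves.non_crossing = bool(signs.size and np.all(signs == signs[0]))
    if curves.non_crossing:
        warnings.warn(
            "FDR and FNR curves do not cross on the grid; returning the "
            f"boundary minimiser {curves.threshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    return curves.threshold


def expressed_count_at(matrix: ExpressionMatrix, threshold: float) -> int:
    """Number of genes whose nonsmoker median RPKM strictly exceeds the level."""
    med = matrix.group_median(NONSMOKER)
    return int((med > threshold).sum())


def relative_increase(n_low_threshold: int, n_high_threshold: int) -> float:
    """Percent increase in expressed-gene count when lowering the threshold.

    ``n_low_threshold`` is the (larger) count at the more permissive
    level, ``n_high_threshold`` the count at the stricter level.
    """
    if n_high_threshold <= 0:
        raise ValueError("count at the stricter threshold must be positive")
    return (n_low_threshold - n_high_threshold) / n_high_threshold * 100.0


def expressed_fraction(n_expressed: int, n_annotated: int) -> float:
    """Percent of annotated genes scored as expressed."""
    if n_annotated <= 0:
        raise ValueError("annotated gene count must be positive")
    return n_expressed / n_annotated * 100.0
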