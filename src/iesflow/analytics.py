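"""Ensemble analyses of IRS tables: histograms, size strata, Venn overlaps and
cross-condition correlation with OLS / LOWESS / orthogonal-regression trends.

Correlations are computed on the intersection of IESs with a defined score in
both conditions; undefined scores are dropped pairwise, never imputed. The
orthogonal line is total least squares (perpendicular residuals), obtained from
the eigen decomposition of the centred second-moment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .retention import IrsTable

__all__ = [
    "IesSubset",
    "CorrelationResult",
    "retention_histogram",
    "size_stratify",
    "subset_overlap",
    "correlate",
]


@dataclass
class IesSubset:
    label: str
    ids: set[str]
    provenance: str = ""


@dataclass
class CorrelationResult:
    pearson_r: float
    ols_slope: float
    ols_intercept: float
    odr_slope: float
    odr_intercept: float
    lowess_x: np.ndarray
    lowess_y: np.ndarray
    lowess_fraction: float
    n_points: int
    hexbin_counts: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def retention_histogram(
    table: IrsTable, bin_width: float = 0.05, min_irs: float = 0.1
) -> Histogram:
    """Bin defined scores strictly above ``min_irs`` into [min_irs, 1].

    The filter mirrors the retained-IES convention (strict inequality); the
    final bin is closed at 1 so a fully retained IES is counted.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    vals = np.array(
        [v for v in table.defined_scores().values() if v > min_irs], dtype=float
    )
    n_bins = int(np.ceil((1.0 - min_irs) / bin_width - 1e-12)) or 1
    edges = min_irs + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)
    if vals.size == 0:
        return Histogram(edges=edges, counts=np.zeros(n_bins, dtype=int))
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(edges=edges, counts=counts.astype(int))


@dataclass
class SizeStrata:
    cutoffs: list[int]
    counts: np.ndarray  # per stratum, len(cutoffs)+1
    fractions: np.ndarray  # within-subset fractions (NaN when subset empty)
    reference_fractions: np.ndarray | None = None  # per-stratum |subset|/|reference|

    @property
    def empty(self) -> bool:
        return int(self.counts.sum()) == 0


def _stratum_counts(ids: set[str], lengths: Mapping[str, int], cutoffs: Sequence[int]) -> np.ndarray:
    missing = [i for i in ids if i not in lengths]
    if missing:
        raise ValueError(f"missing lengths for ids: {sorted(missing)[:5]}")
    edges = [0, *cutoffs, np.inf]
    vals = np.array([lengths[i] for i in ids], dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    return counts.astype(int)


def size_stratify(
    subset: IesSubset,
    lengths: Mapping[str, int],
    cutoffs: Sequence[int] = (200,),
    reference: IesSubset | None = None,
) -> SizeStrata:
    """Fraction of subset IESs per length stratum (strata split at ``cutoffs``,
    left-closed). With a ``reference`` subset (e.g. all IESs retained after
    excisase knockdown), per-stratum fractions relative to the reference are
    also returned."""
    cutoffs = sorted(int(c) for c in cutoffs)
    counts = _stratum_counts(subset.ids, lengths, cutoffs)
    total = counts.sum()
    fractions = counts / total if total else np.full(len(counts), np.nan)
    ref_fracs = None
    if reference is not None:
        ref_counts = _stratum_counts(reference.ids, lengths, cutoffs)
        with np.errstate(divide="ignore", invalid="ignore"):
            ref_fracs = np.where(ref_counts > 0, counts / ref_counts, np.nan)
    return SizeStrata(
        cutoffs=list(cutoffs),
        counts=counts,
        fractions=fractions,
        reference_fractions=ref_fracs,
    )


def subset_overlap(subsets: Sequence[IesSubset]) -> dict[str, int]:
    """Venn partition counts for 2 or 3 subsets.

    Keys are '+'-joined subset labels; each element of the union is counted in
    exactly one region, so the region counts sum to the union cardinality.
    """
    if not 2 <= len(subsets) <= 3:
        raise ValueError("subset_overlap takes 2 or 3 subsets")
    labels = [s.label for s in subsets]
    if len(set(labels)) != len(labels):
        raise ValueError("subset labels must be unique")
    out: dict[str, int] = {}
    n = len(subsets)
    for mask in range(1, 2**n):
        inside = [s.ids for i, s in enumerate(subsets) if mask >> i & 1]
        outside = [s.ids for i, s in enumerate(subsets) if not mask >> i & 1]
        region = set.intersection(*inside)
        for o in outside:
            region -= o
        key = "+".join(l for i, l in enumerate(labels) if mask >> i & 1)
        out[key] = len(region)
    return out


def _total_least_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal (perpendicular-residual) line via eigen decomposition of the
    centred second-moment matrix; the line direction is the leading
    eigenvector."""
    xm, ym = x.mean(), y.mean()
    m = np.cov(np.vstack([x - xm, y - ym]))
    evals, evecs = np.linalg.eigh(m)
    dx, dy = evecs[:, np.argmax(evals)]
    if abs(dx) < 1e-300:
        raise ValueError("orthogonal fit is vertical; slope undefined")
    slope = dy / dx
    return float(slope), float(ym - slope * xm)


def hexbin_counts(x: np.ndarray, y: np.ndarray, gridsize: int = 40) -> np.ndarray:
    """Counts per occupied hexagon; visualization-only geometry, but the counts
    must conserve the number of points."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    try:
        coll = ax.hexbin(x, y, gridsize=gridsize)
        counts = np.asarray(coll.get_array()).astype(int)
    finally:
        plt.close(fig)
    return counts


def correlate(
    x_table: IrsTable,
    y_table: IrsTable,
    lowess_fraction: float = 0.3,
    gridsize: int = 40,
) -> CorrelationResult:
    """Pearson r plus OLS, LOWESS (tricube, 3 robustness iterations) and
    orthogonal trends, over IESs defined in both conditions."""
    xs = x_table.defined_scores()
    ys = y_table.defined_scores()
    shared = sorted(set(xs) & set(ys))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared defined records")
    x = np.array([xs[i] for i in shared])
    y = np.array([ys[i] for i in shared])

    r = float(stats.pearsonr(x, y).statistic)
    ols_slope, ols_intercept = np.polyfit(x, y, 1)
    odr_slope, odr_intercept = _total_least_squares(x, y)

    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(y, x, frac=lowess_fraction, it=3, return_sorted=True)
    counts = hexbin_counts(x, y, gridsize=gridsize)

    return CorrelationResult(
        pearson_r=r,
        ols_slope=float(ols_slope),
        ols_intercept=float(ols_intercept),
        odr_slope=odr_slope,
        odr_intercept=odr_intercept,
        lowess_x=smoothed[:, 0],
        lowess_y=smoothed[:, 1],
        lowess_fraction=lowess_fraction,
        n_points=len(shared),
        hexbin_counts=counts,
    )
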