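"""Per-IES nucleosome density from MNase and input fragment libraries.

Density of IES *i* is the dimensionless ratio of library-normalised fragment
counts, (m_i/M) / (g_i/G), where M and G are the post-downsampling mapped
totals of the MNase and input libraries. MNase libraries are first restricted
to mononucleosome-protected fragment sizes (125-175 bp inclusive), and
libraries within a group are downsampled without replacement to a common size.
Group differences are tested with the Mann-Whitney U test under Holm-Bonferroni
correction; the correction family is all comparisons passed in one call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import IesAnnotation

__all__ = [
    "FragmentRecord",
    "DensityRecord",
    "TestResult",
    "read_fragments_sam",
    "filter_fragments",
    "downsample_libraries",
    "count_over_intervals",
    "compute_density",
    "mann_whitney_u",
    "holm_bonferroni",
    "box_summary",
    "compare_groups",
]

MONONUCLEOSOME_MIN = 125
MONONUCLEOSOME_MAX = 175


@dataclass(frozen=True)
class FragmentRecord:
    scaffold: str
    start: int
    end: int
    library: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # left-median base, so an even-length fragment straddling two adjacent
        # intervals resolves to the lower-coordinate one
        return (self.start + self.end - 1) // 2


def read_fragments_sam(path: str | Path, library: str = "") -> list[FragmentRecord]:
    """Read paired alignments as fragments (leftmost mate + template length).

    Only primary, properly paired records are used; each pair yields one
    fragment, taken from the mate with positive TLEN.
    """
    out: list[FragmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_proper_pair
                or rec.template_length <= 0
            ):
                continue
            out.append(
                FragmentRecord(
                    scaffold=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_start + rec.template_length,
                    library=library,
                )
            )
    return out


def filter_fragments(
    fragments: Sequence[FragmentRecord],
    min_len: int = MONONUCLEOSOME_MIN,
    max_len: int = MONONUCLEOSOME_MAX,
) -> list[FragmentRecord]:
    """Keep fragments with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def downsample_libraries(
    libraries: Mapping[str, Sequence[FragmentRecord]], seed: int = 0
) -> dict[str, list[FragmentRecord]]:
    """Sample every library down to the smallest library size, without
    replacement, deterministically under the seed."""
    if len(libraries) < 2:
        raise ValueError("downsampling needs at least 2 libraries in a group")
    sizes = {k: len(v) for k, v in libraries.items()}
    if min(sizes.values()) == 0:
        empty = [k for k, n in sizes.items() if n == 0]
        raise ValueError(f"empty libraries: {empty}")
    target = min(sizes.values())
    rng = np.random.default_rng(seed)
    out: dict[str, list[FragmentRecord]] = {}
    for label in libraries:
        frags = list(libraries[label])
        idx = rng.choice(len(frags), size=target, replace=False)
        out[label] = [frags[i] for i in sorted(idx)]
    return out


def count_over_intervals(
    fragments: Sequence[FragmentRecord],
    annotations: Sequence[IesAnnotation],
    mode: str = "any-overlap",
) -> dict[str, int]:
    """Per-IES fragment counts.

    ``any-overlap``: a fragment counts toward every IES it overlaps by >= 1 bp
    (interval-count semantics of the usual counting tools); ``midpoint``: it
    counts toward the unique IES containing its midpoint, ties resolved to the
    lower-coordinate IES. Annotated intervals are non-overlapping per scaffold.
    """
    if mode not in ("any-overlap", "midpoint"):
        raise ValueError("mode must be 'any-overlap' or 'midpoint'")
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    arrs = {}
    for s, lst in by_scaffold.items():
        lst.sort(key=lambda a: a.start_mic)
        arrs[s] = (
            np.array([a.start_mic for a in lst]),
            np.array([a.end_mic for a in lst]),
            lst,
        )
    counts = {a.ies_id: 0 for a in annotations}
    for f in fragments:
        if f.scaffold not in arrs:
            raise ValueError(f"fragment scaffold {f.scaffold!r} not in annotation")
        starts, ends, lst = arrs[f.scaffold]
        if mode == "any-overlap":
            lo = int(np.searchsorted(ends, f.start, side="right"))
            hi = int(np.searchsorted(starts, f.end, side="left"))
            for j in range(lo, hi):
                counts[lst[j].ies_id] += 1
        else:
            mid = f.midpoint
            j = int(np.searchsorted(starts, mid, side="right")) - 1
            if j >= 0 and mid < ends[j]:
                counts[lst[j].ies_id] += 1
    return counts


@dataclass
class DensityRecord:
    ies_id: str
    mnase_count: int
    input_count: int
    density: float | None

    @property
    def defined(self) -> bool:
        return self.density is not None


def compute_density(
    mnase_counts: Mapping[str, int],
    input_counts: Mapping[str, int],
    mnase_total: int,
    input_total: int,
) -> list[DensityRecord]:
    """density_i = (m_i / M) / (g_i / G); undefined where the input count is
    zero (flagged, excluded from downstream tests)."""
    if mnase_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be > 0")
    out: list[DensityRecord] = []
    for ies_id in mnase_counts:
        m = int(mnase_counts[ies_id])
        g = int(input_counts.get(ies_id, 0))
        if m < 0 or g < 0:
            raise ValueError("negative fragment counts")
        density = (m / mnase_total) / (g / input_total) if g > 0 else None
        out.append(DensityRecord(ies_id=ies_id, mnase_count=m, input_count=g, density=density))
    return out


# ---------------------------------------------------------------------------
# statistics


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by enumeration when the pooled sample has at most 12 observations
    and no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, restored to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class TestResult:
    comparison: str
    u_statistic: float
    p_raw: float
    p_adj: float
    n_x: int
    n_y: int


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[TestResult]:
    """Mann-Whitney tests over the requested group pairs (all pairs by
    default), Holm-corrected as one family."""
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    raw: list[float] = []
    partial: list[tuple[str, float, int, int]] = []
    for a, b in pairs:
        u, p = mann_whitney_u(groups[a], groups[b])
        raw.append(p)
        partial.append((f"{a} vs {b}", u, len(groups[a]), len(groups[b])))
    adj = holm_bonferroni(raw)
    return [
        TestResult(label, u, p, float(pa), nx, ny)
        for (label, u, nx, ny), p, pa in zip(partial, raw, adj)
    ]


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Tukey box-plot summary: quartiles by linear interpolation, whiskers at
    the most extreme points within 1.5x IQR of the quartiles, the rest flagged
    as outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_summary of empty data")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )
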