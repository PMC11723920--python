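"""Per-IES retention scores (IRS) from dual-reference alignments.

The retention score of an IES is the fraction of junction-informative reads
supporting the IES-containing (germline) form: reads covering either IES
boundary on the MAC+IES reference count toward retention, reads spanning the
collapsed excision junction on the somatic (MAC) reference count toward
excision. An IRS of 0 means complete excision, 1 complete retention; scores
above 0.1 conventionally define a "retained" IES, with the strict inequality
excluding weak stochastic retention.

A read supports a boundary only when it is aligned with at least ``anchor``
bases on both sides of it; on the somatic side the anchor flanks the retained
junction TA. Reads are counted independently on each reference — a read may
align to both, but is junction-informative on at most one form of any IES.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .annotations import IesAnnotation

__all__ = [
    "JunctionCounts",
    "IrsRecord",
    "IrsTable",
    "RetentionClassification",
    "count_junction_reads",
    "compute_irs",
    "classify_retention",
]


@dataclass
class JunctionCounts:
    ies_id: str
    left_plus: int = 0
    right_plus: int = 0
    mac_minus: int = 0
    anchor: int = 5
    # distinct reads contributing any of the counts above; a read spanning a
    # whole short IES supports both boundaries but is one observation
    informative_reads: int = 0

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError("anchor must be >= 1")
        if min(self.left_plus, self.right_plus, self.mac_minus) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class IrsRecord:
    ies_id: str
    irs: float | None
    left_plus: int
    right_plus: int
    mac_minus: int
    irs_left: float | None = None
    irs_right: float | None = None
    informative_reads: int = 0

    @property
    def coverage_ok(self) -> bool:
        return self.irs is not None


@dataclass
class IrsTable:
    """IRS of every annotated IES for one silencing condition."""

    condition: str
    records: dict[str, IrsRecord] = field(default_factory=dict)

    def defined_scores(self) -> dict[str, float]:
        return {k: r.irs for k, r in self.records.items() if r.irs is not None}

    @classmethod
    def from_scores(cls, condition: str, scores: Mapping[str, float | None]) -> "IrsTable":
        recs = {
            k: IrsRecord(k, None if v is None else float(v), 0, 0, 0)
            for k, v in scores.items()
        }
        return cls(condition=condition, records=recs)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for r in self.records.values():
            rows.append(
                {
                    "ies_id": r.ies_id,
                    "left_plus": r.left_plus,
                    "right_plus": r.right_plus,
                    "mac_minus": r.mac_minus,
                    "irs_left": "" if r.irs_left is None else f"{r.irs_left:.10g}",
                    "irs_right": "" if r.irs_right is None else f"{r.irs_right:.10g}",
                    "irs_global": "" if r.irs is None else f"{r.irs:.10g}",
                    "coverage_ok": int(r.coverage_ok),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str | None = None) -> "IrsTable":
        df = pd.read_csv(path, sep="\t")
        cond = condition or Path(path).stem
        recs: dict[str, IrsRecord] = {}
        if "irs_global" in df.columns:
            for _, row in df.iterrows():
                irs = None if pd.isna(row["irs_global"]) else float(row["irs_global"])
                recs[str(row["ies_id"])] = IrsRecord(
                    str(row["ies_id"]),
                    irs,
                    int(row.get("left_plus", 0)),
                    int(row.get("right_plus", 0)),
                    int(row.get("mac_minus", 0)),
                )
            return cls(condition=cond, records=recs)
        raise ValueError(
            "not a per-record IRS table; for wide condition tables use read_wide_irs_tsv"
        )


def read_wide_irs_tsv(path: str | Path, id_column: str | None = None) -> dict[str, IrsTable]:
    """Read a wide table (one id column, one column per silencing condition)."""
    df = pd.read_csv(path, sep="\t")
    idc = id_column or df.columns[0]
    out: dict[str, IrsTable] = {}
    for col in df.columns:
        if col == idc:
            continue
        scores = {
            str(i): (None if pd.isna(v) else float(v))
            for i, v in zip(df[idc], df[col])
        }
        out[col] = IrsTable.from_scores(col, scores)
    return out


# ---------------------------------------------------------------------------
# counting


def _check_header(sam: pysam.AlignmentFile, scaffolds: set[str], label: str) -> None:
    present = set(sam.references)
    missing = scaffolds - present
    if missing:
        raise ValueError(
            f"annotation scaffolds missing from {label} SAM header: {sorted(missing)[:3]}"
        )


def count_junction_reads(
    mic_sam: str | Path,
    mac_sam: str | Path,
    annotations: Sequence[IesAnnotation],
    anchor: int = 5,
) -> list[JunctionCounts]:
    """Tally boundary-supporting reads on both references.

    On the MAC+IES reference a read increments ``left_plus``/``right_plus``
    when one of its aligned blocks extends >= ``anchor`` bases on both sides of
    the IES start/end. On the somatic reference it increments ``mac_minus``
    when a block covers the junction TA plus >= ``anchor`` bases on each side.
    Secondary/supplementary and unmapped records are skipped.
    """
    if anchor < 1:
        raise ValueError("anchor must be >= 1")
    counts = {a.ies_id: JunctionCounts(a.ies_id, anchor=anchor) for a in annotations}
    scaffolds = {a.scaffold for a in annotations}

    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    for lst in by_scaffold.values():
        lst.sort(key=lambda a: a.start_mic)

    # germline side: boundaries at IES start and end
    with pysam.AlignmentFile(str(mic_sam), "r") as sam:
        _check_header(sam, scaffolds, "MAC+IES")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            anns = by_scaffold.get(rec.reference_name)
            if not anns:
                continue
            starts = [a.start_mic for a in anns]
            ends = [a.end_mic for a in anns]
            touched: set[str] = set()
            for bs, be in rec.get_blocks():
                lo, hi = bs + anchor, be - anchor
                if lo > hi:
                    continue
                for j in range(
                    bisect.bisect_left(starts, lo), bisect.bisect_right(starts, hi)
                ):
                    counts[anns[j].ies_id].left_plus += 1
                    touched.add(anns[j].ies_id)
                for j in range(
                    bisect.bisect_left(ends, lo), bisect.bisect_right(ends, hi)
                ):
                    counts[anns[j].ies_id].right_plus += 1
                    touched.add(anns[j].ies_id)
            for ies_id in touched:
                counts[ies_id].informative_reads += 1

    # somatic side: collapsed junctions (junction TA occupies 2 bp)
    mac_by_scaffold: dict[str, list[IesAnnotation]] = {
        s: sorted(lst, key=lambda a: a.junction_mac) for s, lst in by_scaffold.items()
    }
    with pysam.AlignmentFile(str(mac_sam), "r") as sam:
        _check_header(sam, scaffolds, "MAC")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            anns = mac_by_scaffold.get(rec.reference_name)
            if not anns:
                continue
            junctions = [a.junction_mac for a in anns]
            for bs, be in rec.get_blocks():
                lo, hi = bs + anchor, be - anchor - 2
                if lo > hi:
                    continue
                for j in range(
                    bisect.bisect_left(junctions, lo),
                    bisect.bisect_right(junctions, hi),
                ):
                    counts[anns[j].ies_id].mac_minus += 1
                    counts[anns[j].ies_id].informative_reads += 1

    return [counts[a.ies_id] for a in annotations]


def compute_irs(c: JunctionCounts) -> IrsRecord:
    """Boundary-symmetric global score (L+R)/(L+R+2M), plus per-boundary views.

    The factor 2 balances the two germline boundaries against the single
    somatic junction. Undefined (no informative reads) is a value, not an
    error.
    """
    s = c.left_plus + c.right_plus
    denom = s + 2 * c.mac_minus
    irs = s / denom if (s + c.mac_minus) > 0 else None
    irs_left = (
        c.left_plus / (c.left_plus + c.mac_minus)
        if (c.left_plus + c.mac_minus) > 0
        else None
    )
    irs_right = (
        c.right_plus / (c.right_plus + c.mac_minus)
        if (c.right_plus + c.mac_minus) > 0
        else None
    )
    return IrsRecord(
        ies_id=c.ies_id,
        irs=irs,
        left_plus=c.left_plus,
        right_plus=c.right_plus,
        mac_minus=c.mac_minus,
        irs_left=irs_left,
        irs_right=irs_right,
        informative_reads=c.informative_reads,
    )


def build_irs_table(
    counts: Iterable[JunctionCounts], condition: str = "condition"
) -> IrsTable:
    return IrsTable(
        condition=condition, records={c.ies_id: compute_irs(c) for c in counts}
    )


@dataclass
class RetentionClassification:
    threshold: float
    retained: set[str]
    undefined: set[str]

    @property
    def n_undefined(self) -> int:
        return len(self.undefined)


def classify_retention(table: IrsTable, threshold: float = 0.1) -> RetentionClassification:
    """Retained = IRS strictly greater than the threshold (default 0.1)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    retained = {
        k for k, r in table.records.items() if r.irs is not None and r.irs > threshold
    }
    undefined = {k for k, r in table.records.items() if r.irs is None}
    return RetentionClassification(threshold=threshold, retained=retained, undefined=undefined)
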