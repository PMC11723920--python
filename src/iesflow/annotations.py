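"""IES annotations and coordinate arithmetic between germline and somatic references.

An internal eliminated sequence (IES) is a short, TA-bounded germline segment
that is precisely excised during development of the somatic macronucleus (MAC).
The germline-inclusive reference ("MAC+IES", historically the MIC-informed
assembly) carries every IES; the somatic reference carries a single TA at each
excision junction.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open. An IES occupies
``[start_mic, end_mic)`` on the MAC+IES reference; its sequence begins and ends
with ``TA`` and is at least 26 bp long (the shortest IES known in this system).
Excision removes ``[start_mic, end_mic - 2)`` — equivalently the whole interval
while retaining one TA — so the somatic scaffold is the germline scaffold with
``length - 2`` bases deleted per IES. ``junction_mac`` is the 0-based start of
the retained TA on the somatic reference.

GFF3 output is 1-based inclusive, feature type ``internal_eliminated_sequence``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

MIN_IES_LENGTH = 26
GFF_FEATURE_TYPE = "internal_eliminated_sequence"


@dataclass(frozen=True)
class IesAnnotation:
    """One TA-bounded eliminated interval plus its collapsed somatic junction."""

    ies_id: str
    scaffold: str
    start_mic: int
    end_mic: int
    junction_mac: int
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end_mic - self.start_mic

    def __post_init__(self) -> None:
        if self.end_mic <= self.start_mic:
            raise ValueError(f"{self.ies_id}: empty or inverted interval")
        if self.sequence:
            if len(self.sequence) != self.length:
                raise ValueError(f"{self.ies_id}: sequence length mismatch")
            if not (self.sequence.startswith("TA") and self.sequence.endswith("TA")):
                raise ValueError(f"{self.ies_id}: IES sequence must be TA-bounded")


def sort_and_check(annotations: Iterable[IesAnnotation]) -> list[IesAnnotation]:
    """Sort per scaffold by start and reject overlapping IESs."""
    out = sorted(annotations, key=lambda a: (a.scaffold, a.start_mic))
    prev: IesAnnotation | None = None
    for ann in out:
        if prev is not None and prev.scaffold == ann.scaffold and ann.start_mic < prev.end_mic:
            raise ValueError(f"overlapping IESs: {prev.ies_id} and {ann.ies_id}")
        prev = ann
    return out


def excise(mic_scaffold: str, annotations: Sequence[IesAnnotation]) -> str:
    """Delete every annotated IES from a germline scaffold, keeping one TA each.

    This is the ground-truth somatic sequence for a fully excised genome and the
    round-trip check for the simulator.
    """
    pieces: list[str] = []
    cursor = 0
    for ann in sorted(annotations, key=lambda a: a.start_mic):
        pieces.append(mic_scaffold[cursor : ann.start_mic])
        cursor = ann.end_mic - 2  # retain the trailing TA as the junction TA
    pieces.append(mic_scaffold[cursor:])
    return "".join(pieces)


def mic_to_mac(position: int, annotations: Sequence[IesAnnotation]) -> int:
    """Map a MAC+IES coordinate to the somatic reference.

    Valid for positions outside the removable core ``[start+2, end-2)`` of every
    IES; positions inside either terminal TA map onto the junction TA.
    """
    shift = 0
    for ann in annotations:
        if ann.end_mic - 2 <= position:
            shift += ann.length - 2
        elif ann.start_mic + 2 <= position < ann.end_mic - 2:
            raise ValueError(f"position {position} inside removable core of {ann.ies_id}")
    return position - shift


# ---------------------------------------------------------------------------
# I/O


def write_gff3(annotations: Sequence[IesAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={ann.ies_id};junction_mac={ann.junction_mac}"
            fh.write(
                "\t".join(
                    [
                        ann.scaffold,
                        "iesflow",
                        GFF_FEATURE_TYPE,
                        str(ann.start_mic + 1),
                        str(ann.end_mic),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[IesAnnotation]:
    out: list[IesAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != GFF_FEATURE_TYPE:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                IesAnnotation(
                    ies_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    scaffold=f[0],
                    start_mic=int(f[3]) - 1,
                    end_mic=int(f[4]),
                    junction_mac=int(attrs.get("junction_mac", -1)),
                )
            )
    return sort_and_check(out)


def read_bed(path: str | Path) -> list[IesAnnotation]:
    """BED3+ input: scaffold, start, end[, name]. Junctions unknown (-1)."""
    out: list[IesAnnotation] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            name = f[3] if len(f) > 3 else f"ies_{i}"
            out.append(
                IesAnnotation(
                    ies_id=name,
                    scaffold=f[0],
                    start_mic=int(f[1]),
                    end_mic=int(f[2]),
                    junction_mac=-1,
                )
            )
    return sort_and_check(out)


def read_annotation(path: str | Path) -> list[IesAnnotation]:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed(path)
    return read_gff3(path)


def write_lengths_tsv(annotations: Sequence[IesAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ies_id", "scaffold", "start_mic", "end_mic", "length"])
        for a in annotations:
            w.writerow([a.ies_id, a.scaffold, a.start_mic, a.end_mic, a.length])
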