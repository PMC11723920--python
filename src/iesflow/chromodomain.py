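"""Chromodomain reader-preference classification.

Chromodomains (CDs) bind methylated histone lysines through an aromatic cage
of three F/Y/W residues. Two further determinants discriminate the H3K9me
readers (HP1 family) from the H3K27me readers (Polycomb family): the polarity
of two "clasp" residues outside the cage, and the overall acidity of the
domain. HP1-like CDs carry a polar clasp and an acidic predicted isoelectric
point; Pc-like CDs carry a hydrophobic clasp and a more basic pI. A CD whose
cage is degenerate is called a non-binder regardless of the other features.

Candidate CDs are read off against a bundled reference CD with annotated cage
and clasp alignment columns via global pairwise alignment (BLOSUM62, affine
gaps); the bundled references are synthetic constructs built to the canonical
HP1/Pc CD architecture (see ``data/cd_references_synthetic.fasta``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "CdReference",
    "CdReferenceEntry",
    "CdClassification",
    "load_bundled_reference",
    "locate_cage_and_clasp",
    "compute_pi",
    "classify_cd",
    "classify_sequence",
    "AROMATIC",
    "POLAR",
    "NONPOLAR",
    "EMBOSS_PKA",
]

AROMATIC = set("FYW")
POLAR = set("STNQCYDEKRH")
NONPOLAR = set("GAVLIPMFW")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# EMBOSS default pKa values for the ionisable groups
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_BASIC_GROUPS = ("Nterm", "H", "K", "R")
_ACIDIC_GROUPS = ("Cterm", "C", "D", "E", "Y")


class NotChromodomainLike(ValueError):
    """Alignment score against every reference CD fell below the floor."""


@dataclass(frozen=True)
class CdReferenceEntry:
    name: str
    sequence: str
    cage_columns: tuple[int, int, int]
    clasp_columns: tuple[int, int]

    def __post_init__(self) -> None:
        for c in (*self.cage_columns, *self.clasp_columns):
            if not 0 <= c < len(self.sequence):
                raise ValueError(f"{self.name}: annotated column {c} out of bounds")
        cage = [self.sequence[c] for c in self.cage_columns]
        if any(a not in AROMATIC for a in cage):
            raise ValueError(f"{self.name}: reference cage residues must be aromatic")


@dataclass
class CdReference:
    entries: list[CdReferenceEntry]


def load_bundled_reference() -> CdReference:
    """Load the bundled synthetic HP1-type and Pc-type reference CDs."""
    data = importlib.resources.files("iesflow") / "data"
    fasta = data / "cd_references_synthetic.fasta"
    columns = data / "cd_reference_columns.tsv"
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
    entries: list[CdReferenceEntry] = []
    lines = columns.read_text().strip().splitlines()
    for line in lines[1:]:
        name, c1, c2, c3, p1, p2 = line.split("\t")
        entries.append(
            CdReferenceEntry(
                name=name,
                sequence=seqs[name],
                cage_columns=(int(c1), int(c2), int(c3)),
                clasp_columns=(int(p1), int(p2)),
            )
        )
    return CdReference(entries=entries)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@dataclass
class CageClaspResidues:
    reference: str
    score: float
    cage: tuple[str, str, str]  # '-' marks a gap at that column
    clasp: tuple[str, str]


def locate_cage_and_clasp(
    cd_sequence: str,
    reference: CdReference | None = None,
    min_score: float = 40.0,
) -> CageClaspResidues:
    """Read candidate residues at the annotated cage/clasp columns.

    The candidate is globally aligned to every reference entry and read off
    against the best-scoring one; a best score below ``min_score`` (BLOSUM62
    units) means the sequence is not CD-like and is rejected.
    """
    cd_sequence = cd_sequence.upper().strip("*")
    if not 30 <= len(cd_sequence) <= 80:
        raise ValueError("candidate must be CD-sized (30-80 aa)")
    if reference is None:
        reference = load_bundled_reference()
    aligner = _make_aligner()
    best = None
    for entry in reference.entries:
        aln = aligner.align(entry.sequence, cd_sequence)[0]
        if best is None or aln.score > best[1].score:
            best = (entry, aln)
    entry, aln = best
    if aln.score < min_score:
        raise NotChromodomainLike(
            f"best alignment score {aln.score:.1f} < floor {min_score:.1f}"
        )

    def residue_at(ref_col: int) -> str:
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            if ts <= ref_col < te:
                return cd_sequence[qs + (ref_col - ts)]
        return "-"

    cage = tuple(residue_at(c) for c in entry.cage_columns)
    clasp = tuple(residue_at(c) for c in entry.clasp_columns)
    return CageClaspResidues(
        reference=entry.name, score=float(aln.score), cage=cage, clasp=clasp
    )


def net_charge(sequence: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH."""
    pka = pka or EMBOSS_PKA
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in sequence:
        if aa in pka:
            counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for group in _BASIC_GROUPS:
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _ACIDIC_GROUPS:
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def compute_pi(
    sequence: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """Predicted isoelectric point by bisection on the net-charge curve.

    The pI is the pH at which the Henderson-Hasselbalch sum over the termini
    and the ionisable side chains (D, E, C, Y, H, K, R) crosses zero; bisection
    runs until |charge| < ``tol``. 'X' residues are ignored; other unknown
    letters are rejected.
    """
    sequence = sequence.upper().strip("*")
    if not sequence:
        raise ValueError("empty sequence")
    unknown = set(sequence) - AMINO_ACIDS - {"X"}
    if unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    sequence = sequence.replace("X", "")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(sequence, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class CdClassification:
    cd_id: str
    cage: tuple[str, str, str]
    cage_intact: bool
    clasp: tuple[str, str]
    clasp_polarity: str  # polar | nonpolar | mixed
    pi: float
    call: str  # H3K9me-type | H3K27me-type | non-binder | indeterminate


def _clasp_polarity(clasp: Sequence[str]) -> str:
    if all(a in POLAR for a in clasp):
        return "polar"
    if all(a in NONPOLAR for a in clasp):
        return "nonpolar"
    return "mixed"


def classify_cd(
    cage: Sequence[str],
    clasp: Sequence[str],
    pi: float,
    ph_boundary: float = 7.0,
    dead_zone: float = 0.0,
) -> str:
    """Reader-class call from cage integrity, clasp polarity and pI.

    Degenerate cage -> non-binder. Intact cage with a polar clasp and an
    acidic domain -> H3K9me-type (HP1-like); with a hydrophobic clasp and a
    basic domain -> H3K27me-type (Pc-like); anything else -> indeterminate.
    ``dead_zone`` optionally widens the acid/base boundary into an
    indeterminate band (off by default).
    """
    cage_intact = all(a in AROMATIC for a in cage)
    if not cage_intact:
        return "non-binder"
    polarity = _clasp_polarity(clasp)
    if abs(pi - ph_boundary) <= dead_zone:
        return "indeterminate"
    if polarity == "polar" and pi < ph_boundary:
        return "H3K9me-type"
    if polarity == "nonpolar" and pi > ph_boundary:
        return "H3K27me-type"
    return "indeterminate"


def classify_sequence(
    cd_id: str,
    cd_sequence: str,
    reference: CdReference | None = None,
    min_score: float = 40.0,
    pka: dict[str, float] | None = None,
    dead_zone: float = 0.0,
) -> CdClassification:
    """Full pipeline for one candidate CD: align, read residues, compute pI,
    classify."""
    residues = locate_cage_and_clasp(cd_sequence, reference, min_score=min_score)
    pi = compute_pi(cd_sequence, pka=pka)
    call = classify_cd(residues.cage, residues.clasp, pi, dead_zone=dead_zone)
    return CdClassification(
        cd_id=cd_id,
        cage=residues.cage,
        cage_intact=all(a in AROMATIC for a in residues.cage),
        clasp=residues.clasp,
        clasp_polarity=_clasp_polarity(residues.clasp),
        pi=pi,
        call=call,
    )


def classify_fasta(
    path: str | Path,
    reference: CdReference | None = None,
    min_score: float = 40.0,
) -> list[CdClassification]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(classify_sequence(rec.id, str(rec.seq), reference, min_score))
    return out
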