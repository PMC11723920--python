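"""Synthetic toy genomes and read simulators with known ground truth.

This module builds a miniature dual-reference system mirroring the one used for
*Paramecium* DNA-elimination analyses: a somatic ("MAC") genome and a
germline-inclusive ("MAC+IES") genome that differs only by short TA-bounded
IES insertions. On top of it, three simulators emit sequencing-like data with
per-read truth labels:

* genomic DNA fragments drawn from the IES-retained haplotype of IES *i* with a
  configurable probability ``r_i`` (retention fraction),
* MNase-protected fragments whose midpoint density over interval *i* is
  proportional to a planted weight ``w_i``,
* small-RNA reads drawn from length/class mixtures (23 nt siRNA, 25 nt scnRNA,
  26–31 nt iesRNA, the latter exclusively from IES sequences).

Because read placement is known exactly, truth alignments are emitted directly
as SAM; no aligner is involved at toy scale. Real datasets enter the downstream
modules as user-supplied SAM instead. All simulators are byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pysam

from .annotations import MIN_IES_LENGTH, IesAnnotation, excise, write_gff3

__all__ = [
    "ToyGenomeSpec",
    "TruthTable",
    "ToyGenome",
    "build_toy_genome",
    "simulate_genomic_reads",
    "simulate_mnase_fragments",
    "simulate_srna_reads",
    "default_ies_length_sampler",
    "default_mnase_length_sampler",
    "random_dna",
]

SRNA_CLASSES = ("siRNA", "scnRNA", "iesRNA")
SRNA_LENGTHS = {"siRNA": (23, 23), "scnRNA": (25, 25), "iesRNA": (26, 31)}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class CapacityError(ValueError):
    """Requested IESs do not fit on the requested scaffolds."""


def default_ies_length_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Shifted-exponential IES lengths: 26 bp minimum, ~94% below 150 bp.

    The real length distribution is only loosely constrained (minimum 26 bp,
    large majority under one nucleosome footprint); an exponential tail with
    scale 45 bp reproduces those two facts and is not asserted as biology.
    """
    return (MIN_IES_LENGTH + rng.exponential(scale=45.0, size=size)).astype(int)


def default_mnase_length_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Fragment lengths ~N(150, 20) bp, clipped at 50: spans the 125-175 bp
    mononucleosome window and deliberately produces out-of-window lengths so
    size filtering has something to remove."""
    return np.clip(rng.normal(150.0, 20.0, size=size).round().astype(int), 50, None)


@dataclass
class ToyGenomeSpec:
    n_scaffolds: int = 5
    scaffold_length: int = 30_000
    n_ies: int = 200
    ies_length_sampler: Callable[[np.random.Generator, int], np.ndarray] = (
        default_ies_length_sampler
    )
    gc_content: float = 0.3
    seed: int = 0
    # junction sites keep this many background bases from scaffold ends and
    # from each other, so no sequencing fragment spans two IESs
    min_spacing: int = 500
    max_ies_length: int = 2_000

    def __post_init__(self) -> None:
        if self.n_ies < 0:
            raise ValueError("n_ies must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class TruthTable:
    """Simulation ground truth: per-IES retention, per-interval nucleosome
    weight, and per-read origin labels."""

    retention: dict[str, float] = field(default_factory=dict)
    nucleosome_weights: dict[str, float] = field(default_factory=dict)
    read_origins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention fraction for {k} outside [0,1]")
        for k, w in self.nucleosome_weights.items():
            if w <= 0:
                raise ValueError(f"nucleosome weight for {k} must be > 0")

    def write_retention_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ies_id\tretention\n")
            for k, r in self.retention.items():
                fh.write(f"{k}\t{r}\n")


@dataclass
class ToyGenome:
    mac: dict[str, str]
    mic: dict[str, str]
    annotations: list[IesAnnotation]

    def annotations_for(self, scaffold: str) -> list[IesAnnotation]:
        return [a for a in self.annotations if a.scaffold == scaffold]

    def write(self, outdir: str | Path, prefix: str = "toy") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mac": outdir / f"{prefix}_mac.fasta",
            "mic": outdir / f"{prefix}_mac_with_ies.fasta",
            "gff3": outdir / f"{prefix}_ies.gff3",
        }
        write_fasta(self.mac, paths["mac"])
        write_fasta(self.mic, paths["mic"])
        write_gff3(self.annotations, paths["gff3"])
        return paths


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def build_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """Build paired somatic / germline-inclusive references plus annotations.

    The somatic scaffold is i.i.d. background sequence carrying a forced ``TA``
    at each junction site; the germline scaffold is produced by splicing in the
    IES so that its trailing TA coincides with the somatic junction TA. Excising
    every annotated IES (keeping one TA) therefore reproduces the somatic
    scaffold byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    # round-robin distribution of IESs over scaffolds
    per_scaffold = [spec.n_ies // spec.n_scaffolds] * spec.n_scaffolds
    for i in range(spec.n_ies % spec.n_scaffolds):
        per_scaffold[i] += 1

    mac: dict[str, str] = {}
    mic: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    for s in range(spec.n_scaffolds):
        name = f"scaffold_{s + 1}"
        k = per_scaffold[s]
        seq = random_dna(rng, spec.scaffold_length, spec.gc_content)
        slack = spec.scaffold_length - 2 * spec.min_spacing - (k - 1) * spec.min_spacing
        if k > 0 and slack < 0:
            raise CapacityError(
                f"{k} IESs with spacing {spec.min_spacing} do not fit on a "
                f"{spec.scaffold_length} bp scaffold"
            )
        sites: list[int] = []
        if k > 0:
            offsets = np.sort(rng.integers(0, slack + 1, size=k))
            sites = [
                int(spec.min_spacing + offsets[i] + i * spec.min_spacing)
                for i in range(k)
            ]
        chars = list(seq)
        for j in sites:
            chars[j], chars[j + 1] = "T", "A"
        mac_seq = "".join(chars)
        mac[name] = mac_seq

        lengths = np.clip(
            spec.ies_length_sampler(rng, k), MIN_IES_LENGTH, spec.max_ies_length
        )
        pieces: list[str] = []
        cursor = 0
        offset = 0
        for idx, (j, length) in enumerate(zip(sites, lengths)):
            ies_seq = "TA" + random_dna(rng, int(length) - 4, spec.gc_content) + "TA"
            pieces.append(mac_seq[cursor:j])
            pieces.append(ies_seq[:-2])  # trailing TA coincides with the MAC TA
            cursor = j
            annotations.append(
                IesAnnotation(
                    ies_id=f"{name}_ies_{idx + 1}",
                    scaffold=name,
                    start_mic=j + offset,
                    end_mic=j + offset + int(length),
                    junction_mac=j,
                    sequence=ies_seq,
                )
            )
            offset += int(length) - 2
        pieces.append(mac_seq[cursor:])
        mic[name] = "".join(pieces)

    genome = ToyGenome(mac=mac, mic=mic, annotations=annotations)
    # paranoia: the excision round trip must hold by construction
    for name in mac:
        assert excise(genome.mic[name], genome.annotations_for(name)) == mac[name]
    return genome


# ---------------------------------------------------------------------------
# genomic DNA simulator


@dataclass
class AlignedRead:
    name: str
    scaffold: str
    pos: int
    seq: str
    reverse: bool = False


@dataclass
class SimulatedReadSet:
    reads: list[tuple[str, str]]  # (name, sequenced-strand sequence)
    mic_alignments: list[AlignedRead]
    mac_alignments: list[AlignedRead]
    fragment_truth: list[tuple[str, str, bool]]  # (fragment, ies_id, retained)
    mic_lengths: dict[str, int]
    mac_lengths: dict[str, int]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    def _write_sam(
        self, path: str | Path, alignments: list[AlignedRead], lengths: dict[str, int]
    ) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in lengths.items()],
        }
        names = list(lengths)
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for aln in alignments:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = aln.name
                rec.query_sequence = aln.seq
                rec.flag = 16 if aln.reverse else 0
                rec.reference_id = names.index(aln.scaffold)
                rec.reference_start = aln.pos
                rec.mapping_quality = 60
                rec.cigarstring = f"{len(aln.seq)}M"
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
                out.write(rec)

    def write_mic_sam(self, path: str | Path) -> None:
        self._write_sam(path, self.mic_alignments, self.mic_lengths)

    def write_mac_sam(self, path: str | Path) -> None:
        self._write_sam(path, self.mac_alignments, self.mac_lengths)


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a == merged[-1][1]:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def simulate_genomic_reads(
    genome: ToyGenome,
    truth: TruthTable,
    depth: float = 100.0,
    read_length: int = 100,
    insert_size: int = 300,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate genomic fragments from a partially excised genome.

    Each fragment carries the IES-retained form of IES *i* with probability
    ``truth.retention[ies_id]`` (independently per fragment and per spanned
    IES). Both fragment ends are read; every read is written as a truth
    alignment to each reference it is colinear with: the germline-inclusive
    reference when it crosses no excision junction, the somatic reference when
    it covers no retained-IES core bases. Reads touching neither IES form are
    emitted to both.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    if truth.retention and not genome.annotations:
        raise ValueError("retention truth supplied but annotation is empty")
    missing = [a.ies_id for a in genome.annotations if a.ies_id not in truth.retention]
    if missing:
        raise ValueError(f"retention truth missing for {missing[:3]}...")

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    mic_alns: list[AlignedRead] = []
    mac_alns: list[AlignedRead] = []
    frag_truth: list[tuple[str, str, bool]] = []
    reads_per_frag = 2 if insert_size > read_length else 1

    for scaffold, mic_seq in genome.mic.items():
        anns = genome.annotations_for(scaffold)
        starts = [a.start_mic for a in anns]
        ends = [a.end_mic for a in anns]
        ends_m2 = [e - 2 for e in ends]
        r_frac = [truth.retention[a.ies_id] for a in anns]
        # cumulative somatic-coordinate shift: IES j contributes once a
        # position has passed its removable core
        shift = np.concatenate([[0], np.cumsum([a.length - 2 for a in anns])])
        mic_len = len(mic_seq)
        k = len(anns)
        n_frags = int(np.ceil(depth * mic_len / (reads_per_frag * read_length)))

        for fi in range(n_frags):
            for _attempt in range(50):
                f = int(rng.integers(0, mic_len - insert_size + 1))
                segs: list[tuple[int, int]] = []
                # i -> (retained, unconditioned). A draw made when the walk
                # reaches the IES from outside is a plain Bernoulli(r_i); a
                # fragment *starting* inside an IES exists only on retained
                # molecules, so its (re)draw is conditioned and excluded from
                # the binomial truth labels.
                statuses: dict[int, tuple[bool, bool]] = {}
                p, need = f, insert_size
                i = bisect.bisect_right(ends_m2, f)
                bad_start = False
                while need > 0 and p < mic_len:
                    if i < k and p >= starts[i]:
                        if i not in statuses:
                            statuses[i] = (
                                bool(rng.random() < r_frac[i]),
                                p <= starts[i],
                            )
                        if not statuses[i][0]:
                            if p > starts[i]:
                                bad_start = True  # started inside an excised core
                                break
                            p = ends_m2[i]
                            i += 1
                            continue
                        q = min(ends[i], p + need)
                        segs.append((p, q))
                        need -= q - p
                        p = q
                        if p >= ends[i]:
                            i += 1
                        continue
                    nxt = starts[i] if i < k else mic_len
                    q = min(nxt, p + need)
                    segs.append((p, q))
                    need -= q - p
                    p = q
                if not bad_start:
                    break
            else:  # pragma: no cover - pathological retention=0 everywhere
                continue
            segs = _merge_segments(segs)
            realized = "".join(mic_seq[a:b] for a, b in segs)
            if len(realized) < read_length:
                continue
            frag_id = f"{scaffold}_frag_{fi}"
            for idx, (ret, unconditioned) in statuses.items():
                if unconditioned:
                    frag_truth.append((frag_id, anns[idx].ies_id, ret))

            mate_windows = [(0, read_length)]
            if reads_per_frag == 2:
                mate_windows.append((len(realized) - read_length, len(realized)))
            for mate, (a_off, b_off) in enumerate(mate_windows, start=1):
                rname = f"{frag_id}/{mate}"
                fwd_seq = realized[a_off:b_off]
                reverse = mate == 2
                reads.append((rname, revcomp(fwd_seq) if reverse else fwd_seq))
                # locate the read's kept segments in germline coordinates
                covered: list[tuple[int, int]] = []
                off = 0
                for a, b in segs:
                    lo, hi = max(a_off, off), min(b_off, off + (b - a))
                    if lo < hi:
                        covered.append((a + (lo - off), a + (hi - off)))
                    off += b - a
                if len(covered) == 1:  # colinear on the germline reference
                    mic_alns.append(
                        AlignedRead(rname, scaffold, covered[0][0], fwd_seq, reverse)
                    )
                # colinear on the somatic reference iff no retained core base
                touches_core = any(
                    statuses.get(j, (False, False))[0]
                    and max(lo, starts[j] + 2) < min(hi, ends_m2[j])
                    for lo, hi in covered
                    for j in range(
                        bisect.bisect_right(ends_m2, lo), bisect.bisect_left(starts, hi)
                    )
                )
                if not touches_core:
                    p0 = covered[0][0]
                    idx0 = bisect.bisect_right(ends_m2, p0)
                    mac_alns.append(
                        AlignedRead(
                            rname, scaffold, p0 - int(shift[idx0]), fwd_seq, reverse
                        )
                    )

    return SimulatedReadSet(
        reads=reads,
        mic_alignments=mic_alns,
        mac_alignments=mac_alns,
        fragment_truth=frag_truth,
        mic_lengths={n: len(s) for n, s in genome.mic.items()},
        mac_lengths={n: len(s) for n, s in genome.mac.items()},
    )


# ---------------------------------------------------------------------------
# MNase fragment simulator


@dataclass
class SimulatedFragmentSet:
    fragments: list[tuple[str, int, int]]  # (scaffold, start, end)
    lengths: dict[str, int]
    interval_of_fragment: list[str]  # planted source interval id per fragment

    def write_sam(self, path: str | Path) -> None:
        """Write each fragment as a properly paired read pair (mates at the
        fragment ends, TLEN = fragment length)."""
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in self.lengths.items()],
        }
        names = list(self.lengths)
        read_len = 50
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, (scaffold, start, end) in enumerate(self.fragments):
                flen = end - start
                rlen = min(read_len, flen)
                rid = names.index(scaffold)
                r1 = pysam.AlignedSegment(out.header)
                r1.query_name = f"frag_{i}"
                r1.query_sequence = "N" * rlen
                r1.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, first
                r1.reference_id = rid
                r1.reference_start = start
                r1.mapping_quality = 60
                r1.cigarstring = f"{rlen}M"
                r1.next_reference_id = rid
                r1.next_reference_start = end - rlen
                r1.template_length = flen
                r2 = pysam.AlignedSegment(out.header)
                r2.query_name = f"frag_{i}"
                r2.query_sequence = "N" * rlen
                r2.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, rev, second
                r2.reference_id = rid
                r2.reference_start = end - rlen
                r2.mapping_quality = 60
                r2.cigarstring = f"{rlen}M"
                r2.next_reference_id = rid
                r2.next_reference_start = start
                r2.template_length = -flen
                out.write(r1)
                out.write(r2)


def simulate_mnase_fragments(
    reference_lengths: Mapping[str, int],
    intervals: Sequence[IesAnnotation],
    weights: Mapping[str, float],
    n_fragments: int,
    frag_length_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> SimulatedFragmentSet:
    """Place fragments so that expected midpoint density over interval *i* is
    proportional to its planted weight ``w_i`` (per bp)."""
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    if frag_length_sampler is None:
        frag_length_sampler = default_mnase_length_sampler
    w = np.array([weights[iv.ies_id] for iv in intervals], dtype=float)
    if np.any(w <= 0):
        raise ValueError("interval weights must be strictly positive")
    lens = np.array([iv.length for iv in intervals], dtype=float)
    p = w * lens
    p /= p.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(intervals), size=n_fragments, p=p)
    frag_lens = frag_length_sampler(rng, n_fragments)
    fragments: list[tuple[str, int, int]] = []
    origin: list[str] = []
    for idx, flen in zip(which, frag_lens):
        iv = intervals[int(idx)]
        mid = int(rng.integers(iv.start_mic, iv.end_mic))
        start = mid - int(flen) // 2
        end = start + int(flen)
        ref_len = reference_lengths[iv.scaffold]
        start = max(0, start)
        end = min(ref_len, end)
        fragments.append((iv.scaffold, start, end))
        origin.append(iv.ies_id)
    return SimulatedFragmentSet(
        fragments=fragments,
        lengths=dict(reference_lengths),
        interval_of_fragment=origin,
    )


# ---------------------------------------------------------------------------
# small-RNA simulator


@dataclass
class SimulatedSrnaSet:
    reads: list[tuple[str, str]]
    truth: list[tuple[str, str, str]]  # (read_id, class, source record)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reads:
                fh.write(f">{name}\n{seq}\n")


def simulate_srna_reads(
    class_mix: Mapping[str, float],
    sources: Mapping[str, Sequence[tuple[str, str]]],
    n_reads: int,
    seed: int = 0,
    both_strands: bool = True,
) -> SimulatedSrnaSet:
    """Draw small-RNA reads from per-class source sequences.

    ``class_mix`` gives proportions over ``siRNA`` (23 nt), ``scnRNA`` (25 nt)
    and ``iesRNA`` (26-31 nt, sourced exclusively from IES sequences — the
    caller supplies IES records as the iesRNA source). Reads are exact
    substrings of their source (reverse-complemented half the time when
    ``both_strands``); truth labels record class and source record.
    """
    mix = {c: class_mix.get(c, 0.0) for c in SRNA_CLASSES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    for cls, frac in mix.items():
        if frac > 0:
            if cls not in sources or not sources[cls]:
                raise ValueError(f"no source references for class {cls}")
            if any(len(seq) == 0 for _, seq in sources[cls]):
                raise ValueError(f"zero-length source reference under class {cls}")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, [mix[c] for c in SRNA_CLASSES])
    reads: list[tuple[str, str]] = []
    truth: list[tuple[str, str, str]] = []
    ridx = 0
    for cls, n_cls in zip(SRNA_CLASSES, counts):
        if n_cls == 0:
            continue
        recs = list(sources[cls])
        lo, hi = SRNA_LENGTHS[cls]
        rec_w = np.array([len(s) for _, s in recs], dtype=float)
        rec_w /= rec_w.sum()
        for _ in range(int(n_cls)):
            length = int(rng.integers(lo, hi + 1))
            for _attempt in range(100):
                j = int(rng.choice(len(recs), p=rec_w))
                name, seq = recs[j]
                if len(seq) >= length:
                    break
            else:
                raise ValueError(f"all {cls} sources shorter than {length} nt")
            pos = int(rng.integers(0, len(seq) - length + 1))
            sub = seq[pos : pos + length]
            if both_strands and rng.random() < 0.5:
                sub = revcomp(sub)
            rid = f"srna_{ridx}"
            ridx += 1
            reads.append((rid, sub))
            truth.append((rid, cls, name))
    return SimulatedSrnaSet(reads=reads, truth=truth)
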