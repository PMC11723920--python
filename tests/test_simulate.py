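"""Simulator ground-truth guarantees: excision round trips, TA boundaries,
determinism, and binomial behaviour of the planted signals."""

import io

import numpy as np
import pytest

from iesflow.annotations import excise
from iesflow.simulate import (
    CapacityError,
    SRNA_LENGTHS,
    ToyGenomeSpec,
    TruthTable,
    build_toy_genome,
    default_ies_length_sampler,
    simulate_genomic_reads,
    simulate_mnase_fragments,
    simulate_srna_reads,
    write_fasta,
)


def _fasta_bytes(records):
    buf = io.StringIO()
    for name, seq in records.items():
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()


class TestToyGenome:
    def test_no_ies_means_identical_references(self):
        g = build_toy_genome(ToyGenomeSpec(n_scaffolds=2, scaffold_length=5000, n_ies=0, seed=1))
        assert g.mac == g.mic

    def test_deterministic_under_seed(self):
        spec = ToyGenomeSpec(n_scaffolds=2, scaffold_length=8000, n_ies=8, seed=42)
        g1, g2 = build_toy_genome(spec), build_toy_genome(spec)
        assert _fasta_bytes(g1.mic) == _fasta_bytes(g2.mic)
        assert _fasta_bytes(g1.mac) == _fasta_bytes(g2.mac)
        assert [(a.ies_id, a.start_mic, a.sequence) for a in g1.annotations] == [
            (a.ies_id, a.start_mic, a.sequence) for a in g2.annotations
        ]

    def test_excision_round_trip(self):
        g = build_toy_genome(ToyGenomeSpec(n_scaffolds=1, scaffold_length=12_000, n_ies=10, seed=3))
        assert len(g.annotations) == 10
        for name in g.mic:
            assert excise(g.mic[name], g.annotations_for(name)) == g.mac[name]

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_ies_invariants(self, seed):
        g = build_toy_genome(ToyGenomeSpec(n_scaffolds=2, scaffold_length=15_000, n_ies=16, seed=seed))
        prev_end = {}
        for a in g.annotations:
            seq = g.mic[a.scaffold][a.start_mic : a.end_mic]
            assert seq == a.sequence
            assert seq.startswith("TA") and seq.endswith("TA")
            assert a.length >= 26
            assert g.mac[a.scaffold][a.junction_mac : a.junction_mac + 2] == "TA"
            assert a.start_mic >= prev_end.get(a.scaffold, 0)
            prev_end[a.scaffold] = a.end_mic

    def test_capacity_error_when_ies_do_not_fit(self):
        with pytest.raises(CapacityError):
            build_toy_genome(ToyGenomeSpec(n_scaffolds=1, scaffold_length=2000, n_ies=50, seed=0))

    def test_default_length_sampler_range(self, rng):
        lens = default_ies_length_sampler(rng, 5000)
        assert lens.min() >= 26
        assert 0.85 < (lens < 150).mean() < 0.99


class TestGenomicReads:
    def _genome(self):
        return build_toy_genome(
            ToyGenomeSpec(n_scaffolds=1, scaffold_length=15_000, n_ies=12, seed=5)
        )

    def test_full_retention_leaves_no_excised_junction_reads(self):
        g = self._genome()
        truth = TruthTable(retention={a.ies_id: 1.0 for a in g.annotations})
        rs = simulate_genomic_reads(g, truth, depth=20, seed=1)
        junctions = {(a.scaffold, a.junction_mac) for a in g.annotations}
        for aln in rs.mac_alignments:
            for scaffold, jm in junctions:
                if aln.scaffold == scaffold:
                    # no somatic read spans a junction TA with a base each side
                    assert not (aln.pos < jm and aln.pos + len(aln.seq) > jm + 2)

    def test_full_excision_leaves_no_boundary_reads(self):
        g = self._genome()
        truth = TruthTable(retention={a.ies_id: 0.0 for a in g.annotations})
        rs = simulate_genomic_reads(g, truth, depth=20, seed=1)
        for aln in rs.mic_alignments:
            for a in g.annotations:
                lo, hi = aln.pos, aln.pos + len(aln.seq)
                # no germline-reference read touches an excisable IES core
                assert not (lo < a.end_mic - 2 and hi > a.start_mic + 2)
        assert all(not retained for _, _, retained in rs.fragment_truth)

    def test_half_retention_is_binomial_on_fragment_truth(self):
        g = self._genome()
        truth = TruthTable(retention={a.ies_id: 0.5 for a in g.annotations})
        rs = simulate_genomic_reads(g, truth, depth=100, read_length=100, seed=2)
        flags = np.array([retained for _, _, retained in rs.fragment_truth])
        se = np.sqrt(0.25 / flags.size)
        assert abs(flags.mean() - 0.5) < 3 * se

    def test_truth_annotation_mismatch_rejected(self):
        g = build_toy_genome(ToyGenomeSpec(n_scaffolds=1, scaffold_length=5000, n_ies=0, seed=1))
        truth = TruthTable(retention={"ghost_ies": 0.5})
        with pytest.raises(ValueError, match="annotation is empty"):
            simulate_genomic_reads(g, truth, depth=5, seed=0)

    def test_reads_match_emitting_reference(self):
        g = self._genome()
        rng = np.random.default_rng(9)
        truth = TruthTable(retention={a.ies_id: float(rng.uniform()) for a in g.annotations})
        rs = simulate_genomic_reads(g, truth, depth=5, seed=4)
        from iesflow.simulate import revcomp

        for alns, refs in ((rs.mic_alignments, g.mic), (rs.mac_alignments, g.mac)):
            for aln in alns[:500]:
                assert refs[aln.scaffold][aln.pos : aln.pos + len(aln.seq)] == aln.seq


class TestMnaseFragments:
    def _intervals(self):
        g = build_toy_genome(
            ToyGenomeSpec(
                n_scaffolds=1,
                scaffold_length=10_000,
                n_ies=2,
                seed=6,
                ies_length_sampler=lambda rng, n: np.full(n, 200),
            )
        )
        lengths = {n: len(s) for n, s in g.mic.items()}
        return g.annotations, lengths

    def test_equal_weights_give_equal_counts(self):
        anns, lengths = self._intervals()
        sim = simulate_mnase_fragments(lengths, anns, {a.ies_id: 1.0 for a in anns}, 20_000, seed=1)
        counts = {a.ies_id: 0 for a in anns}
        for origin in sim.interval_of_fragment:
            counts[origin] += 1
        a, b = counts.values()
        se = np.sqrt(20_000 * 0.25)
        assert abs(a - b) < 4 * se

    def test_two_to_one_weights(self):
        anns, lengths = self._intervals()
        w = {anns[0].ies_id: 2.0, anns[1].ies_id: 1.0}
        sim = simulate_mnase_fragments(lengths, anns, w, 30_000, seed=2)
        counts = {a.ies_id: 0 for a in anns}
        for origin in sim.interval_of_fragment:
            counts[origin] += 1
        ratio = counts[anns[0].ies_id] / counts[anns[1].ies_id]
        assert abs(ratio - 2.0) < 0.15

    def test_zero_weight_rejected(self):
        anns, lengths = self._intervals()
        with pytest.raises(ValueError, match="strictly positive"):
            simulate_mnase_fragments(lengths, anns, {anns[0].ies_id: 0.0, anns[1].ies_id: 1.0}, 100)

    def test_nonpositive_fragment_count_rejected(self):
        anns, lengths = self._intervals()
        with pytest.raises(ValueError, match="n_fragments"):
            simulate_mnase_fragments(lengths, anns, {a.ies_id: 1.0 for a in anns}, 0)


class TestSrnaReads:
    def _sources(self, small_genome):
        ies = [(a.ies_id, a.sequence) for a in small_genome.annotations]
        mds = list(small_genome.mac.items())
        return {"siRNA": mds, "scnRNA": mds, "iesRNA": ies}

    def test_pure_sirna_mix_has_length_23(self, small_genome):
        sim = simulate_srna_reads({"siRNA": 1.0}, self._sources(small_genome), 500, seed=1)
        assert all(len(seq) == 23 for _, seq in sim.reads)

    def test_iesrna_reads_are_ies_substrings(self, small_genome):
        from iesflow.simulate import revcomp

        sim = simulate_srna_reads({"iesRNA": 1.0}, self._sources(small_genome), 500, seed=2)
        ies_seqs = {a.ies_id: a.sequence for a in small_genome.annotations}
        for (rid, seq), (_, cls, src) in zip(sim.reads, sim.truth):
            assert cls == "iesRNA"
            assert seq in ies_seqs[src] or revcomp(seq) in ies_seqs[src]
            assert 26 <= len(seq) <= 31

    def test_mixture_proportions_multinomial(self, small_genome):
        mix = {"siRNA": 0.2, "scnRNA": 0.5, "iesRNA": 0.3}
        sim = simulate_srna_reads(mix, self._sources(small_genome), 10_000, seed=3)
        counts = {c: 0 for c in mix}
        for _, cls, _ in sim.truth:
            counts[cls] += 1
        for cls, p in mix.items():
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(counts[cls] / 10_000 - p) < 3 * se

    def test_zero_length_source_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            simulate_srna_reads({"siRNA": 1.0}, {"siRNA": [("empty", "")]}, 10)

    def test_bad_mix_rejected(self, small_genome):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_srna_reads({"siRNA": 0.7}, self._sources(small_genome), 10)

    def test_deterministic(self, small_genome):
        s1 = simulate_srna_reads({"iesRNA": 1.0}, self._sources(small_genome), 200, seed=9)
        s2 = simulate_srna_reads({"iesRNA": 1.0}, self._sources(small_genome), 200, seed=9)
        assert s1.reads == s2.reads
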