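import numpy as np
import pysam
import pytest

from iesflow.simulate import ToyGenomeSpec, build_toy_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 2-scaffold toy genome with 30 IESs, shared across read-only tests."""
    return build_toy_genome(
        ToyGenomeSpec(n_scaffolds=2, scaffold_length=20_000, n_ies=30, seed=11)
    )


def write_sam(path, reads, lengths):
    """Write simple fully-matched single-end records.

    ``reads`` is a list of (name, scaffold, start, length) placements.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in lengths.items()],
    }
    names = list(lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, scaffold, start, length in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = name
            rec.query_sequence = "A" * length
            rec.flag = 0
            rec.reference_id = names.index(scaffold)
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigarstring = f"{length}M"
            out.write(rec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
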