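"""Per-IES nucleosome density from simulated MNase and input libraries with a
planted 2:1 occupancy difference between two IES groups, tested with
Mann-Whitney U under Holm correction.
"""

import tempfile
from pathlib import Path

import numpy as np

from iesflow import (
    ToyGenomeSpec,
    box_summary,
    build_toy_genome,
    compare_groups,
    compute_density,
    count_over_intervals,
    filter_fragments,
    read_fragments_sam,
    simulate_mnase_fragments,
)

genome = build_toy_genome(
    ToyGenomeSpec(
        n_scaffolds=2,
        scaffold_length=40_000,
        n_ies=60,
        ies_length_sampler=lambda rng, n: rng.integers(180, 221, size=n),
        seed=21,
    )
)
anns = genome.annotations
occupied = {a.ies_id for a in anns[:30]}
weights = {a.ies_id: (2.0 if a.ies_id in occupied else 1.0) for a in anns}
flat = {a.ies_id: 1.0 for a in anns}
ref_lengths = {n: len(s) for n, s in genome.mic.items()}

mnase = simulate_mnase_fragments(ref_lengths, anns, weights, 40_000, seed=22)
inp = simulate_mnase_fragments(ref_lengths, anns, flat, 40_000, seed=23)
with tempfile.TemporaryDirectory() as tmp:
    m_sam, g_sam = Path(tmp) / "mnase.sam", Path(tmp) / "input.sam"
    mnase.write_sam(m_sam)
    inp.write_sam(g_sam)
    m_frags = filter_fragments(read_fragments_sam(m_sam))  # 125-175 bp only
    g_frags = read_fragments_sam(g_sam)

print(
    f"mononucleosome filter kept {len(m_frags)} of {len(mnase.fragments)} "
    "MNase fragments (125-175 bp inclusive)"
)
records = compute_density(
    count_over_intervals(m_frags, anns),
    count_over_intervals(g_frags, anns),
    len(m_frags),
    len(g_frags),
)
dens = {r.ies_id: r.density for r in records if r.defined}
hi = [dens[i] for i in occupied if i in dens]
lo = [v for i, v in dens.items() if i not in occupied]
print(
    f"median density: occupied group {np.median(hi):.2f}, "
    f"depleted group {np.median(lo):.2f} (planted ratio 2)"
)
for group, values in (("occupied", hi), ("depleted", lo)):
    s = box_summary(values)
    print(
        f"  {group}: median {s.median:.2f}, IQR [{s.q1:.2f}, {s.q3:.2f}], "
        f"{s.outliers.size} outliers beyond 1.5xIQR whiskers"
    )
(test,) = compare_groups({"occupied": hi, "depleted": lo})
print(
    f"Mann-Whitney U = {test.u_statistic:.0f}, Holm-adjusted p = "
    f"{test.p_adj:.2e} -> the planted occupancy shift is detected."
)
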