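"""Classify chromodomains into putative H3K9me / H3K27me readers.

The call combines three determinants: an intact aromatic cage (three F/Y/W
residues), the polarity of the two clasp residues, and the predicted
isoelectric point of the domain. HP1-like H3K9me readers carry a polar clasp
and an acidic pI; Pc-like H3K27me readers a hydrophobic clasp and a basic pI.
"""

from iesflow import classify_sequence, load_bundled_reference

reference = load_bundled_reference()
candidates = [(e.name, e.sequence) for e in reference.entries]

# a cage-broken variant: first cage aromatic replaced by leucine
broken = reference.entries[0].sequence
col = reference.entries[0].cage_columns[0]
candidates.append(("cage_mutant", broken[:col] + "L" + broken[col + 1 :]))

print(f"{'candidate':<32}{'cage':<7}{'clasp':<7}{'polarity':<10}{'pI':>6}  call")
for name, seq in candidates:
    c = classify_sequence(name, seq, reference)
    print(
        f"{name:<32}{''.join(c.cage):<7}{''.join(c.clasp):<7}"
        f"{c.clasp_polarity:<10}{c.pi:>6.2f}  {c.call}"
    )
print(
    "\nA degenerate cage overrides everything else: the mutant is called a "
    "non-binder even though its clasp and pI still look Pc- or HP1-like."
)
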