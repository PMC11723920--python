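# Methods

This note records the models, conventions and numerical choices behind
`iesflow`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinates and the IES representation

All interval arithmetic is 0-based half-open internally; GFF3 output is
1-based inclusive with feature type `internal_eliminated_sequence`. An IES is
stored with both terminal TAs included (`sequence` starts and ends with `TA`,
length ≥ 26 bp). Excision removes the interval while retaining a single TA,
so the somatic scaffold equals the germline scaffold with `length − 2` bases
deleted per IES, and `junction_mac` is the start of the retained TA on the
somatic reference. This representation makes excision exactly reversible,
which the genome builder asserts for every scaffold it emits.

## Retention scoring

A read supports an IES boundary when one of its aligned blocks covers the
boundary with at least `anchor` bases on both sides; on the somatic reference
the anchor must flank the 2-bp junction TA on each side. The anchor defaults
to 5 bp: it is not standardised anywhere, small anchors inflate spurious
junction support from terminal mismatches, and the value is exposed in the API
and CLI. Secondary and supplementary alignments are skipped; duplicates are
not removed. Mates of a pair are counted independently.

The global score (L⁺+R⁺)/(L⁺+R⁺+2M⁻) is boundary-symmetric: a read spanning a
whole short IES legitimately supports both boundaries (+2), while the excised
form presents a single junction, hence the factor 2 on M⁻. Whether the
upstream tools pool counts or average per-boundary scores is not documented,
so per-boundary scores are emitted alongside the global one. `IrsRecord`
additionally carries the number of *distinct* informative reads, which is the
right effective sample size for binomial error bands (boundary double-counts
are one observation, not two).

An IRS is undefined (not zero) when no informative read exists; undefined
records are reported separately by `classify_retention` and dropped pairwise
by the correlation analytics — imputing them would manufacture signal.
Retention uses a strict inequality (IRS > threshold); the conventional cutoff
0.1 excludes weak stochastic retention, and 0.01 is commonly used as a
weak-retention cutoff, so the threshold is a parameter everywhere rather than
a constant.

## Correlation trends

Pearson's r, OLS, LOWESS and an orthogonal line are fitted on the IESs
defined in both conditions. LOWESS is the standard tricube locally weighted
regression (statsmodels), default fraction 0.3 with 3 robustness iterations —
the method is conventional for these plots but its parameters are not, so
they are recorded in the result object. The orthogonal line is total least
squares computed from the eigen decomposition of the centred second-moment
matrix; tests cross-check it against a dense perpendicular-residual grid
search and against an independent iterative orthogonal-regression fitter.
Hexbin counts (matplotlib geometry, 40 bins across the x-range) are
visualization support; only their conservation of the point count is treated
as a contract.

## Small-RNA classification

Iterative alignment with read subtraction is modelled as priority-ordered
full-length matching: each read takes the first label in the hierarchy whose
reference contains it (either strand; Hamming mismatch budget, default 0) and
is then subtracted. The default order — vector → host bacterium → TE → OES →
IES → MDS — puts contaminant and most-specific references before the
genome-wide one; the true order used with aligner-based workflows is not
documented, so the order is configuration, recorded in the result, and the
tests verify that single-reference reads are order-invariant. Multi-locus
matches within a reference resolve to the first record; reads are never
fractionally assigned, keeping all count conservation exact. At toy scale the
matcher is exact string search; real datasets can be classified upstream and
enter as per-reference alignments.

Class definitions follow the developmental small-RNA biology: 23 nt siRNAs,
25 nt scnRNAs, 26–31 nt iesRNAs (IES-exclusive). The scanning ratio is
IES-matching over MDS-matching read counts at 25 nt, undefined when the
denominator is zero. The iesRNA contribution at threshold *t* is the fraction
of feature-assigned iesRNA reads whose source IES has IRS > *t*; it is
monotone non-increasing in *t* by construction, and reads without an assigned
feature are tallied but excluded from the denominator.

## Nucleosome density

MNase libraries are filtered to mononucleosome fragment lengths, 125–175 bp
inclusive at both ends. Libraries within a group are downsampled without
replacement to the smallest library size (deterministic under the seed).
Fragments are counted over IESs either by any-overlap (≥ 1 bp, the default,
matching interval-count semantics of the common counting tools) or by
midpoint (left-median base, so an even-length fragment straddling two
adjacent intervals resolves to the lower coordinate). Density is
(mᵢ/M)/(gᵢ/G) with post-filter, post-downsampling totals; it is undefined
when the input count is zero, and undefined records are excluded from tests
with the exclusion counted. Presentation-range truncation of density values
(e.g. plotting 0–4) is never applied to statistics.

Mann–Whitney U uses midrank ties, exact enumeration when the pooled sample
has ≤ 12 observations and no ties, otherwise the normal approximation with
tie and continuity corrections (scipy backend; an enumeration oracle in the
tests pins the exact branch). Holm–Bonferroni is the standard step-down
(statsmodels backend, hand-checked); the correction family is exactly the set
of comparisons passed in one `compare_groups` call, since any wider family
definition would be an unstated analysis choice. Box summaries use linear
interpolation quartiles and 1.5×IQR whiskers clamped to data points.

## Chromodomain classification

Candidates (30–80 aa) are globally aligned (BLOSUM62, gap open −10, extend
−0.5) to bundled reference CDs carrying annotated cage (3) and clasp (2)
columns, and residues are read off the best-scoring reference; a best score
below 40 rejects the sequence as not CD-like. The aromatic set is {F, Y, W} —
histidine is excluded, since admitting it would silently change non-binder
calls. Polarity uses the standard side-chain partition (polar:
S T N Q C Y D E K R H; nonpolar: G A V L I P M F W). pI is found by bisection
on the Henderson–Hasselbalch net charge over termini and D/E/C/Y/H/K/R side
chains, EMBOSS pKa values by default (switchable), to |charge| < 1e-4. The
acid/base boundary for the call is pH 7, with an optional dead zone
(default off) that returns indeterminate near the boundary, because the pKa
set choice can move pI by a few tenths of a unit.

The bundled references are **synthetic** constructs (so labelled in the data
file): they reproduce the canonical HP1-type architecture (cage Y/W/Y, polar
clasp, strongly acidic composition) and Pc-type architecture (cage Y/W/W,
hydrophobic clasp, basic composition) without quoting any particular
database sequence. Published per-protein pI values depend on unstated pKa
sets and are not used as oracles; the contract tested is the one the
classification rule defines: each reference classifies as its own type, and
any cage-divergent variant is a non-binder regardless of clasp and pI.

## Synthetic data: what it emulates, and what it does not

The toy genome is i.i.d. background sequence (default GC 0.3, matching the
AT-rich genome) with a forced TA at each junction site; sites keep 500 bp
from scaffold ends and each other so no fragment spans two IESs. IES lengths
default to 26 + Exponential(scale 45 bp), reproducing the two constraints the
length distribution is known to satisfy — a 26 bp minimum and ~93–94% below
one nucleosome footprint — without asserting the true distribution's shape;
the sampler is a plain callable and several tests substitute uniform ones.

The genomic-read simulator draws fragments (default 300 bp insert, 100 bp
reads from both ends) along the germline reference and gives each fragment
the IES-retained form of IES *i* with probability r_i, independently per
fragment and spanned IES. Truth alignments are emitted directly — placement
is known, so no aligner runs at toy scale — to each reference the read is
colinear with. One physical subtlety: a fragment starting inside an IES can
only exist on a retained molecule, so those retention draws are conditioned;
they are correct for coverage but excluded from the binomial truth labels.
Sequencing error is off by default because none of the downstream statistics
model it.

The MNase simulator places fragment midpoints so density per bp over interval
*i* is proportional to its planted weight, with N(150, 20) lengths clipped at
50 bp — deliberately wider than the 125–175 bp window so the size filter has
work to do. The small-RNA simulator draws exact substrings from per-class
source records (record chosen proportional to length, position uniform,
strand random).

Consequently, green tests show that the *computations* are correct under
known truth: junction counting matches interval arithmetic, IRS converges to
the planted retention at the binomial rate, classification recovers truth on
k-mer-disjoint references, density recovers planted occupancy ratios, and the
test stack is calibrated under the null. They do not demonstrate robustness
to alignment artefacts, repeats, copy-number variation, sequencing error,
PCR duplicates, or imprecise excision boundaries — real data enter as SAM and
inherit whatever the upstream aligner did.

## Problem sizes and determinism

End-to-end experiments run at desk scale chosen for tight statistical bands:
200 IESs at 100× coverage for IRS recovery (≈160k reads), 10,000 small-RNA
reads, 50,000 fragments per MNase library, 1000 replicates for the null
calibration of the Mann–Whitney test at n = 30/30. Every stochastic step
takes an explicit seed and is byte-deterministic under it; the acceptance
script derives all sub-seeds from its single `--seed` argument.
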