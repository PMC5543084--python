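# Methods

## Matching model

All primer–template comparison reduces to position-wise IUPAC base-set
intersection. Each of the 15 ambiguity codes denotes a set of concrete bases;
two codes *mismatch* at a position iff their sets are disjoint. Consequences:

- `N` matches everything; `Y` vs `C` is a match; `Y` vs `R` is a mismatch
  only through disjointness (here `{C,T} ∩ {A,G} = ∅`, so it is one).
- `pattern_mismatches(a, b)` equals the minimum Hamming distance over the
  Cartesian product of the two expansions, because positions are independent.
  The test suite verifies this against a brute-force oracle.
- Database sequences may themselves carry ambiguity codes; they participate
  in the same intersection rule (an ambiguous database base is "sequence
  information", not missing data). Gap (`-`) and missing (`.`) characters
  have an empty base set: they mismatch everything and mark a window
  non-concrete.
- `U` is normalized to `T` on input; lowercase to uppercase. Gap characters
  are illegal inside a primer pattern (they belong to alignments).
- Degenerate expansion is capped at 4,096 variants by default to guard
  against accidental poly-N patterns; the cap is an explicit argument.

## Coordinates and amplicons

Internally everything is 0-based, half-open. The published primer names
encode 1-based reference coordinates: the forward footprint starts at
position 244 and the amplicon ends inclusively at 658 (= 659 − 1), giving the
printed 415 bp product; this is the only reading consistent with
`415 = 659 − 244`. The synthetic default template reproduces this layout on
a 1,000 bp background.

In-silico PCR pairs forward hits with antisense reverse hits under a
*symmetric nearest-partner rule*: a product is kept when the reverse hit is
the nearest downstream partner of its forward hit or the forward hit is the
nearest upstream partner of its reverse hit, within length bounds (defaults
50–5,000 bp, overridable plumbing choices). Both template orientations are
scanned and minus-orientation products are mapped back to supplied-strand
coordinates, so the predicted product set is invariant under
reverse-complementing the input — as it must be, since PCR amplifies a
double-stranded region. A one-directional "each forward hit takes its
nearest downstream reverse hit" rule would break this symmetry whenever two
forward sites share one reverse site; the symmetric rule keeps both nested
products.

Unspecific short products seen on gels at low annealing temperatures are a
thermodynamic phenomenon and are deliberately not modeled; only binding-site
arithmetic is in scope.

## Eligibility, coverage, specificity

A database record contributes to coverage/specificity denominators only if
it holds concrete sequence information across both binding windows:

- *Unaligned databases*: each window is located per record by a best-hit scan
  (minimum mismatch count over members and positions, gaps counting as
  mismatches; leftmost tie-break). The record is `truncated` when it cannot
  hold the expected amplicon downstream of the forward site, `gap` when the
  best window overlaps a gap/missing character.
- *Aligned databases*: window columns are located once per group as the
  offset minimizing the mean mismatch count across fully-concrete rows, with
  the reverse window constrained downstream of the forward one. The spec of
  the alignment columns is thereby derived from the data rather than supplied.

*Coverage* counts a sequence as matched only at 0 mismatches for at least one
forward member AND one reverse member ("fully match"). Percentages are
rounded half-up for table display; full precision is kept in reports.

*Specificity* reports, per off-target sequence, the per-primer minimum
mismatch count over members at the best position, combined as the maximum
over the two primers: a primer pair is only as unspecific as its
better-behaved primer allows. This max-over-primers reading of "the pair has
k mismatches" is one of several possible conventions and is flagged on every
report (`combination_rule`).

## Equimolar mixture design

Highly degenerate syntheses inevitably contain variants matching no real
target, which degrades specificity and qPCR accuracy. The designer rebuilds
defined mixtures from the multiset of observed binding-site k-mers under a
no-phantom constraint: candidate oligos carry at most `max_ambiguities`
degenerate positions (default 1, as in the published mixtures), placed only
at columns where ≥ 2 distinct bases are observed, and a candidate is admitted
only if its full expansion is a subset of the observed k-mers. Selection
maximizes multiplicity-weighted coverage with at most `max_oligos` members.
Instances within an enumeration budget (200,000 candidate combinations) are
solved exactly by bitmask search; larger instances fall back to greedy
selection. Ties break deterministically: fewer oligos, lower total
degeneracy, lexicographic order. Exact search was chosen over pure greedy
because greedy provably misses the optimum on some small weighted instances,
and small instances are the practically relevant regime (binding sites have
few variable columns).

## Melting temperature

Two standard formulas, applied per expanded variant and summarized as
min/mean/max (a degenerate primer is a mixture, so a single Tm is ill-posed):

- basic: `Tm = 64.9 + 41·(GC − 16.4)/L`
- salt-adjusted (default, [Na+] = 50 mM):
  `Tm = 100.5 + 41·GC/L − 820/L + 16.6·log10([Na+])`

The salt-adjusted form at 50 mM reproduces ≈ 47.5–48 °C for the clade-A
forward oligos, matching the design target of the published primers. No
nearest-neighbor thermodynamics, dimer or hairpin screening is attempted.

## OTU clustering

Pairwise identity = matches / aligned columns under a global alignment with
free terminal gaps (match +2, mismatch −1, gap open −4, extend −1), terminal
gap columns excluded — so equal-length indel-free pairs reduce to Hamming
identity, and a fragment nested in a longer sequence scores on the overlap
only. Clustering is greedy centroid clustering at a fixed threshold (default
0.95): sequences processed by descending length then id found a new cluster
when no existing centroid reaches the threshold. Because pure greedy
assignment can leave a member nearer a centroid founded later, a final
deterministic re-assignment pass moves every member to its best centroid;
this makes the output stable under a best-centroid re-check without changing
the centroid set. The identity metric and clustering order are package
choices (the convention in the field varies by program), so OTU counts on
real data are comparable only approximately across tools. One known artifact
of overlap identity: sequences differing only by a shifted homopolymer end
can score 1.0.

## qPCR model

`Cq = intercept + slope·log10(copies)`, fitted by ordinary least squares over
all replicate points; `r² = ρ²` of the fit, flagged below 0.98 (the usual
curve-acceptance rule). Efficiency `E = (10^(−1/slope) − 1)·100`, the
standard transformation (100% = perfect doubling, slope −3.3219).

Unknowns measured at several template dilutions are back-scaled
(`copies·dilution_factor`, replicates combined by geometric mean on the log
scale); the pair of *highest* dilutions agreeing within 0.3 log10 (≈ 2-fold,
configurable) gives the final value as the pair's geometric mean. Geometric
averaging is used throughout because copy estimates are exponential in Cq.
A single measured dilution degenerates to its own estimate; no agreeing pair
flags the result inconclusive rather than raising. Relative abundance is the
per-assay fraction of the summed copy number, undefined (and flagged) when
the total is zero.

## Synthetic data

Generators are pure functions of spec + seed (one `numpy` PRNG stream each;
identical bytes on rerun). They emulate the structural features the toolkit
consumes — binding sites at canonical coordinates, planted per-primer
mismatch counts, gapped/truncated records, dilution series with known
efficiency — and none of the features of real survey data they do not need:
no phylogenetic correlation, no codon structure, no chimeras, uniform A/C/G/T
background. Passing tests on synthetic data therefore demonstrate the
*arithmetic* (site finding, counting, fitting) is right, not that real-data
coverage values will be reproduced; the published database-scale coverage
figures require the authors' reference alignment and are an optional external
validation, not part of the test surface.

Planted mismatches are placed only at primer positions that are
non-degenerate across all members, mutated to a base outside the allowed
set, so the planted count equals the measured minimum exactly. After
assembly every record is re-scanned with the package's own search; a
background that happens to contain a better-matching site is resampled
(deterministically, bounded at 200 attempts) so truth tables are exact by
construction. The default template plants sites drawn from the clade-A
equimolar mix members — all of which lie inside the degenerate expansions —
so the same template amplifies identically under both clade-A primer
representations.

qPCR generation uses `slope = −1/log10(1 + E)` with Gaussian Cq noise;
defaults (8 tenfold levels from 10¹ copies, triplicates, E = 88.5%) mirror
the study conditions. Problem sizes used in tests (databases of 10–30
records of 600 bp, 500 noise simulations, OTU sets of ≤ 10 sequences of
100–200 bp) were chosen as the smallest sizes at which each property is
non-trivially exercised.

## Known limitations

- Mismatch counting is indel-free by design; a primer binding across an
  indel is simply a poor match.
- Aligned-database window location assumes the primer region is present in
  the alignment; wildly diverged alignments could lock onto a wrong column.
- The specificity combination rule (max over primers) is a convention; other
  published counts may use per-primer or summed rules.
- OTU identity is alignment-parameter dependent near the threshold.
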