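# Methods

## Motif model and coordinate conventions

Motifs are fixed-length words over one of two degenerate alphabets: the
11-letter alphabet (A, C, G, T, the six two-fold wobbles r, y, s, w, m, k,
and the four-fold wildcard n) used for 8-mers, and the 5-letter alphabet
(A, C, G, T, n) used for 12-mers. Three-fold IUPAC codes (b, d, h, v) are
deliberately not representable: they are rarely informative for binding-site
description and would grow the search space 2.6-fold. A word's integer code
reads its letters as digits (A…n → 0…10) of a base-11 (base-5) number,
leftmost letter most significant, so every statistic lives in a dense array
indexed by code.

Promoters are fixed-length upstream windows (canonically 1000 bp) on the
forward strand, 5'→3', ending immediately upstream of the TSS (or the
translation start / 5'UTR start, depending on how the input set was
extracted — the core treats any fixed window identically). Occurrence
coordinates are 1-based window start indices: position 1 is at
−window_length, and an L-mer's last valid start is S = W − L + 1 (993 for
8-mers in 1000-bp windows). Matching is exact per position against the
wobble's base set. An `N` in the sequence is ambiguity, not degeneracy: no
window overlapping an `N` is extracted, and `N` matches nothing, including
the query-side wildcard n. How assembly gaps should be treated is not
otherwise determined by the method; skipping gapped windows is this
package's choice and keeps presence counts conservative.

Scanning one strand only would double-count motifs that are their own
functional unit read off the other strand, so reverse-complement symmetry is
restored at the reporting stage: after ranking, one member of every RC pair
is dropped (the better-ranked one is kept; palindromic words are kept
unconditionally).

## Cataloging (the indexer)

The defining quantity is the **promoter-presence count**: for every oligo,
the number of promoters containing at least one matching window (per-promoter
presence, not occurrence multiplicity). Conceptually, each promoter
contributes one count to every degenerate expansion of every clean window —
5⁸ = 390,625 expansions per 8-mer window (each position: the base, its three
two-fold wobbles, or n). Materializing expansions is wasteful, so the
implementation computes the identical result with a separable superset
transform: concrete window codes of up to 64 promoters are marked as bits in
a packed uint64 array of length 11⁸, then for each word position every
degenerate digit's slice is OR-ed together from the concrete digits it
covers (r = A|G, …, n = r|y); afterwards bit j of entry c is set iff promoter
j harbors oligo c, and a popcount accumulates the counts. Equivalence with
direct expansion enumeration is exact (each axis independently replaces
"digit = base" with "digit = any covered base") and is verified in the test
suite against a brute-force matcher, exhaustively over all 11³ codes at
word length 3.

The same transform with addition instead of OR (valid because every wobble's
base set is a disjoint union) converts per-code window-occurrence counts and
position sums into occurrence counts and position sums of *every* degenerate
oligo at once; these drive the position-bias statistics.

The dense arrays are the design's memory budget: 11⁸ uint16 counters
(~429 MB) plus a transient 1.7 GB packed batch array; occurrence statistics
add an int32 and an int32/int64 array (857 MB–1.7 GB, freed after use). The
two least-significant word positions are cache-hostile (stride ≤ 11), so
they are processed by small compiled (numba) block kernels over contiguous
121-element tiles, with a pure-numpy fallback path computing the same thing.
Genome indexes are serialized as raw little-endian counter arrays with a
JSON sidecar (alphabet, word length, promoter count, SHA-256 checksum).

## Over-representation statistics

With M cluster promoters inside a K-promoter genome universe, an oligo in m
cluster and k genome promoters is *tested* iff it exists in fewer than half
of the genome's promoters (k < K/2; ubiquitous words are uninformative) and
is over-represented (m > kM/K). Tested oligos get the hypergeometric upper
tail p = P(X ≥ m), X ~ Hypergeom(K, k, M), evaluated by log-gamma summation
with logsumexp — tails of interest reach 10⁻⁴⁰ and beyond, far below naive
summation's underflow. scipy's hypergeometric survival function serves as an
independent cross-check in tests, alongside an exact rational-arithmetic
oracle for all parameter tuples with K ≤ 12 (relative tolerance 1e-12).
Because the p-value depends on (m, k) only, genome-scale scans compute
p-values on the occupied (m, k) grid (at most (M+1)(K+1) cells) and map them
back to the 214M codes in chunks.

Fold enrichment is (m/M)/(k/K), reported but not used for ranking (it is
noisier than the p-value). q-values are Benjamini–Hochberg over the tested,
RC-deduplicated family; when that family is too large to enumerate
(> 2·10⁶), its size is approximated by half the tested count (palindromes
are a vanishing fraction), which only rescales the reported q-values, never
the ranking or the qualification decisions. Which multiple-testing
adjustment the original method used is not documented; BH is the
conventional reading of a q-value column.

The expected number of null (false-positive) oligos below a cutoff p is
bookkept as n_restricted × p / 4, where n_restricted counts oligos with
k < K/2: one factor of ~2 for the over-representation gate and tail
discreteness, one for RC dedup. Both factors are regime-dependent
approximations (see Calibration below).

## Position bias

Under no positional selection, occurrence starts are uniform on {1, …, S},
with mean μ = (1+S)/2 and per-instance variance σ² = (S²−1)/12 (the discrete
uniform variance; for S = 993, μ = 497). An oligo with n occurrence
instances (all occurrences in all selected promoters — occurrence count, not
presence count) at mean position p̄ scores z = (p̄ − μ)/√(σ²/n); positive z
means TSS-proximal bias. Note the /12 belongs in the variance: without it,
null z-scores would have a standard deviation near 0.29 and the z > 3 cutoff
would be uninterpretable; the test suite verifies the null z distribution is
standard-normal-like by simulation. μ and S are always derived from
(window_length, L), so 12-mers and non-1000-bp windows are handled
consistently. The z-score cannot, by construction, detect bias toward the
window interior (a symmetric bump at −500 bp leaves p̄ ≈ μ).

An oligo qualifies as a potential motif if p < 10⁻⁷, or if
10⁻⁷ ≤ p ≤ 10⁻⁵ and z > 3 (both thresholds configurable). The two criteria
measure different signals and are independent under the null.

## Major-motif selection

Ranked significant lists are dominated by degenerate variants of a few
underlying motifs. The position-overlap filter walks the p-value ranking
(ties broken by code for determinism): the best remaining oligo becomes a
major motif and claims its occurrence positions — exact (gene, start) pairs;
any remaining oligo with ≥ 10% of *its own* positions claimed is removed;
iteration halts when fewer than 10 oligos remain (both parameters
configurable). Two design points were genuinely open and resolved as
follows. First, "position" means the exact start: variants matching the same
site one window to the left or right are *not* merged by default, consistent
with treating shifted words as distinct discoveries; a ±w bp slack parameter
(default 0) merges frames when desired. Second, the overlap denominator is
the candidate's own position count (asymmetric), which is the natural
per-candidate reading and guarantees the iteration makes progress.

## Two-genome analyses

**Conserved p-values.** A cluster is restricted to genes with orthologous
promoters in a related species (orthology is consumed as a precomputed
one-to-one two-column table; protein-alignment-based ortholog detection is
upstream of this package). Enrichment runs independently per species on the
orthologous promoter sets, per-species records are RC-deduplicated and keyed
by the canonical (smaller-code) orientation, and each oligo joined across
species receives conserved p = max(p₁, p₂), keeping records at or below the
cutoff (default 10⁻⁵). True motifs stay significant in both close relatives;
independent false positives rarely repeat, so the relaxed cutoff recovers
motifs a single-species analysis at 10⁻⁷ would miss.

**Genome-wide bias scan.** All 8-mers with at most two degenerate letters
drawn from {r, y, s, w, n} — C(8,0)·4⁸ + C(8,1)·5·4⁷ + C(8,2)·5²·4⁶ =
3,588,096 words; m and k are excluded from this restricted vocabulary —
are scored by the z-score over *all* promoters of a genome, thresholded
(z ≥ cutoff), RC-deduplicated keeping the higher-z member, and reported in
canonical orientation so that two genomes' scans can be intersected by exact
string equality. Instance counts are occurrence counts, matching the n the
z-score uses.

## Synthetic data generator

The generator emulates the statistical structure the method relies on, not
real promoter biology. Background sequence is i.i.d. with AT-rich
composition (0.33/0.17/0.17/0.33), reflecting plant promoter regions; an
order-1 Markov background is not implemented because every statistic
conditions on the empirical genome index, so the null only needs
self-consistency. Planted motifs are realized per target promoter by drawing
a concrete word uniformly from the motif's match set and overwriting the
background at a start drawn either uniformly or from a TSS-proximal peak
(uniform within [peak_start, peak_end] with a configurable weight). Planted
fractions are realized exactly (rounded counts, sampled without
replacement). The two-species generator mutates each base independently at a
configurable substitution rate (default 0.15, emulating ~85% promoter
identity between close relatives) and can protect planted instances from
mutation (conserved motifs) or let them diverge. All streams derive from one
seed via named spawned substreams, so outputs are byte-identical across
runs.

What the generator does not emulate: positional autocorrelation of real
sequence (repeats, CpG/CpNpG structure), promoter-length variation, indels
between species (orthologous positions stay aligned), and motif multiplicity
per promoter (one planted instance per selected promoter). Passing the
recovery tests therefore demonstrates the machinery — cataloging,
gating, scoring, filtering, conservation logic — under controlled signal,
not performance on real genomes.

## Calibration experiments and their scale

The false-discovery calibration samples random promoter groups (no shared
signal), counts RC-deduplicated oligos below p cutoffs, and compares with
n_restricted × p / 4. The test suite runs this at reduced scale — 3-mers
over the 11-letter alphabet, 30-bp windows, a 200-promoter genome, 20
groups of 20 promoters, cutoffs 0.01/0.05/0.1 — sized so the restricted
family is populated (in 1000-bp windows every 3-mer is ubiquitous) and the
whole experiment takes seconds. At this scale the /4 formula's two factors
are only approximations: on an i.i.d. null, an oligo's and its reverse
complement's p-values are nearly independent, so RC dedup removes far fewer
than half of the sub-cutoff oligos, and the attained tail probability
P(p ≤ α) sits between α/4 and α depending on the discreteness of the
(m, k) grid. The observed counts consequently run a factor ~2 above the
formula while remaining within the 3·√expected band asserted by the tests;
the formula is an order-of-magnitude anchor, tightest in the deep-tail,
real-genome regime it was designed for. The pooled z-scores of tested
oligos on the null are checked for mean ≈ 0 and sd ≈ 1 with tolerances
(|mean| ≤ 0.4, sd within 25%) that reflect the small number of effectively
independent oligos per group — degenerate words overlap heavily, so the
pooled mean fluctuates more than an i.i.d. count would suggest.

The planted-recovery experiment runs at full 8-mer scale on a 96-promoter
genome of 250-bp windows with a 30-promoter cluster (70% planted,
TSS-proximal) and a 15%-diverged second species with protected instances;
these sizes keep the complete two-species analysis within a few minutes on
one CPU while exercising every full-scale code path, including the dense
11⁸ arrays. The recovery criterion allows degenerate-variant equivalence:
the top major motif must claim the planted occurrence positions (its match
set covers the planted instances), not necessarily equal the planted string
— with ~21 planted instances, several degenerate generalizations fit the
data equally well and rank interchangeably.

## Numerical and degenerate-input choices

- Counter dtype is uint16 by default (promoter universes ≤ 65,535) and
  validated against the promoter count; uint32 on request.
- p-values are computed in log space throughout; the smallest representable
  tails (~1e-300) are far below any cutoff of interest.
- Ties in p-value rank break by integer code; all pipeline outputs are
  deterministic given inputs and seeds.
- Empty position lists (z-score), k = 0 (fold enrichment), empty promoter
  subsets, and out-of-range codes raise informative errors rather than
  returning sentinels.
- Promoters consisting entirely of gapped windows contribute nothing to any
  count, including the all-n oligo.

## Known limitations

- Single-strand scanning with reporting-stage RC dedup means a motif's
  reported orientation is rank-dependent (the better-ranked member of the
  pair), not biologically resolved.
- The q-value family-size approximation above 2·10⁶ tested oligos rescales
  q-values by at most the palindrome fraction.
- Interior position bias is invisible to the z-score (see above).
- The position filter can absorb genuinely distinct motifs that share
  binding sites, and exact-start identity treats frame-shifted variants as
  distinct unless slack is enabled.
- The expected-false-positive formula is an approximation whose constituent
  factors weaken off the deep-tail regime (see Calibration).
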