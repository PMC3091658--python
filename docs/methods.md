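# Methods

`estdd` implements the computational core of a classic two-library EST
(expressed sequence tag) study: Sanger reads from two non-normalised cDNA
libraries — here labelled JD (developing seed) and JG (germinating seed) —
are cleaned, collapsed into unisequences, counted per library, rescaled to
ESTs per 10,000 reads, and compared with the Audic–Claverie (AC) tag-count
test. A seeded simulator generates both libraries with known ground truth so
that every stage is testable without chromatogram data.

## The AC tag-count model

For a transcript observed `x` times among the `N1` reads of one library,
the probability of observing `k` occurrences among the `N2` reads of the
other library, under equal underlying expression, is

    p(k | x) = (N2/N1)^k · C(x+k, k) · (1 + N2/N1)^-(x+k+1)

This is a proper probability distribution over `k` (the suite checks
Σ_k p(k|x) = 1 to 1e-10). It is evaluated in log space via `lgamma`, with
successive terms generated by the exact ratio
`p(k)/p(k-1) = r(X+k) / (k(1+r))`, `r = N2/N1`, so counts of any size stay
finite.

**Two-tailed convention.** The reported p-value conditions on the side with
the larger *normalized* count (count/library total), call it `(X, N_X)`,
sums the tail over the other side's count `Y`, doubles, and caps at 1:

    p = min(1, 2 · Σ_{k=0..Y} p(k | X))

Conditioning on the larger normalized rather than raw count matters only
near the diagonal, but it is what published two-library EST tables follow:
with unequal library sizes an equal raw count (x = y = 1 at totals
7,320/5,929) yields 0.84 under this convention, whereas conditioning on the
raw larger count would double a sum exceeding one. All 25 distinct printed
p-values we calibrate against reproduce to their full printed precision (4
significant digits where given) under this convention.

**Monotonicity.** For fixed `x`, once `y` is on the depleted side of the
equal-rate point `y* = x·N2/N1`, the p-value falls strictly as `y → 0`.
Between `y*` and `x` the doubled statistic saturates near 1; the test is
two-sided, so no ordering is claimed there.

**Normalization.** Counts are rescaled to ESTs per 10,000 library reads and
*truncated* (not rounded) to two decimals, computed exactly as
`(c·10000·100) // N / 100`. Truncation is deliberate: 1/7,320 prints as
1.36 (1.366… would round to 1.37) and 33/5,929 as 55.65 (55.658… would
round to 55.66) in the tables this package reproduces.

No multiple-testing correction is applied by default; the CLI exposes
Benjamini–Hochberg (via statsmodels) behind an off-by-default flag.

## Cleaning

Four artefact classes are masked independently (0-based half-open
intervals), then the longest interval free of all masks is kept; survivors
need at least `min_clean_len = 100` clean bases.

- **Low quality**: the union of all sliding windows (default width 10)
  whose mean phred quality is below 20. Window *sums* are compared to
  `min_mean_q · w`, which is exact for integer qualities. Reads shorter
  than the window are judged by one whole-read window.
- **Poly-A/T**: the exact union of all intervals of length ≥ 12 whose A (or
  T) fraction is ≥ 0.9, i.e. qualifying intervals "extended maximally".
  Computed by an O(L²) vectorised scan per read, pre-screened by a
  5-base exact-run seed (any qualifying interval at purity ≥ 0.8 must
  contain one). Note a consequence of maximal extension: a pure tail of
  L extra As can absorb ~L·(1−p)/p adjacent non-A bases (40 As + 4 non-A is
  still 0.909 pure), so the clean region's 3' boundary can sit a few bases
  inside a planted core. The brute-force oracle in the test suite defines
  the intended behaviour.
- **Vector/primer**: local alignment (Smith–Waterman scoring +1/−2, gaps
  −4/−2, via Biopython's PairwiseAligner) of the read against each vector
  sequence; spans with identity ≥ 0.9 over ≥ 20 aligned columns are masked,
  blanked, and the search repeated so multiple hits are found. `N` never
  matches, so it counts against identity.
- **Slippage**: a 5' echo heuristic — if the 30-base read prefix re-occurs
  at offset s ≤ 200 with ungapped identity ≥ 0.9, the duplicated span
  [0, s) is masked. The chromatogram-era cleaning pipelines this emulates
  do not publish their slippage rule; this detector is a documented
  stand-in, not a reimplementation.

Ties for the longest clean region go to the leftmost (5'-most) interval,
since 5'-sequenced reads carry the informative end. Cleaning is idempotent
on its survivors: every window inside a clean region already passed, so
re-running the pipeline on trimmed reads changes nothing (property-tested).

## Clustering

Two cleaned reads are similar when their best local alignment covers ≥ 50
columns at identity ≥ 0.95, identity = matches ÷ aligned columns with gaps
counted as columns. Unisequences are the connected components
(single-linkage closure) of this relation: components of size ≥ 2 are
contigs, the rest singletons. This deliberately replaces a full
overlap-layout-consensus assembler; the clustering role of the similarity
criterion is kept, assembly internals are simplified, and the identity
definition is fixed here even though assemblers differ slightly.

A shared-k-mer prefilter makes the pass near-linear: any overlap of L ≥ 50
columns at ≥ 0.95 identity has at most ⌊0.05L⌋ non-match columns, so its
longest exact run is ≥ ⌈(L−e)/(e+1)⌉; minimising over L gives k = 15, and
only read pairs sharing a 15-mer are aligned, with union-find early exit
skipping pairs already connected. Components are numbered by first-seen
member; all tie-breaks are fixed, so output is reproducible.

Contig consensus uses an ungapped star layout: the longest member anchors,
others are placed by their best qualifying alignment against the anchor
(then against any placed member), using the largest aligned block for the
offset. Per column: plurality vote, ties by summed phred quality, then
alphabetical. Members with no qualifying overlap are appended unaligned and
logged. This is adequate for near-identical Sanger reads; it does not
handle indel-rich layouts (a non-goal).

## Synthetic data

The generator emulates the study's sequencing setup: 5'-sequenced cDNA
reads that are prefixes of their source transcript, with

- transcript lengths Normal(1000, 150) floored at 200, i.i.d. uniform bases;
- per-library abundances: either supplied explicitly or drawn log-normal
  (σ = 1), matching the strong skew of non-normalised libraries;
- read lengths Normal(560, 90) clipped to the transcript — after trimming
  this lands near the ~560 bp mean the emulated study reports;
- substitution errors (default 0.01/base), no indels (a non-goal);
- a 3' poly-A run of 15–40 bases with probability 0.6;
- 5' vector carryover with probability 0.3: a 30–60 base suffix of a
  synthetic cloning-vector sequence ending in the M13F primer
  (TGTAAAACGACGGCCAGT), mimicking a read that starts inside the polylinker;
- phred profile: plateau ~Q40 (jitter ±3, never below 30), decaying
  linearly to ~Q3 over the final 10% of the read. No chromatogram model is
  published for the emulated data; this is the simplest profile that
  exercises quality trimming.

Every read records its planted structure (source transcript, vector end,
insert end, poly-A length, decay start) in `annotations`; `SimTruth` holds
per-transcript abundances, realized counts and a DE flag (abundance ratio
> 2-fold by default). One seeded generator drives all sampling, so a fixed
seed yields byte-identical FASTA/qual output.

What the simulator does *not* model — chromatogram noise structure, indel
errors, chimeric clones, 3' reads, cloning bias — bounds what passing tests
show about real data: they validate the algorithms' contracts and
statistical calibration, not robustness to every Sanger artefact.

## Statistical calibration

At library totals 7,320/5,929 with 2,000 transcripts and 200 replicates
(multinomial sampling, log-normal abundances):

- **Size**: on equal-abundance libraries the pooled rejection rate of the
  AC test at α = 0.05 is ~0.02–0.03 — conservative, as expected for a
  discrete doubled two-tailed statistic at small counts.
- **Power**: for a transcript planted at a 10-fold abundance ratio, the
  detection probability at α = 0.001 rises steeply with expression:
  roughly 0.69 at an enriched-library expected count of 20, 0.93 at 30,
  0.98 at 35, and >0.99 from 40. The generator plants DE transcripts at an
  expected count of 30; pooled detection is therefore ~0.93. Counts below
  ~35 simply do not carry enough evidence for α = 0.001 under the doubled
  two-tailed convention, which is worth remembering when interpreting
  two-library studies of this size.

## Problem sizes used by the test suite

The suite regenerates everything at run time: the recovery fixture uses 100
transcripts × 2,000 reads per library (noiseless, with planted vector and
poly-A), the calibration suite 2,000 transcripts × 200 replicates at the
study totals, and the exact-arithmetic oracle covers all count pairs up to
60 at those totals. Brute-force oracles (exhaustive window evaluation,
substring purity scans, interval enumeration, rational-arithmetic AC sums)
freeze the expected values independently of the implementation.

## Known limitations

- Single-linkage clustering merges through chimeric bridges that a real
  assembler would split; no chimera detection is attempted.
- The consensus is ungapped; indel-containing members shift downstream
  columns instead of gapping them.
- The slippage detector only inspects the read prefix.
- Category rollups normalize summed raw counts and truncate once; published
  aggregate tables computed from unpublished per-unisequence counts cannot
  always be reconciled against any integer count under either
  truncate-then-sum or sum-then-truncate, and no attempt is made to chase
  such rows.
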