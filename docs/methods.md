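# Methods

## Model and procedure

`peako` ranks candidate transcription-factor motifs for a WT/KO ChIP-seq
experiment by combining two differential analyses that address noise
removal in distinct ways.

**Uniform windows.** Both arms start from called peaks. Each narrowPeak
region is re-centered on its summit (column 10; interval midpoint when the
summit is the unknown-summit sentinel −1) and extended to a uniform width
(default 500 bp). Windows that would cross a chromosome boundary are
dropped, not clipped, so that every analyzed sequence has identical length
L; the drop count is logged and slop-style clipping is available behind an
explicit option. Uniform L is load-bearing: the positional null of the
binomial test and the comparability of center displacements both assume it.

**Best-site scanning.** Each motif (length m, column-stochastic PWM) is
scored over both strands of each window with a log-odds matrix in bits,

    S[j, b] = log2(((1 − c)·p[j, b] + c·bg[b]) / bg[b]),

with pseudocount fraction c = 0.01 by default. The background is taken
from, in order of precedence: an explicit override, the MEME file's
background block, or 0-order frequencies estimated from the positive
sequences (floored at 1e−4). One best site per sequence is kept — the
maximum-scoring eligible window with score ≥ `min_score` (default 0 bits,
i.e. better than background; the exact threshold used by the original
enrichment tool is not published, so it is exposed as a flag). Windows
containing N are ineligible rather than background-scored, so masked
regions cannot manufacture central matches. Ties break toward the smallest
|center displacement|, then the + strand, then the leftmost offset. The
center displacement of a site is `offset − (L − m)/2`, half-integral when
L − m is odd.

**Central enrichment.** Candidate windows are the symmetric displacement
sets about 0, narrowest first (sizes 1, 3, 5, … when displacement 0 is
attainable, else 2, 4, …), up to `min(L − m + 1, max_window)`. For each
window covering w of the T = L − m + 1 positions, the non-differential
statistic is the binomial upper tail P(X ≥ k), X ~ Bin(n, w/T), over the n
sequences with a best site, k of them in-window. The reported window
minimizes this raw p (ties → narrowest). In differential mode the window
is selected on the positive-set binomial statistic and a one-sided Fisher
exact test is then computed at that window from
[[k_pos, n_pos − k_pos], [k_neg, n_neg − k_neg]]. Sequences without a best
site count in neither k nor n. E-values are min(p, 1) × n_tests where
n_tests sums the windows evaluated across scored motifs by default
(equivalently #motifs × #windows at uniform motif length); correcting over
motifs only — the convention of tools that correct over the database size —
is selectable. The corrected p-value used downstream is min(p·n_tests, 1).

**Ranking metric.** Per motif, A_WT and A_KO are the positive/negative
peaks whose best site lies in the differential arm's enriched window, and
B the analogous peaks from the non-differential arm. Motifs with corrected
p > 0.1 (strictly greater; the default requires significance in **both**
arms, since both peak sets enter the score — `either` and `pipeline-a`
modes are available) are set aside, then

    r = |merge(intersect_wa(subtract_A(A_WT, A_KO), B))| / |A_WT|.

The operations carry exact BEDTools default semantics on 0-based half-open
intervals: `subtract -A` removes a whole A_WT interval on ≥ 1 shared base
(never truncates); `intersect -wa` emits one copy of the A interval per
overlapping B interval, original coordinates, duplicates retained;
`merge` (distance 0) fuses overlapping *and book-ended* regions — note
book-ended intervals do **not** overlap for subtract/intersect. Merging is
what bounds r at 1; two overlapping surviving A_WT peaks supported by one
B peak fuse and count once, a literal consequence of the definition that
is retained. A_WT is deduplicated by coordinate at load so |A_WT| is well
defined; r := 0 with an `empty_wt` flag when A_WT is empty, keeping the
ranking total. Retained motifs are ranked by descending r, ties by smaller
Pipeline A E-value, then Pipeline B E-value, then motif id; filtered
motifs follow in alphanumeric id order, where rank carries no evidence.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `peak_width` | 500 bp | uniform summit-centered window length |
| `alpha` | 0.1 | corrected-p significance threshold (strictly-greater removal) |
| `pseudocount` | 0.01 | log-odds regularization fraction |
| `min_score` | 0 bits | best-site eligibility threshold |
| `max_window` | L − m + 1 | cap on the centered-window schedule |
| `correction` | windows | E-value burden: motif×window tests vs motifs only |
| `filter_mode` | both | which arm(s) must be significant |

## The synthetic generator

The generator emulates the *structure* the method exploits, not read-level
data. A single-chromosome i.i.d. genome (default 1 Mb, GC 0.41 — a
mammalian-like composition) carries three disjoint classes of 500 bp loci:
`n_wt = 200` signal peaks, `n_shared_noise = 50` technical-noise loci
written verbatim into both the WT and KO peak files (encoding the premise
that shared pileups are noise), and `n_ko = 50` KO-only noise peaks. Each
signal peak receives, with probability `plant_prob = 0.8`, one site drawn
column-wise from the target PWM, on a random strand, at the peak center
plus a round(N(0, σ = 20 bp)) offset clamped inside the peak. The
differential peak set is the locus subtraction WT − KO (= the signal
peaks); this stands in for differential peak calling, which is out of
scope, and is labelled an approximation wherever it is used. The default
target is a synthetic 12-bp CRE-like PWM (consensus TGACGTCATGCA, 0.9
dominant base per column, ≈ 16 bits).

Decoys are column-shuffled copies of the target: identical column multiset
and information content, distinct ids. Shuffles are rejection-sampled to
derangements whose consensus realigns to the parent consensus over at most
⌊m/2⌋ positions at any ungapped offset on either strand. Without this
guard, a permutation can be (near-)cyclic — for a palindromic consensus a
cyclic shift reproduces the motif or its reverse complement — and such a
"decoy" genuinely matches the planted sites, breaking the premise that
decoys are negatives. About 85% of random derangements of the default
target pass the guard, so the decoy distribution is not materially
narrowed.

What the generator does *not* emulate: repeat structure and masking,
fragment-length/pileup shape, replicate structure, peak-width variation,
cooperative or clustered binding, and real genomic background composition.
Passing tests therefore demonstrate correctness of the statistics and set
algebra and recoverability of a clearly planted signal — not performance
on real ChIP-seq data.

## Numerical choices

* Exact arithmetic boundaries: window half-widths and |displacements| are
  integers or exact halves, so the in-window comparison `|d| ≤ half_width`
  is exact in binary floating point.
* Binomial tails use the survival function; Fisher p-values are capped at
  1. Tests verify both against exact rational-arithmetic enumeration
  (n ≤ 12 for all k; all 2×2 tables with margins ≤ 20) to 1e−12.
* `p_raw = 1` whenever k = 0 (no positive evidence), including the
  degenerate empty-negative-set Fisher table.
* Motifs longer than the sequences are skipped with a log entry, not
  fatal; sequences shorter than a motif, or all-N, yield no best site and
  drop out of both k and n.
* With pseudocount 0 a zero probability scores −inf, which simply makes
  windows requiring that base ineligible; the default pseudocount keeps
  all scores finite.
* Determinism: all randomness flows from explicit seeds through
  `numpy.random.default_rng`; identical configs reproduce byte-identical
  output files (asserted in tests).

## Design choices made where the design was open

* Whether the significance filter consults one or both arms is not pinned
  down by the method's description; both peak-set families enter r, so the
  default demands significance in both, with the alternatives one flag away.
* The enrichment tool's exact window schedule and site-score threshold are
  not published; the symmetric growing-window schedule and the 0-bit
  threshold are natural reconstructions, both configurable.
* |A_WT| counts deduplicated (chrom, start, end) coordinates; whether the
  original tooling deduplicated is unstated, and without deduplication the
  denominator would be inflated by exact duplicates while the merged
  numerator counts them once.
* Boundary-crossing windows are dropped rather than clipped to honor the
  uniform-width requirement literally; clipping is available but breaks
  the uniform-L preconditions and is rejected by the enrichment step.

## Problem sizes used in validation

The packaged validation suite runs the complete method end to end on
synthetic experiments of 200 signal peaks in a 1 Mb genome with 20 decoys
(20 seeded replicates), checks the interval algebra against a per-base
brute-force oracle on 1,000 random instances (≤ 3 chromosomes, coordinates
< 1,000, ≤ 30 intervals per set), and bounds r over 1,000 random triples
including adversarial spanning-B draws. These sizes were chosen so the
whole suite completes in about a minute on a single core while every
statistic still operates far from its trivial regimes.

## Known limitations

* Pipeline A's Fisher arm loses power rapidly for small KO peak sets
  (corrected p cannot clear the threshold when n_neg is tiny) — consistent
  with the behavior reported for real small-KO datasets; `filter_mode
  either` is the workaround.
* The locus-subtraction differential approximation ignores signal
  strength; it is a structural stand-in, not a statistical one.
* No significance model is attached to r itself; ranks, not r magnitudes,
  are the interpretable output.
* Exact bit-compatibility with the MEME Suite binaries is a non-goal; the
  enrichment statistics agree with their published definitions, not with
  any particular binary's implementation details.
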