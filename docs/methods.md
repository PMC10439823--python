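# Methods

## Model

`minite` performs library-based (homology) TE annotation by reusing the
seed-and-chain machinery of long-read mapping. The genome plays the role of
the reference; each curated TE plays the role of a noisy read. The method
never computes a base-level alignment: a TE copy is reported as the span of
a colinear cluster of exact k-mer matches, which is what makes the approach
fast and what bounds its boundary resolution (see *Limitations*).

### Minimizer index

Every genome k-mer is 2-bit encoded (A=0, C=1, G=2, T=3) and hashed with an
invertible multiply/xor-shift mixing function masked to 2k bits.
Invertibility guarantees no two k-mers collide, so the hash acts purely as
a pseudo-random total order on k-mers. For each window of w consecutive
bases, all k-mers attaining the window's minimum hash are selected
(ties keep every attaining position — deterministic, and robust to small
shifts); a position selected by several windows is stored once. Codes are
canonical: the stored value is min(hash(forward), hash(reverse
complement)), with the winning orientation recorded, so copies on either
strand are found symmetrically. K-mers containing degenerate IUPAC codes
(N, R, Y, ...) are excluded from candidacy rather than randomised, which
keeps the index deterministic while degenerate bases remain legal input.

Defaults k = 15, w = 20 follow standard long-read seeding practice; on
i.i.d. sequence they retain roughly 2L/(w − k + 2) ≈ 2L/7 positions.
Winnowing is applied to the genome only. The query TE contributes *all* of
its overlapping k-mers: the asymmetry maximises recall per library entry at
negligible cost, because libraries are small relative to genomes.

### Hit chaining

Hits are grouped by (genome sequence, relative strand) and chained by
dynamic programming: hit j can extend hit i iff subject position strictly
increases, query position strictly advances in the strand's direction, the
subject gap is at most `max_gap` and the diagonal drift
|Δsubject − Δquery| is at most `band`. The chain score is the number of
anchors (unit weights — the method clusters hits, it does not score
alignments). The best chain is extracted, its hits are removed, and the DP
repeats, so each hit supports at most one copy; chains with fewer than
`min_chain_hits` anchors are discarded. The chain span, first anchor start
to last anchor end, becomes the annotation.

Parameter defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `k` | 15 bp | k-mer length (index and query) |
| `w` | 20 bp | winnowing window |
| `max_hits_per_te` | 10,000 | cap on raw hits per library entry, truncated in deterministic genomic order *before* chaining so the DP cost stays bounded |
| `band` | 500 bp | diagonal drift tolerance; absorbs indels between copy and consensus |
| `max_gap` | 1,000 bp | maximum anchor gap; separates nearby tandem copies |
| `min_chain_hits` | 5 | noise floor; a 200 bp element carries ≈ 2·200/7 ≈ 57 expected genome minimizers, comfortably above it |
| `iterations` | 2 | search rounds |
| `min_te_length` | 200 bp | final length filter; shorter intervals are likely annotation errors |

`band`, `max_gap` and `min_chain_hits` are exposed on the command line; the
defaults were chosen once from the density argument above, not fitted.

### Merging and iteration

Per round, matches from all library entries are pooled and overlapping
intervals (≥ 1 shared bp) are merged: span = connected-component hull,
support = summed anchor counts, family = family of the best-supported
constituent (ties broken lexicographically — the merged-family rule is a
design choice; only the unmerged case is canonically defined). After each
non-final round the library is augmented with the forward-strand genomic
sequences of the current annotations (deduplicated by locus), and the
fixed genome index is reused — only the library changes between rounds.
Round-r output always covers round-(r−1) output, because every entry of the
smaller library is searched identically in the larger one; coverage is
therefore monotone in the number of iterations. The length filter runs only
after the final round, so short fragments can still seed later discoveries.
The final round's merged, filtered, sorted annotations are reported.

Per-entry searches are independent; with `threads > 1` they run
concurrently but are gathered in library order before merging, so output is
byte-identical at any thread count.

## Masking and comparison

Masking rewrites annotated intervals in place: soft = lowercase (existing
lowercase elsewhere is preserved, so masks compose), hard = 'N'. Both modes
are idempotent and length-preserving.

The comparator reduces two annotation sets to per-sequence interval unions
and reports, in exact integer arithmetic, each union's size and the shared
base pairs in both directions. Against a reference set this yields bp
precision (fraction of predicted bases that are reference) and bp
sensitivity (fraction of reference bases predicted); family labels are
ignored — agreement is purely positional. Empty unions yield fractions of 0
with a warning rather than an error, for batch robustness. Length
histograms (default 200 bp bins) and per-element coverage (best
single-annotation overlap over the element's length, and over the
annotation's own length) support distribution-level comparisons.

## Synthetic benchmark genomes

The simulator emulates the structure that matters to a homology annotator:
a random background (default 100 kb, 40% GC) carrying copies of a few
consensus TEs (default 3 families, 1–4 kb) that are reverse-complemented
with probability 0.5, substituted and indel-mutated per base, optionally
truncated to ≥ 25% of full length, and *inserted* (not substituted) at
positions chosen outside existing copies — or strictly inside one, with the
nesting probability — shifting all previously recorded coordinates, so the
ground truth is exact by construction and each copy's mutation count is
recorded for base-level verification. Everything derives from one seed.

What it does **not** emulate: real TE internal structure (LTRs, target-site
duplications, primer-binding sites), phylogenetic copy bursts,
low-complexity and satellite repeats, GC heterogeneity and assembly gaps.
Passing recovery tests on these genomes demonstrates the mapping machinery
(strand handling, divergence tolerance, boundary accuracy, false-positive
floor) — it does not certify accuracy on real assemblies, where library
completeness dominates performance.

Validation problem sizes were chosen at desk scale: 60–140 kb genomes,
libraries of 1–3 consensus sequences, 8–21 planted copies, 20 replicates
for the iteration-trend measurement. On such genomes the pipeline runs in
seconds; the properties measured (boundary error ≤ k + w, bp
sensitivity/precision ≥ 0.95 at 10% divergence, ≤ 1% false-positive
annotation on repeat-free sequence) are scale-free in the sense that they
depend on per-copy anchor statistics, not genome length.

## Numerical and degenerate-input choices

- Hash ties within a window keep all attaining k-mers; canonical-strand
  ties (possible only for even k) resolve to forward.
- The chain DP breaks score ties toward the earliest chain end and the
  leftmost predecessor; results are fully deterministic.
- A TE shorter than k yields no hits (logged warning); an all-degenerate
  window contributes no minimizers; an empty library yields an empty
  annotation set (warning, not an error).
- Interval arithmetic is 0-based half-open internally and converted to the
  1-based inclusive file convention only at I/O boundaries.

## Known limitations

- Boundaries are anchor positions, not alignment ends: up to ~(k + w) bp
  at each element end can be missed, and diverged element margins lose
  more. At 20% divergence only ~3.5% of 15-mers survive intact, so
  sensitivity degrades sharply and additional rounds mainly re-find
  already-found loci; on simulated 20%-divergence genomes the second round
  is non-decreasing but often neutral. Very diverged families need more
  rounds or a closer library.
- Overlapping and nested insertions are merged into (or split around)
  single intervals; nested elements are not resolved into separate calls.
- Family assignment of merged intervals follows the best-supported
  constituent and can mislabel minority overlaps.
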