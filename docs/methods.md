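# Methods

## Record model and coordinate conventions

All comparison arithmetic runs on 0-based half-open internal coordinates.
A deletion's span covers exactly its deleted bases (the VCF anchor base is
trimmed), so `end - start == svlen`.  An insertion has no span over the
reference; it is given the 1-bp span of its anchor base with the full ALT
(anchor + inserted bases) as its substituted allele.  The 1-bp insertion
span matters: the reference-distance test is a *strict* inequality, and a
zero-length span would make two insertions at the same position fail it at
`refdist = 0`.  Multiallelic records are rejected with an instructive error
rather than split — every similarity formula is defined on a single allele,
and splitting/normalization belongs to upstream tools (`bcftools norm`).
Breakends are recognized and excluded from all comparison streams.

## Streaming: zipper and chunker

Sorted inputs are merge-sorted into one stream (ties keep input order, so
the baseline record precedes the comparison record at equal positions), then
grouped into chunks: a chunk ends when the next start exceeds the running
maximum end plus `chunksize`.  The default `chunksize = max(1000,
refdist + 1)` guarantees that no pair split across chunks could ever pass
the reference-distance check, making chunking a pure performance device;
this is property-tested by comparing chunked benchmarking against a
single-matrix run.  Filtering (size bounds, FILTER status, region
restriction, genotype presence) happens in the chunker, before grouping, so
benchmarking can report filtered comparison calls separately from false
positives.  Default size bounds are 50 bp (the conventional SV definition)
to 50 kb; the upper bound exists to cap haplotype-construction cost and is
a package choice, not a community standard.

## Metric details and numerical choices

* **Reciprocal overlap** uses the maximum *span* as denominator.  Insertion
  spans are expanded by `svlen // 2` both directions before overlap is
  computed (integer floor; the expansion is symmetric so the floor never
  changes which of two calls has the larger span by more than 1 bp).
* **Sequence similarity** is `1 - ed/(|H1| + |H2|)` with `ed` the unit-cost
  edit distance between the pair's local haplotypes.  This normalization is
  kept exactly as stated even though it is generous: two *unrelated*
  equal-length sequences score ≈ 0.5 (not 0), and in fact random DNA scores
  ≈ 0.74 because the expected Levenshtein distance between random
  4-letter strings is only ≈ 0.52 per base.  An alternative
  `1 - 2·ed/(|H1|+|H2|)` normalization is available behind
  `MatchParams(rescale_seqsim=True)`, off by default.
  Identical haplotypes — including the degenerate both-empty case produced
  by two identical deletions — score 1.0 without aligning.
  Edit distance is computed by Biopython's global `PairwiseAligner` with
  match 0 / mismatch −1 / gap −1, whose optimal score equals minus the
  Levenshtein distance; the test suite verifies it against an independent
  quadratic dynamic program on thousands of pairs.
* **Haplotype window**: `[min(S1,S2), max(E1,E2))` with no flanking buffer.
  A consequence worth knowing: deletions are *context-free brittle* — a
  deletion shifted or resized in non-repetitive sequence shares almost no
  haplotype sequence with the original (the two haplotypes reduce to the
  disagreeing bases only), so its seqsim collapses toward 0.  This is
  scientifically defensible: shifted deletions only represent the same
  allele when the surrounding context is repetitive, in which case the
  haplotypes agree and seqsim is high.
* **TruScore** is 100 × the mean of (recovl, sizesim, seqsim).  When
  `pctseq = 0` (sequence-free callsets) seqsim is skipped and the mean runs
  over the two remaining metrics, so such callsets are not penalized.
  Seqsim is also skipped — and excluded from the mean — for pairs that
  already failed a cheaper check: its cost is quadratic in the window and a
  failing pair's exact score can only affect ordering among other failing
  pairs, never the output classification.
* **Breakpoint distances** are reported signed, base minus comp.
* **Genotype match** compares sorted allele indices of one designated
  sample per file, ignoring phase.

## Match assignment

The match matrix is raveled and swept greedily: passing pairs first, by
descending TruScore, ties broken by (base start, comp start) for
determinism.  A pair is emitted only if neither member was consumed;
leftover records become FN (base) / FP (comp).  Sorting passing-before-
failing is required for the chunking-equivalence guarantee — in a
single-matrix run, a high-TruScore *failing* pair (e.g. a distant
near-identical duplicate) must not consume records away from a passing
pair.  Greedy assignment is deliberately not optimal-weight matching; the
exhaustive-enumeration optimum exists only as a test oracle, which the
greedy sweep provably equals when scores are distinct.  Multi-match mode
instead reports each row's and column's best passing partner, letting one
baseline allele absorb several redundant comparison representations.

## Collapse

Within a chunk, clusters form by a position-ordered seed sweep: the most
upstream unconsumed call seeds a cluster and gathers every unconsumed call
whose pairwise match with the seed passes.  Every member therefore directly
matches its cluster's seed, and — because later seeds were compared against
earlier seeds and did not match — re-collapsing the kept output removes
nothing (idempotence, property-tested with the default `keep=first`, whose
representative is exactly the seed).  With `keep=maxqual`/`common` the
representative can differ from the seed and idempotence is not formally
guaranteed; this is a documented limitation.  `--chain` replaces the sweep
with connected components (union-find) over all passing pairs, which is
idempotent for any keep strategy since representatives of different
components never pass-match.

Genotype consolidation sums members' ALT-allele counts per sample, capped
at 2 (diploid saturation; events and lost alleles are counted and reported).
`keep=common` reads "most common" as the highest total ALT-allele count
across samples.  In `--hap` mode a pair whose genotypes cannot coexist in
one individual — any hom-ALT against any ALT, or two phased hets on the
same haplotype — is never a valid match; unphased het pairs are allowed
because they *may* lie on opposite haplotypes.  Missing genotypes are
treated as compatible and logged.

A naive 50%-reciprocal-overlap merge is expressible as
`MatchParams(pctseq=0, pctovl=0.5, refdist=500)` (insertion spans expanded
by half their length as always); it is a parameterization, not a separate
code path.

## Annotation and the tandem-repeat audit

Neighbor counting measures the gap between closest span edges (not starts),
so a 5-kb deletion ending near an insertion is its neighbor; neighborhoods
are transitive proximity groups computed with the chunker rule.
Breakpoint intersection reports one relation per (variant, interval) pair —
containment in either direction for spanning variants, breakpoint hits
otherwise; insertions, being point events, only register breakpoint hits.
The interval index is a small sorted-array structure since no interval-tree
package is available in the environment; queries are O(log n + k) in the
common sorted case.

The tandem-repeat audit consumes *precomputed* (motif, copy-number)
annotations — a TSV sidecar of `(contig, start, locus_id, motif,
copy_diff)` — rather than running TandemRepeatFinder; `read_tr_annotations`
is the seam where a TRF wrapper would plug in.  Within a locus, alleles
sharing a (motif, copy_diff) key beyond the first are redundant.  Auditing
a merged locus against the exact-merge baseline counts `missing` (baseline
keys with no surviving representative: over-merging) and `redundant`
(surviving duplicates: under-merging).  Motifs are keyed literally;
rotated phases of the same motif (ACG vs CGA) count as different motifs —
a known limitation.  Aggregation across loci excludes loci with identical
results in every compared merge, to emphasize the informative ones.

## Synthetic data: what it emulates, what it does not

The generator emulates replicate-callset noise on an idealized genome:
uniform-random contigs, optionally with planted tandem-repeat arrays;
implanted non-overlapping DEL/INS of 100–1000 bp spaced ≥ 3 kb apart so
loci are isolated at default thresholds; perturbations of breakpoint
position (≤ 20 bp), size (≤ 5%), and sequence (1% per-base error) that stay
inside the default benchmarking thresholds *by construction*, plus drop and
novel-call rates; and single-threshold violation arms (shift 600–1000 bp,
doubled size, homopolymer-replaced sequence) that fail exactly one check.
Every perturbation run emits a ledger of expected TP/FN/FP identifiers so
test expectations are computed, not guessed.

Two deliberate asymmetries: (i) within-threshold perturbations apply to
insertions only — by the haplotype-window argument above, any shifted or
resized deletion in random sequence would fail the sequence check, so a
"perturbed but matchable" deletion does not exist outside repeat context;
(ii) the sequence-violation arm replaces the insert with a homopolymer of
its least frequent base (seqsim ≈ 0.625) because a random replacement still
scores ≈ 0.74 under the stated normalization and would *pass* the 0.70
threshold.

The worked tandem-repeat locus plants a 29-bp motif ×10 in the reference
and inserts, for each copy number +2..+5, the identical k-copy sequence at
two anchors 4 motif-lengths (116 bp) apart inside the array — the
left-shift/right-shift alignment ambiguity seen in real repeats.  The two
representations yield literally identical haplotypes (seqsim 1.0) while
alleles of adjacent copy numbers have size similarity ≤ 0.8, so default
collapse merges exactly the redundant pairs.  Eight heterozygous carriers
are spread over 10 samples.

None of this reproduces real genomes: no SNP background, no realistic
repeat landscape, no coverage- or caller-specific error profiles, no
population structure.  A green test establishes that the *engine* honors
its contracts on inputs whose truth is known by construction — not that
any particular biological callset will benchmark at a given accuracy.

## Known limitations

* Arbitrary per-sample FORMAT fields are carried in memory and re-emitted
  only when the writer is given the source header's FORMAT definitions (the
  CLI does this); ad-hoc library writers emit GT only.
* Region restriction filters by start position only; matches are not
  clipped at region edges.
* INV/DUP records are compared by span/size/type (and sequence when
  resolved); no breakpoint-refinement or BND pairing logic exists.
* `keep=maxqual`/`common` collapse is not formally idempotent (above).
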