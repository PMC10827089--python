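# Methods

## Problem and model

Multi-copy repeats (here a *Jockey*-like non-LTR retroelement family at and
around centromeres) make read-level transcription estimates ambiguous: a
short read consistent with several copies cannot be attributed to one locus.
`centrotx` treats the three alignment reporting modes as bounds on
locus-level transcription:

* `best_match` (one placement per read) concentrates all signal but may
  misattribute multi-mapping reads — a lower-bound-style profile. The
  "lower bound" label is heuristic: per locus, best-match counts are not
  mathematically below filtered counts, and no ordering between
  `best_match` and the other modes is asserted or tested.
* `k100` (up to 100 placements per read) over-counts by construction: every
  compatible copy receives the read, so per-locus counts are upper bounds.
* `k100_filtered` retains a k100 alignment iff its reference span fully
  contains at least one single-copy k-mer of the assembly. Containment of a
  unique k-mer implies the read's span covers sequence found nowhere else,
  so retained records are locus-certified. The subset property
  (filtered ⊆ k100) is asserted on every run.

Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
complement; counting is strand-collapsed, windows containing N contribute
nothing, and uniqueness means global count exactly 1 over all contigs.
k-mers are packed into rows of ≤ 31-base base-4 integer parts (one int64
each), so any k ≤ 64 runs through one vectorized path; defaults are k = 21
for PRO-seq and k = 51 for RNA-seq, matched to library insert length.

PRO-seq reads are reduced to their 3′-end base (polymerase position):
+-strand alignment [s, e) → e−1, −-strand → s. Libraries in which read 1
was reverse-complemented before alignment are handled by flipping the
mapped strand before applying the rule (`orientation="read1_revcomp"`).
3′-end extraction precedes counting for PRO-seq; RNA-seq counts use full
spans. Counting uses the ≥ 1 bp overlap rule (a single-base 3′-end record
counts iff the base lies inside the interval); a record overlapping two
copies of the same family on one contig increments the family × contig
matrix cell once. Density normalizes each cell by the total records on
that contig; zero-total contigs get NA, not 0.

CENP-A domains: on each centromeric contig the CEN domain spans first-to-last
peak; elsewhere peaks merge into nonCEN domains at merge distance 0 (only
overlapping or book-ended peaks merge — the most conservative reading of
"peaks alone"). Peaks on centromeric contigs outside the CEN span become
ordinary nonCEN domains. Elements are labeled by ≥ 1 bp overlap with CEN
taking precedence over nonCEN; expression = read count ≥ 2 (configurable).
Matched random controls place fixed-length intervals uniformly over
eligible positions (contigs weighted by eligible-position count), with
rejection-resampling against an exclusion set; excluding CENP-A domains and
centromeric contigs is the default because the controls stand for
"nonCENP-A / nonCEN" background, with a `--no-exclude` flag for the literal
unconstrained behaviour.

## Statistics

`unpaired_ttest` wraps the pooled-variance Student test (default) or Welch;
identical degenerate samples return t = 0, p = 1, while zero pooled
variance with unequal means is an error naming the offending sample.
`fisher_exact_2x2` is two-sided by the "sum of tables no more probable than
the observed" convention (the common exact-test definition; two-sided
conventions differ between tools, so this is fixed and tested against full
hypergeometric enumeration). The Pfaffl relative quantity is
E_target^ΔCt_target / E_ref^ΔCt_ref with ΔCt = Ct(control) − Ct(treated)
and efficiencies required in (1, 2]; with equal efficiencies of 2 and
ΔCt_target = −1, the ratio is 0.5 (a halving of the target). Group
proportion tables report extreme per-copy densities alongside the rest
rather than dropping outliers; no outlier exclusion rule is applied.

## The simulator

The generator emulates, with known ground truth: centromere contigs whose
retroelement island (the copies plus random background spacers) is flanked
by satellite arrays (unit AATAT, 3 kb per flank by default); arm contigs
with copies in random background; one family (consensus 4,500 bp, ORF2 at
[1300, 4200)) with full-length copies and 5′-truncated copies retaining a
uniform 10–70% 3′ suffix — capped below the fraction at which a suffix
would still contain the whole ORF2, so generator truth and the completeness
classifier agree by construction. Copy counts default to the modeled
system's census: five centromere contigs with 2/11/21/21/147 copies (nine
full-length, all on the Y-like contig) and two arms with 127 copies (14
full-length), 329 in all. Each copy is independently diverged by point
substitutions (default 5%/bp); strands are random.

Nascent reads: `depth` (default 10) reads per active copy, uniform 3′-end
positions on the copy's sense strand, read = the `read_length` (default
100) transcript-sense bases ending there, kept entirely inside the copy.
The default active set is the full-length copies overlapping designated
CENP-A regions (islands, plus a random 15% of arm copies); alternatives:
all full-length copies, a random fraction, or an explicit list. Peaks tile
each island (3 per island, first/last flush with the island boundaries so
the reconstructed CEN domain equals the island) and cover each designated
arm copy once; signals are normal draws with CEN mean 20 vs nonCEN mean 2
(≈ 10× separation).

The multi-mapper enumerates *all* placements with ≤ `max_mismatch`
(default 1) substitutions on both strands. Candidates come from a
pigeonhole index (a placement with ≤ m mismatches matches one of m+1
disjoint read chunks exactly; chunk hits are found via sorted rolling
hashes and verified base-by-base), which is exact for substitution-only
alignment — indels are out of scope by design, which keeps both the mapper
and the containment-filter semantics unambiguous. k100 keeps up to 100
placements preferring fewer mismatches (seeded subsample inside the last
stratum); best_match keeps a minimal-mismatch placement with seeded
uniform tie-breaking.

Each stage draws from `default_rng([seed, stage_tag])`, so stages are
independently reproducible; all writers emit deterministically ordered
rows, and same-seed runs are byte-identical.

### What the simulator does not model

Indels and structural variants; sequencing error profiles and base
qualities (a flat substitution error rate is available but off by
default); PCR duplicates and spike-ins; transcription-level heterogeneity
(all active copies share one depth); nested insertions of one element into
another; CUT&Tag read-level noise (peaks are drawn directly). Passing
tests therefore validate the pipeline's logic — bound ordering, filter
semantics, domain algebra, labeling rules — under clean substitution-only
ambiguity, not its robustness to alignment artifacts in real libraries.

## Numerical and design choices

* Coordinates 0-based half-open everywhere; 1-based conversions happen at
  I/O boundaries only.
* Completeness is decided from consensus coverage alone (containment of the
  family ORF2), never from element length.
* N never matches any base: not in probe census, not in k-mer windows, not
  in the mapper's verification.
* Probe census counts genomic loci on both strands (DNA view); max
  mismatch defaults to 0 and is configurable up to 3.
* Containment filtering uses the alignment's full reference span and tests
  each unique-k-mer interval separately (whole-k-mer containment, not
  pooled overlap bases).
* Deterministic output order: (assembly contig order, start, read_id).
* Expression may be computed under any reporting mode; the default is
  best_match, and the per-mode counts are written side by side in
  `labels.tsv` because the grouping is mode-sensitive.
* Unique-k-mer coverage of a diverged copy follows ≈ 1 − (1 − d)^(2k−1)
  (≈ 0.88 of positions at d = 0.05, k = 21): a window is single-copy only
  if it carries a private substitution, so coverage rises with divergence —
  the direction the truncated-vs-full-length comparison exploits.

## Problem sizes

The default configuration builds a ~1 Mb genome (329 copies) and runs the
full pipeline in a few seconds; the test suite uses a ~150 kb desk-scale
configuration for most end-to-end checks, 20 seeded replicates of the
twin-copy experiment at ~10³ reads each, 200 random genomes (up to 100 kb)
for the k-mer oracle sweep, and the full 35,650-table Fisher enumeration.
These sizes were chosen so the whole suite exercises every property at
comfortable desk scale.

## Known limitations

Best-match tie-breaking is a seeded uniform choice, not an aligner's
heuristic; real aligners (soft-clipping, indels, quality-aware scoring)
will differ near copy boundaries. The k100 cap mirrors the 100-placement
reporting convention; families with more than 100 near-identical copies
would be under-reported in the upper bound (a seeded subsample is kept).
MACS2-style peak calling itself is upstream and out of scope — peaks are
ingested, never called. The per-brain nested analysis of replicate imaging
designs is not implemented; per-group summaries suitable for external
nested models are emitted instead.
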