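# centrotx

Repeat-aware quantification of centromere transcription.

Centromeres of many species, including *Drosophila melanogaster*, are built
on islands of retroelements (e.g. the non-LTR *Jockey*-like families)
embedded in simple-satellite arrays. Because these elements exist in many
near-identical copies, short nascent-transcription reads (PRO-seq) and
RNA-seq reads do not map uniquely, and naive counting cannot say *which*
copy is transcribed. `centrotx` implements the standard remedy: bound the
locus-level transcription of every repeat copy from below and above, and
recover an intermediate, locus-certified estimate with single-copy k-mer
filtering. It is aimed at researchers analysing transcription and CENP-A
chromatin over repeat-dense assemblies.

## The method

For one alignment run, three reporting modes are compared:

* **best_match** — one placement per read (a lower-bound-style profile:
  signal is placed somewhere consistent, but multi-mapping reads may be
  attributed to the wrong copy);
* **k100** — up to 100 placements per read (an over-fit upper bound: every
  compatible copy receives the read);
* **k100_filtered** — the k100 set restricted to alignments whose reference
  span fully contains a *single-copy k-mer*: a k-length subsequence whose
  canonical form (min of the k-mer and its reverse complement) occurs
  exactly once among all k-mers of the assembly. Full containment of such a
  k-mer certifies the aligned locus; partial overlap (even k−1 of k bases)
  does not retain the alignment. Defaults: k = 21 for PRO-seq, 51 for
  RNA-seq (matched to library insert size).

For PRO-seq, each read is reduced to its 3′-end base — the position of the
engaged RNA polymerase: a +-strand alignment [s, e) contributes position
e−1, a −-strand alignment contributes s (with the read-1
reverse-complement library convention handled by flipping the mapped
strand first). Per-repeat profiles are summarised as a family × contig
matrix with density(f, c) = reads overlapping family f on contig c divided
by all reads mapping to contig c.

CENP-A occupancy enters as peak calls: the centromeric (CEN) domain of a
centromere contig spans from the first to the last peak; non-centromeric
(nonCEN) domains are merged peak clusters elsewhere. Repeat copies are
labeled CENPA_CEN / CENPA_nonCEN / nonCENPA by ≥ 1 bp overlap (CEN takes
precedence) and called *expressed* when ≥ 2 reads overlap them. Copies are
*full-length* when their consensus coverage contains the family's entire
ORF2 interval, else *truncated* (5′-truncated suffixes, the non-LTR
truncation mode). Matched random control intervals (e.g. 333 × 773 bp) and
the small statistics used alongside (Student/Welch t-test, Fisher's exact
2×2, Pfaffl relative qPCR quantity) are included.

Because real centromere-scale sequencing data cannot ship with a package,
`centrotx` includes a first-class, ground-truthed simulator
(`centrotx.simulate`): synthetic genomes with retroelement islands and
satellite flanks, diverged full-length/truncated copies, nascent reads with
known sources, an exact brute-force multi-mapper (pigeonhole-seeded,
substitution-only), and peak calls — so every claim the pipeline makes can
be checked against known truth.

## Worked example

```python
import centrotx as ct

cfg = ct.small_config(seed=7)      # 3 contigs, 38 copies, desk scale
res = ct.run_pipeline(cfg)

print("copies:", len(res["elements"]),
      "full-length:", sum(e.completeness == "full_length" for e in res["elements"]))
print("active copies:", len(res["truth"].active_ids), "reads:", len(res["reads"]))
for mode, aset in res["alignment_sets"].items():
    print(f"{mode}: {len(aset.alignments)} alignments")
print("CEN domains:", sum(d.klass == "CEN" for d in res["domains"]),
      "nonCEN domains:", sum(d.klass == "nonCEN" for d in res["domains"]))
g = res["groups"].set_index(["association", "completeness"])
print("FL x CENP-A-CEN expressed:", g.loc[("CENPA_CEN", "full_length"), "proportion"])
print("FL x nonCENP-A expressed:", g.loc[("nonCENPA", "full_length"), "proportion"])
```

prints

```
copies: 38 full-length: 7
active copies: 4 reads: 40
best_match: 40 alignments
k100: 40 alignments
k100_filtered: 39 alignments
CEN domains: 2 nonCEN domains: 2
FL x CENP-A-CEN expressed: 1.0
FL x nonCENP-A expressed: 0.0
```

The simulator activated the four full-length copies that overlap CENP-A
regions; the pipeline recovers exactly that contrast: all full-length
CENP-A-associated copies are called expressed, no full-length copy outside
CENP-A chromatin is. One k100 alignment was dropped by the 21-mer
containment filter (its span contained no single-copy 21-mer).

The same stages are available from the shell:

```bash
centrotx simulate --seed 7 --outdir fixtures/
centrotx kmers    --fasta fixtures/genome.fa -k 21 --out unique21.bed
centrotx filter   --aln fixtures/aln_k100.tsv --track unique21.bed --out filtered.tsv
centrotx profile  --aln filtered.tsv --mode k100_filtered --library proseq \
                  --repeats fixtures/repeats.bed --fasta fixtures/genome.fa \
                  --out-matrix density.tsv
centrotx domains  --peaks fixtures/peaks.narrowPeak --fasta fixtures/genome.fa \
                  --cen-contigs cen2,cen3,cen4,cenX,cenY --out domains.bed
centrotx classify --elements fixtures/elements.tsv --domains domains.bed \
                  --aln fixtures/aln_best_match.tsv --threshold 2 --out labels.tsv
centrotx report   --fixtures fixtures/
```

## File formats

* repeat annotation: BED6+2 — contig, start, end, element_id, score
  (ignored), strand, family, `consensus_start:consensus_end`;
* alignments: 7-column TSV — contig, start, end, read_id, mismatches,
  strand, `mate_start:mate_end` or `.`;
* unique-k-mer tracks: BED3 with a `# ... k=21 assembly=<md5>` header;
* peaks: narrowPeak (BED6+4); domains: BED6 with `klass:domain_id` in the
  name field; coverage: bedGraph. All coordinates are 0-based half-open.

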