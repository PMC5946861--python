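# Methods

## The superTranscript model

A superTranscript represents a gene as a single linear sequence containing
every exonic base of the gene exactly once, ordered transcriptionally. The
collection over all genes (the superTranscriptome) serves as a compact
alignment reference: reads from any isoform align contiguously or with
splice junctions that skip unused blocks, and standard gene-level counting
applies unchanged. The assumption underlying the whole construction is that
isoforms of one gene share their exonic sequence, so a union-of-exons
representation loses no sequence, only isoform structure — which is
recovered afterwards at block resolution.

## Coordinate conventions

All intervals are 1-based inclusive (GTF convention). The one exception is
`PslHit`, which stores PSL-native 0-based half-open coordinates verbatim so
PSL files round-trip bit-faithfully; conversion happens only in the
clustering stage. Splice junctions use the skipped-span convention: `start`
is the first skipped base, `end` the last.

## Stage details and numerical policies

### Combine and flatten

Assembled transcripts are attached to reference genes by **exonic** overlap
(≥ 1 bp, same chromosome, compatible strand). Span overlap is deliberately
not used: a gene nested in another gene's intron must not be absorbed.
Strand compatibility treats `.` as wild; antisense overlap never merges
loci, since antisense transcription units are distinct genes. A transcript
bridging k ≥ 2 reference genes unions them into one locus whose id is the
`+`-joined sorted member id list — deterministic and traceable. Gene
flattening merges overlapping **and bookended** exon intervals; the
extracted sequence is identical either way and fewer blocks are simpler
downstream. Flattening conserves the covered base set exactly and is
idempotent (both properties are tested against a per-base mask oracle).

### superTranscript construction

Minus-strand genes are reverse-complemented **as a whole** after
concatenating exons in ascending genomic order, so the output reads in
transcriptional order and downstream read alignment sees the transcribed
strand. Strand `.` genes are emitted in `+` orientation with a logged
warning — a deterministic default for an inherently ambiguous input.
Ambiguity codes are preserved verbatim; genome assembly gaps therefore
surface as runs of `N`, which is what lets the reassembly stage see and
repair them.

### Contig clustering

"Aligns to a gene" is materialised as a three-threshold predicate on PSL
hits, all configurable:

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 0.98 | matches / aligned query span |
| `min_aligned_fraction` | 0.5 | aligned query span / contig length |
| `min_aligned_bases` | 100 | absolute aligned span floor |

The defaults tolerate de novo assembly errors (a 1–2% substitution load)
while excluding paralog cross-matches and incidental short matches; they are
knobs, not constants, because appropriate stringency depends on genome
quality and polymorphism. A contig with passing hits to two or more genes is
removed as a likely false chimera; multiple hits to the *same* gene are fine
(isoforms). Genome evidence takes precedence: a contig matching both the
genome-based and the related-species superTranscriptome is resolved by the
genome. Novel clusters are keyed by the related-species gene id so all
contigs of one novel gene co-assemble into a single superTranscript.

### Reassembly (anchored block merge)

Members of a cluster are merged in a fixed order — backbone first, then
contigs by (length descending, id ascending) — which makes the output
independent of input order. Each member is decomposed against the growing
consensus into co-linear matched segments using a
longest-common-subsequence block matcher; exact blocks separated only by
short equal-length substitution gaps (≤ 10 bp) are fused into near-exact
segments while identity stays ≥ 99%, and segments shorter than `min_anchor`
(default 30 bp, configurable) are discarded because anchors below
read-length scale create spurious joins. Member sequence absent between two
consensus anchors is handled by case:

- consensus gap empty → the member segment is **inserted** there;
- consensus gap is ≥ 50% `N` (an assembly gap) → it is **replaced** by the
  member's real sequence, tagged `inserted` in the block map;
- both gaps near-identical (equal length, ≤ 1% mismatch) → the consensus
  (genome-derived) bases win, the genome being the better arbiter of
  de novo sequencing errors;
- genuinely different segments → both are kept, member's second.

Because members are only ever spliced in relative to existing anchors, the
block graph is a chain and therefore acyclic by construction; no
cycle-breaking policy is ever exercised, and backbone blocks provably retain
their genomic order. A member sharing no anchor with the consensus is
appended at the end as an inserted block (it still occurs contiguously in
the output). On error-free input every member occurs in the output as a
co-linear chain of exact blocks, and a block shared by k members appears
once — both tested properties.

### Blocking and counting

Junctions are aggregated over primary fragments (a span present in both
mates of a pair counts once); `min_support` defaults to 1 because any
observed junction is evidence of isoform structure, but it is exposed since
spurious junctions inflate block counts. Block boundaries are the junction
endpoints; blocks always tile `[1, L]`. Counting follows featureCounts
fragment semantics with primary-only, paired mode: a read pair is one
fragment; a fragment overlapping features of exactly one group is assigned;
two or more groups → `unassigned_ambiguous` (never counted, matching the
default of not counting multi-overlap fragments); none →
`unassigned_no_feature`; secondary/supplementary records →
`unassigned_secondary`. The ledger conserves totals per sample.

## The synthetic worlds

The generator (`supertx.simulate`) emulates the data situation the pipeline
exists for, with all alignments synthesized from known source coordinates
rather than by running aligners, keeping the fixtures hermetic and
byte-reproducible per seed:

- multi-exon genes on both strands (default 10 genes, 2–6 exons of 120–400
  bp, introns 60–300 bp, 40% minus-strand);
- **gap genes**: one exon's genome copy has a 220 bp segment replaced by a
  20 bp `N` run, so the genome encodes 200 bp less than the true gene —
  reads and contigs carry the real sequence (gap genes use a fixed 4-exon
  layout so that the repair contig keeps > 50% of its length alignable and
  both flanks exceed the merge anchor);
- genes whose reference annotation misses the last exon (every third gene),
  which the assembled annotation restores;
- **novel genes** present only in the related species' CDS annotation and
  among the contigs;
- full-length and partial contigs per gene, one **chimeric** contig fusing
  the first halves of two genes, and one random **unmatched** contig;
- paired-end fragments (default 60 per gene per sample, 2 samples, 200 bp
  fragments, 70 bp reads) with 30% of fragments from junction-bearing genes
  using a spliced isoform that skips the second exon.

Contig errors default to zero substitutions so exact-block merging is
directly checkable; a substitution mode exists (`contig_error_rate`) within
the tolerance of the near-exact anchor chaining. Indels, sequencing-error
quality profiles and realistic expression-level variation (e.g. negative
binomial counts) are deliberately not modelled: passing tests therefore
demonstrate the correctness of the combinatorial and coordinate logic on
clean data, not robustness to every artifact of real libraries or
assemblers.

Truth tables record every contig's intended fate, every gap gene's hidden
segment and net length gain, every novel gene's source, and every planted
junction — sufficient to score each stage without hidden state.

## Problem sizes

Tests and the acceptance script run on worlds of 5–30 genes with tens of
contigs and a few thousand fragments — sizes chosen so the whole matrix of
stage checks, oracle comparisons and two full end-to-end runs completes in
well under a minute while still exercising every code path (both strands,
gaps, novel genes, chimeras, partial contigs, spliced reads).

## Known limitations

- The merge is a consensus chain, not a full splice graph: mutually
  exclusive alternative segments are emitted sequentially rather than as
  graph branches, which can slightly lengthen the superTranscript of genes
  with divergent alternative exons.
- Chimera filtering removes genuine read-through or fragmented-reference
  bridging contigs; this is the intended trade-off against annotation
  contamination.
- PSL hits are summarised at whole-hit granularity (matches, spans); the
  per-block structure of a BLAT alignment is not retained.
- BAM is read where pysam supports it, but all outputs are text formats.
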