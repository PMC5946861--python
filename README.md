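# supertx

**supertx** builds a *superTranscriptome* — one sequence per gene containing
all of that gene's exonic sequence in transcriptional order — by combining a
reference genome annotation, a genome-guided assembly annotation
(StringTie-style GTF) and de novo assembled contigs (Trinity-style FASTA),
and then prepares gene-level and block-level fragment counts for
differential expression and differential isoform-usage testing.

It is aimed at RNA-seq analyses of organisms with an *incomplete* genome or
annotation: assembly gaps, missing exons, genes split across annotations, or
whole genes absent from the reference. Counting against the reference alone
underestimates such genes' expression and costs statistical power; folding
assembled sequence into a compact per-gene reference recovers it. Because de
novo assembly is error prone, a contig that matches no known gene is only
admitted as a *novel* gene if it is also found in the coding sequence of a
well-annotated related species.

Unlike pipeline front ends that drive aligners and assemblers themselves,
supertx consumes their standard file outputs (GTF, FASTA, PSL, SAM) and
implements only the bespoke computational stages, so every stage is a
testable library function.

## Method

For gene *g* with transcripts *T(g)*, the flattening step forms the
nonredundant exon set

> E(g) = merge( ∪_{t ∈ T(g)} exons(t) )

where overlapping and bookended intervals are merged, so each exonic base
appears exactly once. The genome-based superTranscript of *g* is the
concatenation of the genomic subsequences of E(g) in ascending genomic
order, reverse-complemented as a whole for minus-strand genes — i.e. exons
in transcriptional order.

The stages are:

1. **combine + flatten** — assembled transcripts are grouped with reference
   genes by exonic overlap (strand-aware; antisense overlap never merges);
   transcripts bridging several reference genes union those genes into one
   locus; each gene is flattened to E(g).
2. **build** — exonic sequence is extracted from the genome and
   concatenated into the genome-based superTranscriptome, with a block map
   recording each segment's genome interval. The same construction applied
   to the related species' CDS annotation yields the related-species
   superTranscriptome.
3. **cluster** — each de novo contig is assigned from its BLAT (PSL)
   alignments: contigs aligning to exactly one genome-based gene are
   *known*; contigs matching no gene but exactly one related-species gene
   are *novel*; contigs matching two or more genes are removed as likely
   false chimeras; contigs matching nothing are filtered out.
4. **merge** — each cluster (a gene's genome-based superTranscript plus its
   contigs) is reassembled into a single superTranscript through a
   deterministic anchored block merge: shared sequence appears once,
   backbone blocks keep genomic order, and contig-only sequence (for
   example, real sequence spanning a genome assembly gap) is inserted at
   its anchored position and tagged `inserted` in the block map.
5. **blocks + count** — splice junctions observed in the read alignments
   (CIGAR `N` spans) cut each superTranscript into contiguous blocks;
   fragments are counted per gene and per block with featureCounts
   semantics (primary alignments only, one count per read pair, ambiguous
   fragments unassigned).

## Worked example

Everything below is self-contained: `make-world` generates a small synthetic
dataset (genome, annotations, contigs, alignments) with a planted assembly
gap, a novel gene, a chimeric contig and a junk contig, plus a ready-made
`data.txt` configuration.

```sh
supertx make-world --seed 1 --outdir demo
supertx run-all --config demo/data.txt
```

The run prints per-stage record counts:

```
INFO supertx.pipeline: stage flatten: flat_genes = 10
INFO supertx.pipeline: stage flatten: flat_bases = 8840
INFO supertx.pipeline: stage cluster: contigs = 18
INFO supertx.pipeline: stage cluster: contigs_known = 15
INFO supertx.pipeline: stage cluster: contigs_novel = 1
INFO supertx.pipeline: stage cluster: contigs_filtered_chimeric = 1
INFO supertx.pipeline: stage cluster: contigs_filtered_unmatched = 1
INFO supertx.pipeline: stage merge: supertranscripts = 11
INFO supertx.pipeline: stage merge: merged_bases = 9781
INFO supertx.pipeline: stage merge: inserted_bases = 961
INFO supertx.pipeline: stage count: fragments_assigned_genes = 1320
```

Reading: the 10 annotated genes flatten to 8,840 exonic bases; 15 of the 18
contigs join known genes, one founds a novel gene (validated by the related
species), one chimera and one junk contig are filtered. Reassembly yields 11
superTranscripts (10 known + 1 novel) totalling 9,781 bases — 961 of them
de novo sequence absent from the genome, including the 200 bp hidden behind
the planted assembly gap. All 1,320 simulated fragments are assigned.

Outputs land in `demo/out/`: `merged_st.fasta` (the superTranscriptome),
`merged_st_blocks.gtf` (block provenance), `blocks.gtf` (junction-derived
blocks), `gene_counts.tsv` and `block_counts.tsv` (+ `.summary` assignment
ledgers, featureCounts layout: expression columns start at column 7). The
count tables drop straight into edgeR/DESeq2 (genes) or DEXSeq (blocks).
Reruns are no-ops unless an input changed (`demo/out/manifest.json` records
input/output hashes).

The same stages are available as library functions
(`supertx.merge_annotations`, `supertx.flatten`,
`supertx.build_genome_supertranscripts`, `supertx.cluster_contigs`,
`supertx.merge_all`, `supertx.collect_junctions`, `supertx.segment_blocks`,
`supertx.count_fragments`) and as per-stage subcommands (`supertx flatten`,
`supertx cluster`, …).

## Limitations

- Contigs cannot scaffold highly fragmented genomes: a contig spanning two
  annotated genes is indistinguishable from a false chimera and is removed.
- Novel genes absent from both the genome and the related species are
  missed by design.
- Differential expression/usage testing itself is out of scope; the count
  tables are prepared for edgeR/DESeq2/DEXSeq.

See `docs/methods.md` for the model, parameter defaults and numerical
policies.
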