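# probemap

Re-annotation of expression-microarray probe sequences against an in-silico
mRNA reference.

## The problem

Expression arrays report transcript abundance through short oligonucleotide
probes (50 nt on Illumina BeadChips), but manufacturer annotation tables age
badly: genome assemblies and gene models move underneath them, probes end up
assigned to withdrawn genes, wrong loci, or untranscribed regions.  Mapping
probes back to the *genome* does not fix this — a large fraction of the
genome is not uniquely mappable with 50 bp sequences, and probes spanning
exon–exon junctions are not even contiguous in genomic sequence.

`probemap` instead maps each probe against an **in-silico mRNA reference**:
for every transcript isoform in a genePred/refGene gene table, the exon
sequences are extracted from the genome and concatenated in coding
orientation.  Junction probes become contiguous, untranscribed sequence is
excluded by construction, and every hit can be projected back to genomic
coordinates through the transcript's exon block map.

## The method

1. **Reference construction** — one spliced sequence per isoform, with a
   bidirectional transcript↔genome coordinate map.
2. **Step-wise alignment** — probes are aligned to the mRNA reference
   allowing 0 mismatches; unaligned probes are retried at 1, 2, 3, 4
   mismatches.  Only probes failing every mRNA tier are aligned to the whole
   genome (both strands) with the same step-wise loop.  The first tier with
   any hit wins and *all* best hits at that tier are kept (stored as SAM).
   The internal aligner is ungapped and exact: pigeonhole seeding (a
   placement with ≤ m mismatches leaves one of m+1 probe segments
   mismatch-free) followed by full-length Hamming verification, so it finds
   precisely the placements a brute-force scan would.
3. **Projection and filtering** — terminal mismatch/indel runs are trimmed;
   mRNA positions are projected to genomic blocks (junction hits become
   multi-block); hits whose orientation contradicts the gene's coding strand
   are discarded.  Genome hits are classified against the gene models
   (exonic > splicing > UTR > intronic > up/downstream within 1 kb of the
   TSS/TES > intergenic) and intergenic/up/downstream hits are excluded.
4. **Consolidation** — a probe is **reliable** when its surviving hits form
   one cluster: pairwise start distance ≤ 25 bp (half a probe length), a
   shared gene symbol, a single direction.  Every probe gets exactly one
   row in the output table, with an explicit status otherwise
   (`ambiguous_distance`, `ambiguous_gene`, `ambiguous_strand`,
   `excluded_region`, `unaligned`, `too_many_hits`).  SNPs from an optional
   VCF that fall inside a probe footprint are annotated, never filtered.
5. **Evaluation** — to compare two annotations on real data: probes are
   called *expressed* when the detection p-value is < 0.01 in ≥ 50% of
   samples; per tool a 2×2 table of expression status × annotation quality
   yields an odds ratio OR = ad/bc with a Woolf CI,
   exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); probe categories (Both / None / InRA
   / InRM / InRepeat) are compared on intensity CV (sd/mean) with two-sided
   Wilcoxon rank-sum tests, subsampling the larger reference group to match
   sizes.

## Worked example

Everything runs at desk scale from the built-in simulator, which generates a
genome, gene models, probes with known truth, and a VCF:

```sh
$ probemap simulate --seed 3 --out sim/
simulated 2 chromosomes, 20 genes, 200 probes -> sim/

$ probemap run --genome sim/genome.fa --genes sim/genes.genepred \
    --probes sim/probes.tsv --vcf sim/snps.vcf --out run/
172/200 probes reliable (192 aligned); outputs in run/
```

192 of 200 probes align (the 8 unalignable probes are random sequences
planted by the simulator); 172 are reliable — the 20 probes planted in
intergenic space align to the genome but are excluded as untranscribed.
`run/annotation.tsv` has one row per probe (status, gene, 1-based
coordinates, region class, mismatch tier, hit count, SNPs, block structure
for junction probes); `run/summary.json` has the counts and histograms;
`run/alignments.sam` and `run/reliable.bed` support external inspection.

The evaluation statistics work directly from contingency counts:

```sh
$ probemap evaluate --expressed-good 12321 --expressed-bad 1227 \
    --notexpressed-good 22615 --notexpressed-bad 8775
{"odds_ratio": 3.8963, "ci_low": 3.6561, "ci_high": 4.1523, "ci_level": 0.95}
```

i.e. a probe rated "good" by this annotation has 3.9× the odds of passing
the expression-detection filter — well-annotated probes are the ones that
measure real signal.

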