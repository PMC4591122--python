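# Methods

## Model and procedure

The package treats probe re-annotation as an exact combinatorial problem,
not a heuristic alignment problem.  A probe placement is an ungapped
alignment of the full probe against an equal-length window of a reference
sequence, scored by Hamming distance; the step-wise search asks, for
m = 0…4 in order, whether any window of the in-silico mRNA set lies within
distance m, and only on total failure repeats the question against the
genome (both strands).  Because each tier is answered exactly, the winning
tier equals the minimum Hamming distance between the probe and the searched
reference set, and the hit list at the winning tier is complete.  This is
what makes the downstream reliability call meaningful: "this probe has one
placement" is a statement about *all* placements, not about the ones a
heuristic happened to find.

Exactness comes from pigeonhole seeding: the probe is split into m+1
contiguous segments (left-aligned, remainder to the leftmost segments); any
placement with ≤ m mismatches must leave at least one segment exact, so
looking up each segment's k-prefix in an exact k-mer index enumerates a
candidate superset, and full-length verification filters it.  The effective
seed length is min(seed_kmer, ⌊L/(m+1)⌋) — 12 down to 10 for 50 nt probes —
and index tables per k are built lazily.  `N` never matches anything,
including another `N`; a segment containing `N` cannot be exact, which is
consistent with `N` counting as a mismatch.

The internal aligner is deliberately substitution-only.  The mismatch tiers
are defined as mismatch counts, and an ungapped search is the largest search
space that can be verified exactly against a sliding-window oracle (the
acceptance suite does exactly that).  Gapped alignments produced by an
external aligner enter through the SAM importer, which reconstructs per-base
operations from an =/X CIGAR or from CIGAR+MD and feeds the same
trim/project/classify/consolidate path.

### Coordinates and projection

Internally everything is 0-based half-open (the genePred convention);
user-facing tables are 1-based inclusive.  Each in-silico transcript stores
a block map in transcript orientation; minus-strand blocks map transcript
positions right-to-left within a block whose `genomic_start` is its leftmost
genomic base.  Projection of a transcript interval is block-wise, returns
ascending genomic order, and conserves total length — both properties are
tested, as is per-position bijectivity.

### Filtering order

For mRNA hits: trim terminal {X,I,D} runs (whole runs, since the goal is an
alignment that starts and ends on a match), reject residues shorter than
25 nt (half a probe; the same reasoning as the 25 bp cluster rule), check
probe-vs-mRNA orientation, project.  For genome hits: trim, orientation
against the coding strand of any overlapped gene (hits in gene-free space
pass this check), then region classification, excluding intergenic,
upstream and downstream placements (flank default 1 kb from TSS/TES) —
untranscribed sequence cannot contribute signal, so keeping such hits would
only manufacture false multi-hits.  Filtering happens before multi-hit
consolidation.  A probe whose every hit is removed by the region or strand
filters is reported `excluded_region`; one whose hits vanish by trimming
alone is reported `unaligned`.

Region precedence is exonic > splicing > UTR5/UTR3 > intronic >
upstream/downstream > intergenic, the conventional gene-annotation order.
`splicing` means an intronic position within 2 bp of an exon boundary.  UTR
calls need a CDS; models with `cdsStart == cdsEnd` degrade gracefully to
`exonic`.  When several models tie at the winning precedence, all their
symbols are kept (sorted, `;`-joined) so the same-gene rule downstream can
use the full set.

### Consolidation

Reliability of a multi-hit probe requires (a) one chromosome and pairwise
hit-start distances ≤ 25 bp, (b) a non-empty shared gene-symbol set, (c) one
direction — checked in that order, so the reported failure status names the
first violated clause.  The 25 bp distance is measured between hit start
coordinates; an any-overlap criterion would be strictly looser than the
half-probe-length reasoning behind the default.  The reported position is
the span of the cluster; the region class is the highest-precedence class
among hits; both the winning tier and the post-trim mismatch count are
reported, since they can differ after trimming.  Alternate-haplotype
contigs (`_hap`/`_alt` name patterns) are dropped at gene-table parse time,
so a probe can never be called ambiguous against its own alt locus.
SNP overlaps (REF-span interval intersection) are annotated, never used to
remove probes — whether a footprint SNP perturbs hybridisation is an
empirical, per-probe question.

### Evaluation statistics

Expression calls: p < 0.01 (strict, the usual convention for detection
p-values) in at least ⌈0.5·n⌉ samples.  CV = sample SD (n−1)/mean, undefined
for zero mean.  Wilcoxon comparisons subsample the larger reference group
uniformly without replacement (seeded) to match sizes, report the rank-sum
W of the first group, and use the exact two-sided null when both groups are
≤ 25 and tie-free, otherwise the normal approximation with continuity and
tie correction.  The odds-ratio CI is the Woolf log-normal interval; zero
cells get the Haldane–Anscombe +0.5 correction with a warning.  The five
categories are made disjoint by peeling off repeat-flagged probes first.
On the published contingency counts the Woolf interval is marginally
narrower than the printed one (3.656–4.152 vs 3.65–4.16), so the point OR
is the stable reproduction surface, not the CI bounds; the acceptance check
therefore compares the OR to two decimals and only requires the CI width to
agree within 10%.

## Synthetic data

The simulator emulates the input battery at desk scale — defaults: 2
chromosomes × 50 kb, 20 multi-exon genes (2–4 exons of 80–250 bp, introns
60–400 bp, half on the minus strand), 200 probes of 50 nt — small enough
that every probe can be verified against the full reference by direct scan,
large enough that every pipeline branch is exercised.  Probe classes:

* **exonic** (70) — exact single-exon transcript substrings, rejection-
  sampled until the sequence occurs exactly once in the genome (either
  strand), so truth is unambiguous;
* **junction** (40) — transcript substrings straddling an exon boundary
  with ≥ 10 nt on each side; introns are at least one probe length, and the
  generator additionally verifies the sequence is beyond Hamming distance 4
  from every genomic window on both strands — these probes *cannot* be
  annotated by a genome-only approach, which is the central property the
  mRNA-first design exists for;
* **mismatched** (8 per k, k = 1…4) — exonic probes with exactly k interior
  substitutions (never terminal, so trimming is a no-op), verified to have
  exactly one transcript window within distance 4, at distance exactly k;
* **snp_bearing** (10) — exonic probes plus 1–2 VCF records planted inside
  the footprint;
* **intronic** (20) — unique intron substrings in coding orientation
  (exercise the genome stage and the strand filter);
* **intergenic** (20) — drawn from a reserved gene-free tail ≥ 2 kb from
  any gene, so the 1 kb flank rule is unambiguous;
* **unmappable** (8) — random sequences verified beyond distance 4 from
  every genomic and transcript window.

All randomness flows from one seed; the same seed yields byte-identical
files.  What the simulator does **not** model: repeat families and
low-complexity sequence (uniqueness is enforced by rejection sampling, so
multi-hit consolidation is exercised by unit fixtures rather than by the
simulator), empirical base composition, overlapping isoforms, and
assembly artefacts.  Passing the truth-recovery suite therefore shows the
machinery is exact on unambiguous inputs; it does not certify behaviour on
repeat-rich real genomes, where the multi-hit statuses carry the load.

## Numerical and design choices

* Hit lists are sorted (ref_id, offset, strand); reruns are byte-identical.
* A per-probe hit cap (default 10 000) marks pathological low-complexity
  probes `too_many_hits` rather than silently truncating.
* Duplicate transcript accessions get `_loc2`, `_loc3`, … suffixes; every
  isoform stays its own reference record (no isoform merging).
* Soft-masked genome bases are uppercased and used; no repeat masking
  anywhere — demonstrably mappable probes in repeat-marked regions should
  not be discarded.
* Probe-vs-mRNA orientation defaults to forward-only (the reference is
  already in coding orientation and manifests are mRNA-sense); a `both`
  switch exists because manifests vary.  The genome stage always searches
  both strands.
* Problem sizes in tests and the acceptance script (100 kb of random
  reference, 500/300 probes for oracle comparison; the simulator defaults
  for end-to-end runs) were chosen as the smallest scales at which every
  code path — all tiers, both strands, every probe class — is exercised
  with comfortable margin.

## Known limitations

* The internal aligner does not produce gapped alignments; indel-containing
  hits exist only via SAM import.
* UTR classification is span-based (hit entirely on the UTR side of the
  CDS), not per-base; a hit overlapping both UTR and CDS is `exonic`.
* The k-mer index is a plain hash table built in memory; it is sized for
  transcriptome-scale references, not for repeated whole-mammalian-genome
  re-indexing in one process.
* The evaluation consumes an already-normalised expression matrix;
  normalisation itself is out of scope.
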