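"""Post-alignment projection of probe hits to genomic coordinates.

Three steps are applied to every surviving alignment, in order: terminal
non-matches are trimmed away, transcript-space positions are pushed through
the transcript's coordinate map onto the genome (splitting at exon
junctions), and alignments whose orientation contradicts the gene's coding
strand are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .align import AlignerConfig, ProbeHit
from .refdb import InSilicoTranscript

__all__ = [
    "GenomicBlockSet",
    "trim_terminal",
    "project_to_genome",
    "strand_filter",
    "write_bed12",
]

#: Default minimum residual alignment length after trimming (half of a 50 nt
#: probe, mirroring the half-probe-length uniqueness reasoning); shorter
#: residues are rejected as unreliable.
DEFAULT_MIN_RESIDUAL_LEN = 25


@dataclass(frozen=True)
class GenomicBlockSet:
    """A probe hit expressed as genomic blocks.

    ``blocks`` are ``(genomic_start, length)`` pairs, non-overlapping and in
    ascending genomic order; a junction-spanning hit has one block per exon.
    ``strand`` is the gene's coding strand for mRNA-derived hits and the
    alignment strand for genome hits.  ``tier`` is the winning mismatch
    tier; ``post_trim_mismatches`` counts mismatches surviving the trim.
    """

    probe_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    tier: int
    origin: str  # "mrna" | "genome"
    post_trim_mismatches: int = 0

    def __post_init__(self) -> None:
        prev_end = -1
        for start, length in self.blocks:
            if length <= 0:
                raise ValueError(f"{self.probe_id}: empty genomic block")
            if start < prev_end:
                raise ValueError(f"{self.probe_id}: blocks overlap or are unsorted")
            prev_end = start + length

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][0] + self.blocks[-1][1]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.blocks)


_TRIMMABLE = frozenset("XID")


def trim_terminal(
    hit: ProbeHit, min_len: int | None = None
) -> ProbeHit | None:
    """Trim terminal mismatch/indel runs so the alignment starts and ends on M.

    The whole leading and trailing run of {X, I, D} is removed; the
    reference offset advances by the reference-consuming length (X and D)
    removed at the start.  Returns ``None`` (rejection) when no match
    remains, or when the residual reference-consuming length falls below
    *min_len*.
    """
    ops = hit.ops
    if "M" not in ops:
        return None
    lo = 0
    while ops[lo] in _TRIMMABLE:
        lo += 1
    hi = len(ops)
    while ops[hi - 1] in _TRIMMABLE:
        hi -= 1
    trimmed = ops[lo:hi]
    lead_ref = sum(1 for op in ops[:lo] if op in ("X", "D"))
    aligned = sum(trimmed.count(op) for op in "MXD")
    if min_len is not None and aligned < min_len:
        return None
    if lo == 0 and hi == len(ops):
        return hit
    return replace(
        hit,
        ref_offset=hit.ref_offset + lead_ref,
        ops=trimmed,
        aligned_length=aligned,
    )


def project_to_genome(hit: ProbeHit, tx: InSilicoTranscript) -> GenomicBlockSet:
    """Project a trimmed mRNA hit through the transcript's coordinate map.

    The transcript interval covered by the alignment is converted to one or
    more genomic blocks (ascending genomic order); total block length equals
    the trimmed aligned length.  The reported strand is the gene's coding
    strand.
    """
    if hit.ref_space != "mrna":
        raise ValueError(f"{hit.probe_id}: project_to_genome expects an mRNA hit")
    blocks = tx.project_interval(hit.ref_offset, hit.ref_end)
    return GenomicBlockSet(
        probe_id=hit.probe_id,
        chrom=tx.coord_map[0].chrom,
        strand=tx.strand,
        blocks=tuple(blocks),
        tier=hit.tier,
        origin="mrna",
        post_trim_mismatches=hit.mismatches(),
    )


def genome_hit_blocks(hit: ProbeHit) -> GenomicBlockSet:
    """Wrap a (trimmed) genome hit as a single-block set."""
    if hit.ref_space != "genome":
        raise ValueError(f"{hit.probe_id}: expected a genome hit")
    # I ops consume no reference; the genomic footprint is the ref interval.
    return GenomicBlockSet(
        probe_id=hit.probe_id,
        chrom=hit.ref_id,
        strand=hit.strand,
        blocks=((hit.ref_offset, hit.aligned_length),),
        tier=hit.tier,
        origin="genome",
        post_trim_mismatches=hit.mismatches(),
    )


def strand_filter(
    hit: ProbeHit,
    locus_strands=None,
    config: AlignerConfig | None = None,
) -> bool:
    """Coding-strand consistency: True to keep the hit.

    mRNA hits: kept iff the probe aligned to the configured sense of the
    in-silico mRNA (default forward; with ``align_probe_strand_to_mrna ==
    "both"`` either orientation passes).  Genome hits: *locus_strands* is
    the coding strand (or set of strands) of the gene(s) overlapped; the
    hit is kept iff its alignment strand matches one of them.  Genome hits
    in gene-free space (``locus_strands`` None/empty) pass here — they are
    removed later by region class.
    """
    config = config or AlignerConfig()
    if hit.ref_space == "mrna":
        if config.align_probe_strand_to_mrna == "both":
            return True
        return hit.strand == "+"
    if not locus_strands:
        return True
    if isinstance(locus_strands, str):
        locus_strands = {locus_strands}
    return hit.strand in locus_strands


def write_bed12(blocksets, path, name_suffix: str = "") -> None:
    """Export projected hits as BED12 for genome-browser inspection."""
    with open(path, "w") as fh:
        for bs in blocksets:
            sizes = ",".join(str(length) for _, length in bs.blocks)
            starts = ",".join(str(start - bs.start) for start, _ in bs.blocks)
            fh.write(
                f"{bs.chrom}\t{bs.start}\t{bs.end}\t{bs.probe_id}{name_suffix}\t"
                f"0\t{bs.strand}\t{bs.start}\t{bs.end}\t0\t"
                f"{len(bs.blocks)}\t{sizes}\t{starts}\n"
            )
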