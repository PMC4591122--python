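"""In-silico mRNA reference construction.

Expression-array probes are designed against mRNA, so the mapping reference
here is not the genome but the set of spliced transcript sequences: for each
gene-model isoform the exon sequences are extracted from the genome and
concatenated, in coding orientation, into one "in-silico mRNA".  Each
transcript carries a block-wise coordinate map so that alignment positions on
the mRNA can later be projected back to genomic coordinates.

Coordinates are 0-based half-open internally (the genePred convention);
user-facing output tables are 1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "CoordBlock",
    "InSilicoTranscript",
    "ReferenceDB",
    "GenePredParseError",
    "parse_genepred",
    "build_insilico_mrna",
    "write_reference_fasta",
    "write_coord_map",
    "reverse_complement",
    "open_genome",
]

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

#: Chromosome-name substrings identifying alternate-haplotype / alt-locus
#: contigs; gene models on these are dropped at parse time so probes are
#: never multi-assigned between a primary chromosome and its alt contig.
DEFAULT_ALT_CONTIG_PATTERNS: tuple[str, ...] = ("_hap", "_alt")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenePredParseError(ValueError):
    """Raised for a malformed gene-table row; message names the line number."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript isoform from a genePred/refGene table.

    Exon coordinates are 0-based half-open on the chromosome forward strand,
    in ascending genomic order regardless of the coding strand.  ``cds_start
    == cds_end`` means the model is non-coding (no UTR can be inferred).
    """

    tx_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int = 0
    cds_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.tx_id}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.tx_id}: exon start/end lists differ in length")
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError(f"{self.tx_id}: empty or inverted exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.tx_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tx_start(self) -> int:
        return self.exon_starts[0]

    @property
    def tx_end(self) -> int:
        return self.exon_ends[-1]

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def has_cds(self) -> bool:
        return self.cds_start < self.cds_end

    def exons(self) -> Iterable[tuple[int, int]]:
        return zip(self.exon_starts, self.exon_ends)


class CoordBlock(NamedTuple):
    """One colinear block of the transcript-to-genome coordinate map.

    ``tx_offset`` is the block's start on the transcript; ``genomic_start``
    is the leftmost genomic coordinate of the block.  For minus-strand
    transcripts the mapping inside a block runs right-to-left on the genome.
    """

    tx_offset: int
    chrom: str
    genomic_start: int
    length: int


@dataclass(frozen=True)
class InSilicoTranscript:
    """A spliced transcript sequence plus its bidirectional coordinate map."""

    tx_id: str
    sequence: str
    coord_map: tuple[CoordBlock, ...]
    source: GeneModel

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def strand(self) -> str:
        return self.source.strand

    def to_genomic(self, tx_pos: int) -> int:
        """Genomic position of a single transcript position."""
        for blk in self.coord_map:
            if blk.tx_offset <= tx_pos < blk.tx_offset + blk.length:
                delta = tx_pos - blk.tx_offset
                if self.strand == "+":
                    return blk.genomic_start + delta
                return blk.genomic_start + blk.length - 1 - delta
        raise IndexError(f"transcript position {tx_pos} outside {self.tx_id}")

    def project_interval(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project the transcript interval [start, end) to genomic blocks.

        Returns ``(genomic_start, length)`` pairs in ascending genomic order;
        an interval crossing an exon junction yields one block per exon
        touched.  Total block length always equals ``end - start``.
        """
        if not (0 <= start < end <= len(self.sequence)):
            raise IndexError(
                f"interval [{start},{end}) outside transcript {self.tx_id} "
                f"of length {len(self.sequence)}"
            )
        blocks: list[tuple[int, int]] = []
        for blk in self.coord_map:
            lo = max(start, blk.tx_offset)
            hi = min(end, blk.tx_offset + blk.length)
            if lo >= hi:
                continue
            if self.strand == "+":
                g_lo = blk.genomic_start + (lo - blk.tx_offset)
            else:
                g_lo = blk.genomic_start + blk.length - (hi - blk.tx_offset)
            blocks.append((g_lo, hi - lo))
        blocks.sort()
        return blocks


@dataclass
class ReferenceDB:
    """The mapping reference: in-silico mRNAs keyed by transcript id."""

    transcripts: dict[str, InSilicoTranscript]
    models: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    def sequences(self) -> dict[str, str]:
        """Plain ``tx_id -> sequence`` mapping (aligner input)."""
        return {t.tx_id: t.sequence for t in self.transcripts.values()}


# ---------------------------------------------------------------------------
# genePred parsing
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _detect_bin_column(fields: Sequence[str]) -> bool:
    # refGene dumps carry a leading integer "bin" column; plain genePred does
    # not.  With bin, strand sits in column 3; without, in column 2.
    if len(fields) >= 4 and fields[0].isdigit() and fields[3] in ("+", "-"):
        return True
    return False


def _int_field(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise GenePredParseError(
            f"line {lineno}: non-numeric {what}: {value!r}"
        ) from None


def _int_list(value: str, lineno: int, what: str) -> tuple[int, ...]:
    items = [v for v in value.strip().split(",") if v != ""]
    return tuple(_int_field(v, lineno, what) for v in items)


def parse_genepred(
    path,
    *,
    drop_alt_contigs: Sequence[str] = DEFAULT_ALT_CONTIG_PATTERNS,
) -> list[GeneModel]:
    """Parse a genePred/refGene tab-delimited table into gene models.

    The optional UCSC ``bin`` column is auto-detected from the first data
    row.  The gene symbol is taken from the extended-genePred ``name2``
    column when present, otherwise the transcript name is used.  Duplicate
    transcript accessions (one accession mapped to several loci) are made
    unique by suffixing ``_loc2``, ``_loc3``, ... onto later occurrences.
    Models on alternate-haplotype contigs (chromosome name containing any of
    *drop_alt_contigs*) are dropped.
    """
    models: list[GeneModel] = []
    seen: dict[str, int] = {}
    with _open_text(path) as fh:
        has_bin: bool | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if has_bin is None:
                has_bin = _detect_bin_column(fields)
            if has_bin:
                fields = fields[1:]
            if len(fields) < 10:
                raise GenePredParseError(
                    f"line {lineno}: expected >=10 genePred columns, got {len(fields)}"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            if strand not in ("+", "-"):
                raise GenePredParseError(f"line {lineno}: unknown strand {strand!r}")
            cds_start = _int_field(fields[5], lineno, "cdsStart")
            cds_end = _int_field(fields[6], lineno, "cdsEnd")
            exon_count = _int_field(fields[7], lineno, "exonCount")
            exon_starts = _int_list(fields[8], lineno, "exonStart")
            exon_ends = _int_list(fields[9], lineno, "exonEnd")
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise GenePredParseError(
                    f"line {lineno}: exonCount={exon_count} but "
                    f"{len(exon_starts)} starts / {len(exon_ends)} ends listed"
                )
            if any(pat in chrom for pat in drop_alt_contigs):
                continue
            gene_symbol = fields[11] if len(fields) >= 12 and fields[11] else name
            n = seen.get(name, 0) + 1
            seen[name] = n
            tx_id = name if n == 1 else f"{name}_loc{n}"
            try:
                models.append(
                    GeneModel(
                        tx_id=tx_id,
                        gene_symbol=gene_symbol,
                        chrom=chrom,
                        strand=strand,
                        exon_starts=exon_starts,
                        exon_ends=exon_ends,
                        cds_start=cds_start,
                        cds_end=cds_end,
                    )
                )
            except ValueError as exc:
                raise GenePredParseError(f"line {lineno}: {exc}") from None
    return models


# ---------------------------------------------------------------------------
# genome access and transcript construction
# ---------------------------------------------------------------------------

def open_genome(genome):
    """Normalise a genome argument to a chrom->sequence-like mapping.

    Accepts a FASTA path (opened with :mod:`pyfaidx`, index on demand), an
    already-open ``pyfaidx.Fasta``, or a plain ``dict`` of strings (used by
    the simulator and tests).
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(genome))
    return genome


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    seg = genome[chrom][start:end]
    seq = seg if isinstance(seg, str) else seg.seq
    return seq.upper()


def build_insilico_mrna(models: Iterable[GeneModel], genome) -> ReferenceDB:
    """Build the in-silico mRNA database from gene models and a genome.

    For every model the exon sequences are concatenated in genomic order;
    minus-strand models are then reverse-complemented so the stored sequence
    is 5'->3' in coding orientation.  The coordinate map is stored in
    transcript orientation (block 0 is the transcript's 5' end).
    """
    genome = open_genome(genome)
    transcripts: dict[str, InSilicoTranscript] = {}
    model_index: dict[str, GeneModel] = {}
    for model in models:
        if model.chrom not in genome:
            raise KeyError(f"{model.tx_id}: chromosome {model.chrom!r} not in genome")
        chrom_len = _chrom_length(genome, model.chrom)
        if model.tx_end > chrom_len:
            raise IndexError(
                f"{model.tx_id}: exon end {model.tx_end} exceeds "
                f"{model.chrom} length {chrom_len}"
            )
        pieces = [_fetch(genome, model.chrom, s, e) for s, e in model.exons()]
        concat = "".join(pieces)
        exon_blocks = list(model.exons())
        if model.strand == "+":
            sequence = concat
            ordered = exon_blocks
        else:
            sequence = reverse_complement(concat)
            ordered = exon_blocks[::-1]
        coord_map = []
        offset = 0
        for s, e in ordered:
            coord_map.append(CoordBlock(offset, model.chrom, s, e - s))
            offset += e - s
        tx = InSilicoTranscript(
            tx_id=model.tx_id,
            sequence=sequence,
            coord_map=tuple(coord_map),
            source=model,
        )
        assert len(tx.sequence) == sum(e - s for s, e in model.exons())
        transcripts[model.tx_id] = tx
        model_index[model.tx_id] = model
    return ReferenceDB(transcripts=transcripts, models=model_index)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_reference_fasta(db: ReferenceDB, path) -> None:
    """Write the in-silico mRNAs as multi-FASTA (one record per isoform)."""
    if not db.transcripts:
        raise ValueError("reference database is empty")
    records = [
        SeqRecord(Seq(t.sequence), id=t.tx_id, description="")
        for t in db.transcripts.values()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_coord_map(db: ReferenceDB, path) -> None:
    """Serialise every transcript's coordinate map as a TSV sidecar."""
    with open(path, "w") as fh:
        fh.write(
            "tx_id\tblock\ttranscript_offset\tchrom\tgenomic_start\tlength\tstrand\n"
        )
        for t in db.transcripts.values():
            for i, blk in enumerate(t.coord_map):
                fh.write(
                    f"{t.tx_id}\t{i}\t{blk.tx_offset}\t{blk.chrom}\t"
                    f"{blk.genomic_start}\t{blk.length}\t{t.strand}\n"
                )
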