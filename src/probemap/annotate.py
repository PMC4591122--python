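"""Gene-context classification of genomic probe hits and SNP annotation.

Each projected hit is classified against the gene models overlapping it:
exonic > splicing > UTR > intronic, then upstream/downstream within a
configurable flank (default 1 kb from the transcription start/end site),
else intergenic.  Genome-derived hits falling in intergenic or flank
regions are excluded from the final annotation — such placements are not
transcribed and a probe there cannot report transcript abundance.  SNPs
overlapping a probe footprint are annotated but never cause removal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .project import GenomicBlockSet
from .refdb import GeneModel

__all__ = [
    "RegionClass",
    "AnnotateConfig",
    "SnpOverlap",
    "SnpTable",
    "build_model_index",
    "classify_region",
    "region_filter",
    "annotate_snps",
    "load_snp_table",
]


class RegionClass(str, enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classification precedence (lower wins) when a hit touches several
#: features or gene models.
PRECEDENCE: dict[RegionClass, int] = {
    RegionClass.EXONIC: 0,
    RegionClass.SPLICING: 1,
    RegionClass.UTR5: 2,
    RegionClass.UTR3: 2,
    RegionClass.INTRONIC: 3,
    RegionClass.UPSTREAM: 4,
    RegionClass.DOWNSTREAM: 4,
    RegionClass.INTERGENIC: 5,
}

#: Region classes excluded for genome-derived hits (untranscribed space).
EXCLUDED_CLASSES = frozenset(
    {RegionClass.INTERGENIC, RegionClass.UPSTREAM, RegionClass.DOWNSTREAM}
)


@dataclass
class AnnotateConfig:
    """Region-classification parameters.

    flank_bp
        Distance (bp) from the transcription start/end site within which a
        gene-free hit is still called upstream/downstream (default 1000).
    splice_window_bp
        Intronic positions within this many bp of an exon boundary are
        classed splicing (default 2).
    chrom_aliases
        Extra chromosome-name aliases for VCF lookup; ``chr``-prefix
        variants are always tried.
    """

    flank_bp: int = 1000
    splice_window_bp: int = 2
    chrom_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be > 0")


def build_model_index(
    models: Iterable[GeneModel], flank_bp: int = 1000
) -> dict[str, IntervalTree]:
    """Interval index of gene models per chromosome, flanks included.

    The index intervals are widened by *flank_bp* so flank classification
    can be answered from the same query; classification itself re-measures
    exact distances.
    """
    index: dict[str, IntervalTree] = {}
    for model in models:
        tree = index.setdefault(model.chrom, IntervalTree())
        tree.addi(max(0, model.tx_start - flank_bp), model.tx_end + flank_bp, model)
    return index


def _classify_against_model(
    blocks: GenomicBlockSet, model: GeneModel, config: AnnotateConfig
) -> RegionClass | None:
    """Class of a hit with respect to one gene model; None if out of reach."""
    span_start, span_end = blocks.start, blocks.end
    overlaps_exon = any(
        bs < e and s < bs + bl
        for bs, bl in blocks.blocks
        for s, e in model.exons()
    )
    if overlaps_exon:
        if model.has_cds:
            if span_end <= model.cds_start:
                return RegionClass.UTR5 if model.strand == "+" else RegionClass.UTR3
            if span_start >= model.cds_end:
                return RegionClass.UTR3 if model.strand == "+" else RegionClass.UTR5
        return RegionClass.EXONIC
    if span_start < model.tx_end and span_end > model.tx_start:
        w = config.splice_window_bp
        for s, e in model.exons():
            # interior exon edges only; distance from the hit interval to the edge
            for edge in (s, e):
                if edge in (model.tx_start, model.tx_end):
                    continue
                if span_start - w <= edge <= span_end + w:
                    return RegionClass.SPLICING
        return RegionClass.INTRONIC
    if span_end <= model.tx_start:
        gap = model.tx_start - span_end
        side_5prime = model.strand == "+"
    else:
        gap = span_start - model.tx_end
        side_5prime = model.strand == "-"
    if gap <= config.flank_bp:
        return RegionClass.UPSTREAM if side_5prime else RegionClass.DOWNSTREAM
    return None


def classify_region(
    blocks: GenomicBlockSet,
    model_index: Mapping[str, IntervalTree],
    config: AnnotateConfig | None = None,
) -> tuple[RegionClass, list[str]]:
    """Classify a hit against all overlapping gene models.

    Every model overlapping the hit (flanks included) is classified
    separately; the highest-precedence class wins and the gene symbols of
    all models achieving it are returned, sorted.  With no model in reach
    the hit is intergenic (empty symbol list).
    """
    config = config or AnnotateConfig()
    tree = model_index.get(blocks.chrom)
    best = RegionClass.INTERGENIC
    symbols: set[str] = set()
    if tree is not None:
        for iv in tree.overlap(blocks.start, blocks.end):
            model: GeneModel = iv.data
            cls = _classify_against_model(blocks, model, config)
            if cls is None:
                continue
            if PRECEDENCE[cls] < PRECEDENCE[best]:
                best = cls
                symbols = {model.gene_symbol}
            elif PRECEDENCE[cls] == PRECEDENCE[best] and best != RegionClass.INTERGENIC:
                symbols.add(model.gene_symbol)
    return best, sorted(symbols)


def region_filter(region_class: RegionClass, origin: str = "genome") -> bool:
    """True to keep the hit.

    Genome-derived hits in intergenic/upstream/downstream space are
    discarded; mRNA-derived hits always pass (transcribed by construction).
    """
    if origin == "mrna":
        return True
    return region_class not in EXCLUDED_CLASSES


# ---------------------------------------------------------------------------
# SNP annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpOverlap:
    """A VCF variant whose reference span intersects a probe's footprint."""

    probe_id: str
    snp_id: str
    chrom: str
    position: int  # 1-based, as printed in the VCF
    alleles: tuple[str, ...]


class SnpTable:
    """Per-chromosome interval index over the REF spans of VCF records."""

    def __init__(self) -> None:
        self.trees: dict[str, IntervalTree] = {}
        self.n_records = 0

    def add(self, chrom: str, start0: int, ref: str, alts, snp_id: str) -> None:
        end0 = start0 + max(1, len(ref))
        tree = self.trees.setdefault(chrom, IntervalTree())
        tree.addi(start0, end0, (snp_id, start0, (ref, *map(str, alts or ()))))
        self.n_records += 1

    def query(self, chrom: str, start0: int, end0: int):
        tree = self.trees.get(chrom)
        return [] if tree is None else sorted(
            tree.overlap(start0, end0), key=lambda iv: iv.begin
        )


def load_snp_table(vcf_path, aliases: Mapping[str, str] | None = None) -> SnpTable:
    """Load a (plain or bgzipped) VCF into an interval index.

    Chromosome names are stored both as given and with the ``chr`` prefix
    toggled, plus any explicit *aliases* (vcf name -> genome name), so a
    "chr1"-genome pipeline can consume a "1"-style VCF.
    """
    import pysam

    table = SnpTable()
    aliases = dict(aliases or {})
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            names = {rec.chrom}
            names.add(
                rec.chrom[3:] if rec.chrom.startswith("chr") else "chr" + rec.chrom
            )
            if rec.chrom in aliases:
                names.add(aliases[rec.chrom])
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            for name in names:
                table.add(name, rec.start, rec.ref, rec.alts, snp_id)
            table.n_records -= len(names) - 1  # count the record once
    return table


def annotate_snps(blocks: GenomicBlockSet, snps: SnpTable) -> list[SnpOverlap]:
    """All variants whose REF span intersects any block of the hit.

    Annotation only: probes are never removed for carrying SNPs — whether a
    SNP in the footprint perturbs hybridisation must be tested per probe.
    """
    out: dict[tuple[str, int], SnpOverlap] = {}
    for start, length in blocks.blocks:
        for iv in snps.query(blocks.chrom, start, start + length):
            snp_id, pos0, alleles = iv.data
            out[(snp_id, pos0)] = SnpOverlap(
                probe_id=blocks.probe_id,
                snp_id=snp_id,
                chrom=blocks.chrom,
                position=pos0 + 1,
                alleles=tuple(alleles),
            )
    return sorted(out.values(), key=lambda s: (s.position, s.snp_id))
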