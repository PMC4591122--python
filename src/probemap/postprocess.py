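"""Multi-hit consolidation and the final per-probe annotation table.

A probe is *reliable* when its surviving alignments form a single genomic
cluster: every pair of hits no more than 25 bp apart (half an Illumina probe
length — the default multi-hit distance), all assignable to the same gene,
and all aligned in the same direction.  Everything else is reported with an
explicit failure status so every input probe appears exactly once in the
output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotate import PRECEDENCE, RegionClass, SnpOverlap
from .project import GenomicBlockSet

__all__ = [
    "PostprocessConfig",
    "AnnotatedHit",
    "ProbeAnnotation",
    "consolidate",
    "write_annotation_table",
    "read_annotation_table",
    "summarize",
    "TABLE_COLUMNS",
]

STATUSES = (
    "reliable",
    "ambiguous_distance",
    "ambiguous_gene",
    "ambiguous_strand",
    "excluded_region",
    "unaligned",
    "too_many_hits",
)


@dataclass
class PostprocessConfig:
    """Consolidation parameters (defaults are the Illumina-array defaults)."""

    max_hit_distance_bp: int = 25
    require_same_gene: bool = True
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.max_hit_distance_bp < 0:
            raise ValueError("max_hit_distance_bp must be >= 0")


@dataclass
class AnnotatedHit:
    """A projected hit together with its classification and SNP overlaps."""

    blocks: GenomicBlockSet
    region_class: RegionClass
    gene_symbols: tuple[str, ...] = ()
    snps: tuple[SnpOverlap, ...] = ()


@dataclass
class ProbeAnnotation:
    """One row of the final annotation table (one per input probe)."""

    probe_id: str
    status: str
    gene_symbol: str = ""
    chrom: str = ""
    start: int | None = None  # 0-based internally; written 1-based
    end: int | None = None
    strand: str = ""
    region_class: str = ""
    n_hits: int = 0
    tier: int | None = None
    post_trim_mismatches: int | None = None
    snp_count: int = 0
    snp_positions: str = ""
    blocks: str = ""  # "start:len,start:len" (0-based starts)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def _blocks_str(bs: GenomicBlockSet) -> str:
    return ",".join(f"{start}:{length}" for start, length in bs.blocks)


def consolidate(
    probe_id: str,
    hits: Sequence[AnnotatedHit],
    config: PostprocessConfig | None = None,
    empty_status: str = "unaligned",
) -> ProbeAnnotation:
    """Collapse a probe's surviving hits into one annotation row.

    With no surviving hit, *empty_status* (recorded upstream: unaligned,
    excluded_region or too_many_hits) is reported.  A single hit is
    reliable.  Multiple hits are reliable only when (a) all on one
    chromosome with start coordinates within ``max_hit_distance_bp`` of
    each other, (b) sharing at least one gene symbol, and (c) sharing
    strand; the reported position is the span of the cluster and the gene
    symbol is the shared set.
    """
    config = config or PostprocessConfig()
    if not hits:
        return ProbeAnnotation(probe_id=probe_id, status=empty_status)

    status = "reliable"
    chroms = {h.blocks.chrom for h in hits}
    if len(chroms) > 1:
        status = "ambiguous_distance"
    else:
        starts = [h.blocks.start for h in hits]
        if max(starts) - min(starts) > config.max_hit_distance_bp:
            status = "ambiguous_distance"
    shared: set[str] = set(hits[0].gene_symbols)
    for h in hits[1:]:
        shared &= set(h.gene_symbols)
    if status == "reliable" and config.require_same_gene and len(hits) > 1:
        if not shared:
            status = "ambiguous_gene"
    if status == "reliable" and config.require_same_strand:
        if len({h.blocks.strand for h in hits}) > 1:
            status = "ambiguous_strand"

    rep = min(hits, key=lambda h: (h.blocks.chrom, h.blocks.start))
    if len(hits) == 1:
        genes = rep.gene_symbols
    else:
        genes = tuple(sorted(shared)) if shared else ()
    best_class = min(
        (h.region_class for h in hits), key=lambda c: PRECEDENCE[c]
    )
    snps = sorted(
        {(s.position, s.snp_id) for h in hits for s in h.snps}
    )
    if status != "reliable":
        return ProbeAnnotation(
            probe_id=probe_id,
            status=status,
            n_hits=len(hits),
            tier=rep.blocks.tier,
            post_trim_mismatches=min(h.blocks.post_trim_mismatches for h in hits),
        )
    start = min(h.blocks.start for h in hits)
    end = max(h.blocks.end for h in hits)
    return ProbeAnnotation(
        probe_id=probe_id,
        status="reliable",
        gene_symbol=";".join(genes),
        chrom=rep.blocks.chrom,
        start=start,
        end=end,
        strand=rep.blocks.strand,
        region_class=best_class.value,
        n_hits=len(hits),
        tier=rep.blocks.tier,
        post_trim_mismatches=min(h.blocks.post_trim_mismatches for h in hits),
        snp_count=len(snps),
        snp_positions=",".join(str(pos) for pos, _ in snps),
        blocks=_blocks_str(rep.blocks),
    )


TABLE_COLUMNS = [
    "probe_id",
    "status",
    "gene_symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "region_class",
    "n_hits",
    "tier",
    "post_trim_mismatches",
    "snp_count",
    "snp_positions",
    "blocks",
]


def write_annotation_table(annotations: Iterable[ProbeAnnotation], path) -> None:
    """Write the annotation table as TSV, rows sorted by probe id.

    Genomic ``start``/``end`` are converted from the internal 0-based
    half-open convention to 1-based inclusive; ``blocks`` keeps 0-based
    starts (browser-style block notation).
    """
    rows = []
    for a in sorted(annotations, key=lambda a: a.probe_id):
        rows.append(
            {
                "probe_id": a.probe_id,
                "status": a.status,
                "gene_symbol": a.gene_symbol,
                "chrom": a.chrom,
                "start": "" if a.start is None else a.start + 1,
                "end": "" if a.end is None else a.end,
                "strand": a.strand,
                "region_class": a.region_class,
                "n_hits": a.n_hits,
                "tier": "" if a.tier is None else a.tier,
                "post_trim_mismatches": (
                    "" if a.post_trim_mismatches is None else a.post_trim_mismatches
                ),
                "snp_count": a.snp_count,
                "snp_positions": a.snp_positions,
                "blocks": a.blocks,
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation table written by :func:`write_annotation_table`."""
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})


def summarize(annotations: Sequence[ProbeAnnotation]) -> dict:
    """Run summary: counts per step plus tier / hits / SNP histograms.

    ``aligned`` counts probes with at least one raw alignment (everything
    except status ``unaligned``); ``reliable`` are the probes surviving all
    filters.  Histograms are over reliable probes.
    """
    reliable = [a for a in annotations if a.status == "reliable"]
    by_status: dict[str, int] = {}
    for a in annotations:
        by_status[a.status] = by_status.get(a.status, 0) + 1

    def _hist(values) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in values:
            out[v] = out.get(v, 0) + 1
        return dict(sorted(out.items()))

    return {
        "total": len(annotations),
        "aligned": sum(1 for a in annotations if a.status != "unaligned"),
        "reliable": len(reliable),
        "reliable_no_mismatch": sum(1 for a in reliable if a.tier == 0),
        "reliable_single_hit": sum(1 for a in reliable if a.n_hits == 1),
        "by_status": by_status,
        "tier_histogram": _hist(a.tier for a in reliable),
        "hits_histogram": _hist(a.n_hits for a in reliable),
        "snp_histogram": _hist(a.snp_count for a in reliable),
    }
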