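"""End-to-end pipeline orchestration.

Runs the full re-annotation flow — reference construction, step-wise
alignment, projection and filtering, region classification, SNP annotation,
multi-hit consolidation — and writes the annotation table, a SAM of all
alignments, a machine-readable summary and a log.  Execution is
single-process and deterministic: rerunning on the same inputs produces
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import (
    AlignerConfig,
    KmerIndex,
    Probe,
    align_stepwise,
    read_probes,
    write_sam,
)
from .annotate import (
    AnnotateConfig,
    SnpTable,
    annotate_snps,
    build_model_index,
    classify_region,
    load_snp_table,
    region_filter,
)
from .evaluate import EvalConfig
from .postprocess import (
    AnnotatedHit,
    PostprocessConfig,
    ProbeAnnotation,
    consolidate,
    summarize,
    write_annotation_table,
)
from .project import (
    DEFAULT_MIN_RESIDUAL_LEN,
    genome_hit_blocks,
    project_to_genome,
    strand_filter,
    trim_terminal,
    write_bed12,
)
from .refdb import (
    build_insilico_mrna,
    open_genome,
    parse_genepred,
    write_coord_map,
    write_reference_fasta,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "annotate_results"]

logger = logging.getLogger("probemap")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the error message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Aggregate configuration of every pipeline stage.

    The defaults reproduce the standard Illumina-array settings: at most 4
    mismatches, 25 bp multi-hit distance, 1 kb up/downstream flank,
    detection p < 0.01 in at least 50% of samples.
    """

    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)
    min_residual_len: int = DEFAULT_MIN_RESIDUAL_LEN

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from a YAML file of section -> {key: value}; unknown keys are errors."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        sections = {
            "aligner": cfg.aligner,
            "annotate": cfg.annotate,
            "postprocess": cfg.postprocess,
            "evaluate": cfg.evaluate,
        }
        for section, values in data.items():
            if section == "min_residual_len":
                cfg.min_residual_len = int(values)
                continue
            if section not in sections:
                raise ValueError(f"unknown config section {section!r}")
            target = sections[section]
            known = {f.name for f in dataclasses.fields(target)}
            for key, value in (values or {}).items():
                if key not in known:
                    raise ValueError(f"unknown config key {section}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def annotate_results(
    results,
    db,
    model_index,
    config: PipelineConfig,
    snp_table: SnpTable | None = None,
) -> list[ProbeAnnotation]:
    """Project, filter, classify and consolidate step-wise alignment results.

    The shared back half of the pipeline, also usable on hits imported from
    an external SAM (wrapped in ``StepwiseResult`` objects).  Probes whose
    every hit is removed by the region or strand filters are reported as
    ``excluded_region``; probes losing every hit to trimming alone come out
    ``unaligned``.
    """
    annotations = []
    for res in results:
        if res.capped:
            annotations.append(
                ProbeAnnotation(probe_id=res.probe_id, status="too_many_hits")
            )
            continue
        if not res.hits:
            annotations.append(
                ProbeAnnotation(probe_id=res.probe_id, status="unaligned")
            )
            continue
        kept: list[AnnotatedHit] = []
        any_filtered = False
        for hit in res.hits:
            trimmed = trim_terminal(hit, min_len=config.min_residual_len)
            if trimmed is None:
                continue
            if trimmed.ref_space == "mrna":
                if not strand_filter(trimmed, None, config.aligner):
                    any_filtered = True
                    continue
                tx = db.transcripts[trimmed.ref_id]
                blocks = project_to_genome(trimmed, tx)
            else:
                blocks = genome_hit_blocks(trimmed)
            cls, genes = classify_region(blocks, model_index, config.annotate)
            if blocks.origin == "genome":
                tree = model_index.get(blocks.chrom)
                strands = set()
                if tree is not None:
                    for iv in tree.overlap(blocks.start, blocks.end):
                        model = iv.data
                        if blocks.start < model.tx_end and blocks.end > model.tx_start:
                            strands.add(model.strand)
                if not strand_filter(trimmed, strands, config.aligner):
                    any_filtered = True
                    continue
                if not region_filter(cls, origin="genome"):
                    any_filtered = True
                    continue
            snps = (
                tuple(annotate_snps(blocks, snp_table)) if snp_table is not None else ()
            )
            kept.append(
                AnnotatedHit(
                    blocks=blocks,
                    region_class=cls,
                    gene_symbols=tuple(genes),
                    snps=snps,
                )
            )
        empty_status = "excluded_region" if any_filtered else "unaligned"
        annotations.append(
            consolidate(res.probe_id, kept, config.postprocess, empty_status)
        )
    return annotations


def run_pipeline(
    genome_path,
    gene_table_path,
    probes_path,
    vcf_path=None,
    config: PipelineConfig | None = None,
    outdir=None,
) -> tuple[list[ProbeAnnotation], dict]:
    """Run the full re-annotation pipeline; returns (annotations, summary).

    With *outdir* set, writes ``annotation.tsv``, ``summary.json``,
    ``alignments.sam``, ``reference.fa`` + ``reference.coordmap.tsv``,
    ``reliable.bed`` and ``pipeline.log``.
    """
    config = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    try:
        logger.info("probemap %s, config %s", __version__, config.digest())
        for label, p in (
            ("genome", genome_path),
            ("genes", gene_table_path),
            ("probes", probes_path),
            ("vcf", vcf_path),
        ):
            if p is not None:
                try:
                    digest = _file_checksum(p)
                except OSError as exc:
                    raise PipelineError("refdb", f"cannot read {label}: {exc}") from exc
                logger.info("input %s: %s md5=%s", label, p, digest)

        try:
            models = parse_genepred(gene_table_path)
            genome = open_genome(genome_path)
            db = build_insilico_mrna(models, genome)
        except Exception as exc:
            raise PipelineError("refdb", str(exc)) from exc

        try:
            probes = read_probes(probes_path)
        except Exception as exc:
            raise PipelineError("input", str(exc)) from exc

        try:
            mrna_refs = db.sequences()
            genome_refs = {
                c: (genome[c] if isinstance(genome[c], str) else str(genome[c][:]))
                .upper()
                for c in genome.keys()
            }
            mrna_index = (
                KmerIndex(mrna_refs, k=config.aligner.seed_kmer) if mrna_refs else None
            )
            genome_index = KmerIndex(genome_refs, k=config.aligner.seed_kmer)
            results = [
                align_stepwise(
                    probe,
                    mrna_refs,
                    genome_refs,
                    config.aligner,
                    mrna_index=mrna_index,
                    genome_index=genome_index,
                )
                for probe in probes
            ]
        except Exception as exc:
            raise PipelineError("align", str(exc)) from exc

        try:
            snp_table = load_snp_table(
                vcf_path, config.annotate.chrom_aliases
            ) if vcf_path is not None else None
        except Exception as exc:
            raise PipelineError("snp", str(exc)) from exc

        try:
            model_index = build_model_index(models, config.annotate.flank_bp)
            annotations = annotate_results(
                results, db, model_index, config, snp_table
            )
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc

        summary = summarize(annotations)
        summary["config_digest"] = config.digest()
        logger.info("summary: %s", json.dumps(summary["by_status"]))

        if out is not None:
            try:
                write_reference_fasta(db, out / "reference.fa")
                write_coord_map(db, out / "reference.coordmap.tsv")
                all_refs = {**mrna_refs, **genome_refs}
                write_sam(
                    results,
                    all_refs,
                    out / "alignments.sam",
                    probes={p.probe_id: p.sequence for p in probes},
                )
                write_annotation_table(annotations, out / "annotation.tsv")
                with open(out / "summary.json", "w") as fh:
                    json.dump(summary, fh, indent=2, sort_keys=True)
                _write_reliable_bed(annotations, out / "reliable.bed")
            except Exception as exc:
                raise PipelineError("output", str(exc)) from exc
        return annotations, summary
    finally:
        if out is not None:
            logger.removeHandler(handler)
            handler.close()


def _write_reliable_bed(annotations, path) -> None:
    from .project import GenomicBlockSet

    blocksets = []
    for a in annotations:
        if a.status != "reliable" or not a.blocks:
            continue
        blocks = tuple(
            (int(s), int(l))
            for s, l in (b.split(":") for b in a.blocks.split(","))
        )
        blocksets.append(
            GenomicBlockSet(
                probe_id=a.probe_id,
                chrom=a.chrom,
                strand=a.strand,
                blocks=blocks,
                tier=a.tier or 0,
                origin="mrna",
            )
        )
    write_bed12(blocksets, path)
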