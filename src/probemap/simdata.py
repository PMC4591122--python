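"""Ground-truth synthetic data for end-to-end pipeline testing.

Emulates the inputs a real re-annotation run consumes — a multi-chromosome
genome, multi-exon gene models on both strands, a probe manifest, and a VCF
of SNPs — at desk scale, with a truth table recording where every probe came
from.  Probe classes cover the pipeline's decision space: exact exonic
probes, exon-junction probes (contiguous on the mRNA but not on the genome —
the mappability case the mRNA-first strategy exists for), intronic and
intergenic probes (genome-stage behaviour), probes with k planted mismatches
(tier recovery), SNP-bearing probes, and unmappable random sequences.

Every probe is verified against the genome/transcript windows by a direct
sliding-window Hamming scan and re-sampled until its truth is unambiguous
(unique exact placement; planted-mismatch probes have exactly one window
within the alignable distance).  Real repeat structure is deliberately
absent.  All randomness derives from ``SimConfig.seed``; the same seed
yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import Probe
from .refdb import GeneModel, ReferenceDB, build_insilico_mrna, reverse_complement

__all__ = ["SimConfig", "SimResult", "simulate", "window_distances", "min_distance"]

_MAX_ATTEMPTS = 500


@dataclass
class SimConfig:
    """Synthetic-data parameters (defaults: 2 x 50 kb genome, 20 genes, 200 probes)."""

    n_chroms: int = 2
    chrom_length: int = 50_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (60, 400)
    minus_strand_fraction: float = 0.5
    n_exonic: int = 70
    n_junction: int = 40
    n_intronic: int = 20
    n_intergenic: int = 20
    n_mismatched: dict[int, int] = field(
        default_factory=lambda: {1: 8, 2: 8, 3: 8, 4: 8}
    )
    n_snp_bearing: int = 10
    n_unmappable: int = 8
    probe_length: int = 50
    gc_content: float = 0.5
    max_mismatches: int = 4  # alignability horizon used in verification scans
    #: gene-free bases reserved at each chromosome end for intergenic probes
    gene_free_tail: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_exonic, self.n_junction, self.n_intronic, self.n_intergenic,
            self.n_snp_bearing, self.n_unmappable, *self.n_mismatched.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("probe counts must be >= 0")
        if self.probe_length < self.max_mismatches + 1:
            raise ValueError("probe_length too short for the mismatch horizon")
        if self.intron_length[0] < self.probe_length:
            raise ValueError(
                "introns must be at least one probe length so junction probes "
                "cannot be matched contiguously on the genome"
            )
        if any(k < 1 for k in self.n_mismatched):
            raise ValueError("planted mismatch counts must be >= 1")

    @property
    def total_probes(self) -> int:
        return (
            self.n_exonic + self.n_junction + self.n_intronic + self.n_intergenic
            + self.n_snp_bearing + self.n_unmappable + sum(self.n_mismatched.values())
        )


@dataclass
class SimResult:
    """In-memory simulation output plus paths of any files written."""

    genome: dict[str, str]
    models: list[GeneModel]
    db: ReferenceDB
    probes: list[Probe]
    snps: list[tuple[str, int, str, str, str]]  # (chrom, pos0, id, ref, alt)
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# verification scans
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def window_distances(probe: str, ref: str) -> np.ndarray:
    """Hamming distance of *probe* to every length-matched window of *ref*.

    ``N`` on either side counts as a mismatch.  Returns an empty array when
    the reference is shorter than the probe.
    """
    L = len(probe)
    if len(ref) < L:
        return np.zeros(0, dtype=np.int64)
    p = _encode(probe)
    r = _encode(ref)
    windows = np.lib.stride_tricks.sliding_window_view(r, L)
    n = ord("N")
    mism = (windows != p) | (windows == n) | (p == n)
    return mism.sum(axis=1)


def min_distance(
    probe: str, refs: Iterable[str], both_strands: bool = False
) -> int:
    """Minimum Hamming distance of *probe* to any window of any reference."""
    best = len(probe) + 1
    queries = [probe, reverse_complement(probe)] if both_strands else [probe]
    for ref in refs:
        for q in queries:
            d = window_distances(q, ref)
            if d.size:
                best = min(best, int(d.min()))
    return best


def _count_exact(pattern: str, texts: Iterable[str]) -> int:
    """Overlapping exact occurrences of *pattern* across *texts*."""
    n = 0
    for text in texts:
        start = text.find(pattern)
        while start != -1:
            n += 1
            start = text.find(pattern, start + 1)
    return n


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def _random_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    at = (1.0 - cfg.gc_content) / 2.0
    gc = cfg.gc_content / 2.0
    bases = np.array(list("ACGT"))
    probs = [at, gc, gc, at]
    return {
        f"chr{i + 1}": "".join(
            rng.choice(bases, size=cfg.chrom_length, p=probs)
        )
        for i in range(cfg.n_chroms)
    }


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    max_span = (
        cfg.exons_per_gene[1] * cfg.exon_length[1]
        + (cfg.exons_per_gene[1] - 1) * cfg.intron_length[1]
    )
    models = []
    idx = 0
    for c, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        zone = cfg.chrom_length - cfg.gene_free_tail
        slot = zone // n_here
        margin = 200
        if slot < max_span + 2 * margin:
            raise ValueError(
                f"infeasible config: gene span up to {max_span} bp does not fit "
                f"a {slot} bp slot on a {cfg.chrom_length} bp chromosome"
            )
        for g in range(n_here):
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            exon_lens = rng.integers(
                cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex
            )
            intron_lens = rng.integers(
                cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(0, n_ex - 1)
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            slot_start = g * slot
            start = slot_start + int(
                rng.integers(margin, slot - span - margin + 1)
            )
            starts, ends = [], []
            pos = start
            for i in range(n_ex):
                starts.append(pos)
                pos += int(exon_lens[i])
                ends.append(pos)
                if i < n_ex - 1:
                    pos += int(intron_lens[i])
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            idx += 1
            models.append(
                GeneModel(
                    tx_id=f"TX{idx:03d}",
                    gene_symbol=f"GENE{idx:03d}",
                    chrom=f"chr{c + 1}",
                    strand=strand,
                    exon_starts=tuple(starts),
                    exon_ends=tuple(ends),
                    cds_start=start,
                    cds_end=ends[-1],
                )
            )
    return models


# ---------------------------------------------------------------------------
# probe generation
# ---------------------------------------------------------------------------

class _Sampler:
    """Shared state for rejection-sampled probe generation."""

    def __init__(self, cfg: SimConfig, rng, genome, models, db):
        self.cfg = cfg
        self.rng = rng
        self.genome = genome
        self.models = models
        self.db = db
        self.chrom_seqs = list(genome.values())
        self.tx_seqs = [t.sequence for t in db.transcripts.values()]

    def unique_in_genome(self, seq: str) -> bool:
        return (
            _count_exact(seq, self.chrom_seqs)
            + _count_exact(reverse_complement(seq), self.chrom_seqs)
        ) == 1

    def absent_from_genome(self, seq: str) -> bool:
        return (
            _count_exact(seq, self.chrom_seqs)
            + _count_exact(reverse_complement(seq), self.chrom_seqs)
        ) == 0

    def _attempts(self, what: str):
        for _ in range(_MAX_ATTEMPTS):
            yield None
        raise RuntimeError(
            f"could not generate a {what} probe in {_MAX_ATTEMPTS} attempts; "
            "the configuration is too constrained"
        )

    # -- per-class generators ------------------------------------------------

    def exonic(self):
        """A unique exact substring of one exon, in coding orientation."""
        cfg, rng = self.cfg, self.rng
        for _ in self._attempts("exonic"):
            model = self.models[int(rng.integers(len(self.models)))]
            exon_ids = [
                i for i, (s, e) in enumerate(model.exons()) if e - s >= cfg.probe_length
            ]
            if not exon_ids:
                continue
            i = exon_ids[int(rng.integers(len(exon_ids)))]
            s, e = model.exon_starts[i], model.exon_ends[i]
            p = int(rng.integers(s, e - cfg.probe_length + 1))
            gseq = self.genome[model.chrom][p : p + cfg.probe_length]
            seq = reverse_complement(gseq) if model.strand == "-" else gseq
            if self.unique_in_genome(seq):
                return seq, model, ((p, cfg.probe_length),)

    def junction(self):
        """A probe straddling an exon junction, >=10 nt on each side."""
        cfg, rng = self.cfg, self.rng
        L = cfg.probe_length
        multi = [m for m in self.models if m.exon_count >= 2]
        for _ in self._attempts("junction"):
            model = multi[int(rng.integers(len(multi)))]
            tx = self.db.transcripts[model.tx_id]
            j = int(rng.integers(1, len(tx.coord_map)))
            boundary = tx.coord_map[j].tx_offset
            left = int(rng.integers(10, L - 10 + 1))
            t0 = boundary - left
            if t0 < 0 or t0 + L > len(tx.sequence):
                continue
            seq = tx.sequence[t0 : t0 + L]
            if not self.absent_from_genome(seq):
                continue
            if _count_exact(seq, self.tx_seqs) != 1:
                continue
            # the defining property: not alignable to the genome at any tier
            if min_distance(seq, self.chrom_seqs, both_strands=True) <= cfg.max_mismatches:
                continue
            blocks = tuple(tx.project_interval(t0, t0 + L))
            return seq, model, blocks

    def mismatched(self, k: int):
        """An exonic probe with exactly k interior substitutions planted."""
        cfg, rng = self.cfg, self.rng
        others = "ACGT"
        for _ in self._attempts(f"{k}-mismatch"):
            seq, model, blocks = self.exonic()
            positions = rng.choice(
                np.arange(1, cfg.probe_length - 1), size=k, replace=False
            )
            chars = list(seq)
            for pos in sorted(int(p) for p in positions):
                choices = [b for b in others if b != chars[pos]]
                chars[pos] = choices[int(rng.integers(3))]
            mutated = "".join(chars)
            # exactly one transcript window within the alignable horizon,
            # and it must sit at distance exactly k (the origin window)
            dists = [window_distances(mutated, t) for t in self.tx_seqs]
            close = np.concatenate(
                [d[d <= cfg.max_mismatches] for d in dists if d.size]
            )
            if close.size == 1 and int(close[0]) == k:
                return mutated, model, blocks

    def intronic(self):
        """A unique intron substring, in the gene's coding orientation."""
        cfg, rng = self.cfg, self.rng
        multi = [m for m in self.models if m.exon_count >= 2]
        for _ in self._attempts("intronic"):
            model = multi[int(rng.integers(len(multi)))]
            i = int(rng.integers(model.exon_count - 1))
            s, e = model.exon_ends[i], model.exon_starts[i + 1]
            if e - s < cfg.probe_length:
                continue
            p = int(rng.integers(s, e - cfg.probe_length + 1))
            gseq = self.genome[model.chrom][p : p + cfg.probe_length]
            seq = reverse_complement(gseq) if model.strand == "-" else gseq
            if not self.unique_in_genome(seq):
                continue
            if min_distance(seq, self.tx_seqs) <= cfg.max_mismatches:
                continue
            return seq, model, ((p, cfg.probe_length),)

    def intergenic(self):
        """A unique probe from the gene-free tail, >=2 kb from any gene."""
        cfg, rng = self.cfg, self.rng
        for _ in self._attempts("intergenic"):
            c = int(rng.integers(cfg.n_chroms))
            chrom = f"chr{c + 1}"
            lo = cfg.chrom_length - cfg.gene_free_tail + 2000
            p = int(rng.integers(lo, cfg.chrom_length - cfg.probe_length + 1))
            seq = self.genome[chrom][p : p + cfg.probe_length]
            if not self.unique_in_genome(seq):
                continue
            if min_distance(seq, self.tx_seqs) <= cfg.max_mismatches:
                continue
            return seq, chrom, ((p, cfg.probe_length),)

    def unmappable(self):
        """A random sequence beyond the mismatch horizon of every window."""
        cfg, rng = self.cfg, self.rng
        bases = np.array(list("ACGT"))
        for _ in self._attempts("unmappable"):
            seq = "".join(rng.choice(bases, size=cfg.probe_length))
            if (
                min_distance(seq, self.chrom_seqs, both_strands=True)
                > cfg.max_mismatches
                and min_distance(seq, self.tx_seqs) > cfg.max_mismatches
            ):
                return seq


def _blocks_str(blocks: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}:{l}" for s, l in blocks)


def simulate(config: SimConfig | None = None, outdir=None) -> SimResult:
    """Generate genome, gene models, probes, SNPs and the truth table.

    With *outdir* set, writes ``genome.fa``, ``genes.genepred``,
    ``probes.tsv``, ``snps.vcf`` and ``truth.tsv`` there (formats the
    pipeline's own readers consume) and records the paths in the result.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome = _random_genome(cfg, rng)
    models = _place_genes(cfg, rng)
    needs_genes = (
        cfg.n_exonic + cfg.n_junction + cfg.n_intronic + cfg.n_snp_bearing
        + sum(cfg.n_mismatched.values())
    )
    if not models and needs_genes:
        raise ValueError("gene-dependent probe classes need n_genes > 0")
    db = build_insilico_mrna(models, genome) if models else ReferenceDB({}, {})
    sampler = _Sampler(cfg, rng, genome, models, db)

    probes: list[Probe] = []
    snps: list[tuple[str, int, str, str, str]] = []
    rows: list[dict] = []

    def add(pid, seq, cls, gene, chrom, strand, blocks, k=0, snp_positions=()):
        probes.append(Probe(pid, seq))
        rows.append(
            {
                "probe_id": pid,
                "class": cls,
                "true_gene": gene,
                "true_chrom": chrom,
                "true_strand": strand,
                "true_blocks": _blocks_str(blocks) if blocks else "",
                "planted_mismatches": k,
                "planted_snps": ";".join(str(p) for p in snp_positions),
            }
        )

    for i in range(cfg.n_exonic):
        seq, model, blocks = sampler.exonic()
        add(f"exonic_{i:03d}", seq, "exonic", model.gene_symbol, model.chrom,
            model.strand, blocks)
    for i in range(cfg.n_junction):
        seq, model, blocks = sampler.junction()
        add(f"junction_{i:03d}", seq, "junction", model.gene_symbol, model.chrom,
            model.strand, blocks)
    for k in sorted(cfg.n_mismatched):
        for i in range(cfg.n_mismatched[k]):
            seq, model, blocks = sampler.mismatched(k)
            add(f"mismatch{k}_{i:03d}", seq, "mismatched", model.gene_symbol,
                model.chrom, model.strand, blocks, k=k)
    for i in range(cfg.n_snp_bearing):
        seq, model, blocks = sampler.exonic()
        start, length = blocks[0]
        n_snp = int(rng.integers(1, 3))
        offs = sorted(
            int(o) for o in rng.choice(np.arange(length), size=n_snp, replace=False)
        )
        positions = []
        for off in offs:
            pos0 = start + off
            ref_base = genome[model.chrom][pos0]
            alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(3))]
            snps.append(
                (model.chrom, pos0, f"snp_{len(snps):04d}", ref_base, alt)
            )
            positions.append(pos0 + 1)
        add(f"snp_{i:03d}", seq, "snp_bearing", model.gene_symbol, model.chrom,
            model.strand, blocks, snp_positions=positions)
    for i in range(cfg.n_intronic):
        seq, model, blocks = sampler.intronic()
        add(f"intronic_{i:03d}", seq, "intronic", model.gene_symbol, model.chrom,
            model.strand, blocks)
    for i in range(cfg.n_intergenic):
        seq, chrom, blocks = sampler.intergenic()
        add(f"intergenic_{i:03d}", seq, "intergenic", "", chrom, "+", blocks)
    for i in range(cfg.n_unmappable):
        seq = sampler.unmappable()
        add(f"unmappable_{i:03d}", seq, "unmappable", "", "", "", ())

    truth = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "class", "true_gene", "true_chrom", "true_strand",
            "true_blocks", "planted_mismatches", "planted_snps",
        ],
    )
    result = SimResult(
        genome=genome, models=models, db=db, probes=probes,
        snps=sorted(snps, key=lambda s: (s[0], s[1], s[2])), truth=truth,
    )
    if outdir is not None:
        result.paths = _write_files(cfg, result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _write_files(cfg: SimConfig, res: SimResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.genepred",
        "probes": outdir / "probes.tsv",
        "vcf": outdir / "snps.vcf",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in res.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["genes"], "w") as fh:
        for m in res.models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            fh.write(
                f"{m.tx_id}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t{m.tx_end}\t"
                f"{m.cds_start}\t{m.cds_end}\t{m.exon_count}\t{starts}\t{ends}\t"
                f"0\t{m.gene_symbol}\n"
            )
    with open(paths["probes"], "w") as fh:
        fh.write("Probe_Id\tProbe_Sequence\n")
        for p in res.probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\n")
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in res.genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, sid, ref, alt in res.snps:
            fh.write(f"{chrom}\t{pos0 + 1}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\n")
    res.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
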