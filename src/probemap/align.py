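"""Step-wise all-best-hits probe alignment.

Probes are first aligned to the in-silico mRNA reference allowing 0
mismatches; probes left unaligned are retried with the allowance increased by
one, up to a maximum (default 4).  Only probes that fail every mRNA tier are
aligned to the genome, with the same step-wise loop, on both strands.  The
first tier that produces any hit wins and *all* hits at that tier are kept.

The internal aligner is ungapped: a hit is a placement of the full probe
against an equal-length reference window, scored by Hamming distance.  A
probe has no per-base qualities and every window with distance <= m must be
found, so candidate placements are generated by the pigeonhole principle:
split the probe into m+1 contiguous segments; any placement with <= m
mismatches leaves at least one segment mismatch-free, so an exact k-mer
lookup of each segment's prefix enumerates every candidate, which is then
verified by a full-length comparison.  Gapped alignments enter the pipeline
only through :func:`import_sam`.

``N`` bases never match anything (including another ``N``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .refdb import ReferenceDB, reverse_complement

__all__ = [
    "Probe",
    "AlignerConfig",
    "ProbeHit",
    "StepwiseResult",
    "KmerIndex",
    "build_kmer_index",
    "find_hits_at_tier",
    "align_stepwise",
    "write_sam",
    "import_sam",
    "SamImportResult",
    "read_probes",
]

_VALID_PROBE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Probe:
    """A short oligonucleotide probe (50 nt on Illumina expression arrays)."""

    probe_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or not _VALID_PROBE.match(seq):
            raise ValueError(
                f"probe {self.probe_id}: sequence must be non-empty over ACGTN"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignerConfig:
    """Tunable alignment parameters.

    max_mismatches
        Highest tier tried (default 4 for 50 nt probes).
    seed_kmer
        Upper bound on the exact-seed length; effective seed length is
        ``min(seed_kmer, probe_len // (m + 1))`` at tier ``m``.
    align_probe_strand_to_mrna
        ``"forward_only"`` (default; the in-silico mRNA is already in coding
        orientation and manifests are mRNA-sense) or ``"both"``.
    max_reported_hits
        Cap on hits per probe; exceeding it flags the probe instead of
        silently truncating.
    """

    max_mismatches: int = 4
    seed_kmer: int = 12
    align_probe_strand_to_mrna: str = "forward_only"
    max_reported_hits: int = 10000

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.seed_kmer < 4:
            raise ValueError("seed_kmer must be >= 4")
        if self.align_probe_strand_to_mrna not in ("forward_only", "both"):
            raise ValueError("align_probe_strand_to_mrna: forward_only or both")


@dataclass(frozen=True)
class ProbeHit:
    """One ungapped (or imported) placement of a probe on a reference.

    ``ops`` is a per-base operation string over M (match), X (mismatch),
    I (insertion to the reference) and D (deletion), in reference order.
    ``ref_offset`` is 0-based on the reference forward strand; for strand
    "-" hits the probe's reverse complement matches the forward reference.
    """

    probe_id: str
    ref_space: str  # "mrna" | "genome"
    ref_id: str
    ref_offset: int
    strand: str
    tier: int
    ops: str
    aligned_length: int

    @property
    def ref_end(self) -> int:
        return self.ref_offset + self.aligned_length

    def mismatches(self) -> int:
        return self.ops.count("X")


@dataclass
class StepwiseResult:
    """Outcome of the step-wise alignment of one probe."""

    probe_id: str
    outcome: str  # "mrna_hit" | "genome_hit" | "unaligned"
    hits: list[ProbeHit] = field(default_factory=list)
    winning_tier: int | None = None
    capped: bool = False  # hit count exceeded AlignerConfig.max_reported_hits


class KmerIndex:
    """Exact k-mer index over the forward strand of a reference collection.

    Lookup tables for several k are built lazily from the stored sequences
    (the pigeonhole seed length shrinks as the mismatch tier grows).  K-mers
    containing ``N`` are not indexed.
    """

    def __init__(self, references: Mapping[str, str], k: int = 12):
        if k < 1:
            raise ValueError("k must be >= 1")
        if not references:
            raise ValueError("reference collection is empty")
        self.references = {rid: seq.upper() for rid, seq in references.items()}
        self.k = k
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._build(k)

    def _build(self, k: int) -> None:
        table: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.references.items():
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((rid, off))
        self._tables[k] = table

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (ref_id, offset) with an exact forward-strand occurrence."""
        k = len(kmer)
        if k not in self._tables:
            self._build(k)
        return self._tables[k].get(kmer, [])


def build_kmer_index(references: Mapping[str, str], k: int = 12) -> KmerIndex:
    """Build a :class:`KmerIndex` over *references* with default seed size *k*."""
    return KmerIndex(references, k=k)


def _compare(probe_seq: str, window: str) -> tuple[int, str]:
    """Hamming distance and M/X ops string; N always mismatches."""
    ops = []
    nm = 0
    for p, r in zip(probe_seq, window):
        if p == r and p != "N":
            ops.append("M")
        else:
            ops.append("X")
            nm += 1
    return nm, "".join(ops)


def _segments(length: int, n: int) -> list[tuple[int, int]]:
    """Split [0, length) into n contiguous near-equal segments.

    Left-aligned: the remainder goes to the leftmost segments.
    """
    base, rem = divmod(length, n)
    out = []
    pos = 0
    for i in range(n):
        seg = base + (1 if i < rem else 0)
        out.append((pos, seg))
        pos += seg
    return out


def _search_oriented(
    seq: str,
    probe_id: str,
    index: KmerIndex,
    m: int,
    strand: str,
    ref_space: str,
) -> list[ProbeHit]:
    refs = index.references  # uppercased copy; keeps seeding and verify consistent
    L = len(seq)
    segs = _segments(L, m + 1)
    shortest = min(s for _, s in segs)
    seed_k = min(index.k, shortest)
    if seed_k < 1:
        return []
    candidates: set[tuple[str, int]] = set()
    for seg_start, _seg_len in segs:
        seed = seq[seg_start : seg_start + seed_k]
        if "N" in seed:
            continue
        for rid, off in index.lookup(seed):
            place = off - seg_start
            if 0 <= place <= len(refs[rid]) - L:
                candidates.add((rid, place))
    hits = []
    for rid, place in candidates:
        nm, ops = _compare(seq, refs[rid][place : place + L])
        if nm <= m:
            hits.append(
                ProbeHit(
                    probe_id=probe_id,
                    ref_space=ref_space,
                    ref_id=rid,
                    ref_offset=place,
                    strand=strand,
                    tier=nm,
                    ops=ops,
                    aligned_length=L,
                )
            )
    return hits


def find_hits_at_tier(
    probe: Probe,
    refs: Mapping[str, str],
    index: KmerIndex,
    m: int,
    strand_mode: str = "forward",
    ref_space: str = "mrna",
) -> list[ProbeHit]:
    """All ungapped placements of *probe* with Hamming distance <= *m*.

    ``strand_mode`` is ``"forward"`` or ``"both"``; reverse-strand hits are
    found by running the identical pigeonhole search on the
    reverse-complemented probe and are reported with strand "-" at
    forward-reference coordinates.  The returned ``tier`` of each hit is its
    actual mismatch count (<= m).  Hits are sorted (ref_id, ref_offset,
    strand) so output is byte-stable.
    """
    if m < 0:
        raise ValueError("mismatch allowance m must be >= 0")
    del refs  # placements are verified against the index's reference copy
    hits = _search_oriented(probe.sequence, probe.probe_id, index, m, "+", ref_space)
    if strand_mode == "both":
        hits += _search_oriented(
            reverse_complement(probe.sequence), probe.probe_id, index, m, "-", ref_space
        )
    hits.sort(key=lambda h: (h.ref_id, h.ref_offset, h.strand))
    return hits


def align_stepwise(
    probe: Probe,
    db: ReferenceDB | Mapping[str, str],
    genome: Mapping[str, str] | None,
    config: AlignerConfig | None = None,
    *,
    mrna_index: KmerIndex | None = None,
    genome_index: KmerIndex | None = None,
) -> StepwiseResult:
    """Step-wise alignment of one probe: mRNA tiers 0..max, then genome.

    Pre-built indexes may be passed to amortise index construction over a
    probe set; they must have been built over the same sequences.
    """
    config = config or AlignerConfig()
    if len(probe) < config.max_mismatches + 1:
        raise ValueError(
            f"probe {probe.probe_id}: length {len(probe)} too short for "
            f"{config.max_mismatches} mismatches"
        )
    mrna_refs = db.sequences() if isinstance(db, ReferenceDB) else dict(db)
    mrna_strand = (
        "both" if config.align_probe_strand_to_mrna == "both" else "forward"
    )
    if mrna_refs:
        if mrna_index is None:
            mrna_index = KmerIndex(mrna_refs, k=config.seed_kmer)
        for m in range(config.max_mismatches + 1):
            hits = find_hits_at_tier(
                probe, mrna_refs, mrna_index, m, mrna_strand, "mrna"
            )
            if hits:
                return _finish(probe.probe_id, "mrna_hit", hits, m, config)
    if genome is not None:
        genome_refs = {c: str(genome[c][:]) if not isinstance(genome[c], str)
                       else genome[c] for c in _genome_keys(genome)}
        if genome_index is None:
            genome_index = KmerIndex(genome_refs, k=config.seed_kmer)
        for m in range(config.max_mismatches + 1):
            hits = find_hits_at_tier(
                probe, genome_refs, genome_index, m, "both", "genome"
            )
            if hits:
                return _finish(probe.probe_id, "genome_hit", hits, m, config)
    return StepwiseResult(probe_id=probe.probe_id, outcome="unaligned")


def _genome_keys(genome) -> Iterable[str]:
    return list(genome.keys())


def _finish(
    probe_id: str, outcome: str, hits: list[ProbeHit], tier: int, config: AlignerConfig
) -> StepwiseResult:
    capped = len(hits) > config.max_reported_hits
    return StepwiseResult(
        probe_id=probe_id,
        outcome=outcome,
        hits=hits,
        winning_tier=tier,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def _ops_to_cigar(ops: str) -> list[tuple[int, int]]:
    """Collapse an ops string to pysam cigartuples (M/X both -> CIGAR M)."""
    opmap = {"M": 0, "X": 0, "I": 1, "D": 2}
    out: list[tuple[int, int]] = []
    for op in ops:
        code = opmap[op]
        if out and out[-1][0] == code:
            out[-1] = (code, out[-1][1] + 1)
        else:
            out.append((code, 1))
    return out


def _md_tag(ops: str, ref_window: str) -> str:
    """MD tag for an alignment, from its ops string and reference bases."""
    md = []
    run = 0
    rpos = 0
    i = 0
    while i < len(ops):
        op = ops[i]
        if op == "M":
            run += 1
            rpos += 1
            i += 1
        elif op == "X":
            md.append(str(run))
            run = 0
            md.append(ref_window[rpos])
            rpos += 1
            i += 1
        elif op == "D":
            md.append(str(run))
            run = 0
            deleted = []
            while i < len(ops) and ops[i] == "D":
                deleted.append(ref_window[rpos])
                rpos += 1
                i += 1
            md.append("^" + "".join(deleted))
        else:  # I consumes no reference
            i += 1
    md.append(str(run))
    return "".join(md)


def write_sam(
    results: Iterable[StepwiseResult],
    refs: Mapping[str, str],
    path,
    probes: Mapping[str, str] | None = None,
) -> None:
    """Write step-wise results as SAM (all best hits; first hit primary).

    *refs* maps every referenced ref_id (transcript or chromosome) to its
    sequence; sequences are needed to emit MD tags so per-base ops survive a
    round trip through :func:`import_sam`.  *probes* optionally maps
    probe_id to sequence so unaligned records carry SEQ.
    """
    ref_ids = list(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rid, "LN": len(refs[rid])} for rid in ref_ids],
    }
    tid = {rid: i for i, rid in enumerate(ref_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            if not res.hits:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = res.probe_id
                rec.is_unmapped = True
                if probes and res.probe_id in probes:
                    rec.query_sequence = probes[res.probe_id]
                out.write(rec)
                continue
            for i, hit in enumerate(res.hits):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = res.probe_id
                rec.reference_id = tid[hit.ref_id]
                rec.reference_start = hit.ref_offset
                rec.mapping_quality = 60
                rec.cigartuples = _ops_to_cigar(hit.ops)
                rec.is_reverse = hit.strand == "-"
                rec.is_secondary = i > 0
                if probes and res.probe_id in probes:
                    seq = probes[res.probe_id]
                    rec.query_sequence = (
                        reverse_complement(seq) if hit.strand == "-" else seq
                    )
                window = refs[hit.ref_id][hit.ref_offset : hit.ref_end]
                nm = sum(hit.ops.count(o) for o in "XID")
                rec.set_tag("NM", nm)
                rec.set_tag("MD", _md_tag(hit.ops, window))
                out.write(rec)


@dataclass
class SamImportResult:
    """Hits recovered from a SAM file plus skip counters."""

    hits: list[ProbeHit]
    n_unmapped: int = 0
    n_unreconstructable: int = 0

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


def _ops_from_record(rec: pysam.AlignedSegment) -> str | None:
    cigar = rec.cigartuples or []
    if any(code in (7, 8) for code, _ in cigar):  # =/X CIGAR: ops are explicit
        m = {7: "M", 8: "X", 0: "M", 1: "I", 2: "D"}
        return "".join(m[code] * n for code, n in cigar if code in m)
    if not rec.has_tag("MD"):
        return None
    ops = []
    for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
        if rpos is None:
            ops.append("I")
        elif qpos is None:
            ops.append("D")
        elif ref_base is not None and ref_base.islower():
            ops.append("X")  # pysam lower-cases the reference base at mismatches
        else:
            ops.append("M")
    return "".join(ops)


def import_sam(path, ref_space: str = "mrna") -> SamImportResult:
    """Import externally produced alignments (e.g. a BWA run) as probe hits.

    Per-base ops are reconstructed from an =/X CIGAR when present, otherwise
    from CIGAR + MD.  Unmapped records and records whose ops cannot be
    reconstructed are skipped and counted.
    """
    result = SamImportResult(hits=[])
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                result.n_unmapped += 1
                continue
            ops = _ops_from_record(rec)
            if ops is None or "M" not in ops:
                result.n_unreconstructable += 1
                continue
            aligned_length = sum(ops.count(o) for o in "MXD")
            result.hits.append(
                ProbeHit(
                    probe_id=rec.query_name,
                    ref_space=ref_space,
                    ref_id=rec.reference_name,
                    ref_offset=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    tier=ops.count("X"),
                    ops=ops,
                    aligned_length=aligned_length,
                )
            )
    return result


# ---------------------------------------------------------------------------
# probe manifest input
# ---------------------------------------------------------------------------

def read_probes(
    path,
    id_col: str = "Probe_Id",
    seq_col: str = "Probe_Sequence",
) -> list[Probe]:
    """Read probes from an Illumina-style TSV manifest or a FASTA file.

    FASTA is detected from the first non-blank character ('>'); otherwise the
    file is read as a tab-delimited table with a header row containing
    *id_col* and *seq_col*.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        return [Probe(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_col, seq_col):
        if col not in df.columns:
            raise ValueError(f"probe manifest missing column {col!r}")
    return [Probe(r[id_col], r[seq_col]) for _, r in df.iterrows()]
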