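"""Step-wise alignment: k-mer index, pigeonhole search, SAM round trip."""

import numpy as np
import pytest

import probemap as pm
from probemap.align import (
    AlignerConfig,
    KmerIndex,
    Probe,
    align_stepwise,
    find_hits_at_tier,
    import_sam,
    write_sam,
)
from probemap.refdb import reverse_complement

from conftest import brute_force_hits


class TestKmerIndex:
    def test_exact_kmer_occurrences(self):
        idx = KmerIndex({"r": "ACGTACGT"}, k=4)
        assert sorted(idx.lookup("ACGT")) == [("r", 0), ("r", 4)]
        assert idx.lookup("TTTT") == []

    def test_reference_shorter_than_k(self):
        idx = KmerIndex({"r": "ACG"}, k=4)
        assert idx.lookup("ACGT") == []

    def test_kmers_containing_n_skipped(self):
        idx = KmerIndex({"r": "ANGT"}, k=2)
        assert idx.lookup("AN") == []
        assert idx.lookup("NG") == []
        assert idx.lookup("GT") == [("r", 2)]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex({"r": "ACGT"}, k=0)


def _mutate(seq, positions, rng):
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


class TestFindHitsAtTier:
    def test_exact_substring_found_at_tier0(self):
        ref = {"r": "TTTTTACGTACGTACGTACGTTTTTT"}
        idx = KmerIndex(ref, k=8)
        probe = Probe("p", ref["r"][5:25])
        hits = find_hits_at_tier(probe, ref, idx, 0)
        assert [(h.ref_id, h.ref_offset, h.tier) for h in hits] == [("r", 5, 0)]
        assert hits[0].ops == "M" * 20

    def test_two_planted_substitutions_recovered(self):
        rng = np.random.default_rng(0)
        ref = {"r": "".join(rng.choice(list("ACGT"), size=400))}
        idx = KmerIndex(ref, k=8)
        seq = _mutate(ref["r"][100:150], [10, 30], rng)
        hits = find_hits_at_tier(Probe("p", seq), ref, idx, 2)
        oracle = brute_force_hits(seq, ref, 2)
        assert {(h.ref_id, h.ref_offset, h.strand) for h in hits} == set(oracle)
        assert ("r", 100, "+") in oracle

    def test_reverse_strand_hit_at_forward_coordinates(self):
        rng = np.random.default_rng(1)
        ref = {"r": "".join(rng.choice(list("ACGT"), size=300))}
        idx = KmerIndex(ref, k=8)
        seq = reverse_complement(ref["r"][40:90])
        hits = find_hits_at_tier(Probe("p", seq), ref, idx, 0, strand_mode="both")
        assert {(h.ref_id, h.ref_offset, h.strand) for h in hits} == {("r", 40, "-")}
        oracle = brute_force_hits(seq, ref, 0, both_strands=True)
        assert set(oracle) == {("r", 40, "-")}

    @pytest.mark.parametrize("m", range(5))
    def test_oracle_equivalence_random_refs(self, m):
        """Every placement the sliding-window oracle finds, the seeded
        search finds too, and nothing extra — for all tiers and strands."""
        rng = np.random.default_rng(100 + m)
        refs = {
            f"r{i}": "".join(rng.choice(list("ACGT"), size=800)) for i in range(4)
        }
        idx = KmerIndex(refs, k=12)
        for trial in range(8):
            src = refs[f"r{rng.integers(4)}"]
            start = rng.integers(0, len(src) - 50)
            seq = _mutate(src[start : start + 50], rng.choice(50, size=m, replace=False), rng)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            mine = find_hits_at_tier(Probe("p", seq), refs, idx, m, strand_mode="both")
            oracle = brute_force_hits(seq, refs, m, both_strands=True)
            assert {(h.ref_id, h.ref_offset, h.strand) for h in mine} == set(oracle)
            for h in mine:
                assert h.ops.count("X") == oracle[(h.ref_id, h.ref_offset, h.strand)]

    def test_pigeonhole_completeness_exhaustive(self):
        """On a tiny reference, enumerate every window and every mismatch
        tier: no placement with <= m mismatches may be missed."""
        rng = np.random.default_rng(5)
        ref = {"r": "".join(rng.choice(list("ACGT"), size=120))}
        idx = KmerIndex(ref, k=12)
        for start in range(0, 70, 7):
            base = ref["r"][start : start + 50]
            for m in range(5):
                seq = _mutate(base, rng.choice(50, size=m, replace=False), rng)
                mine = {
                    (h.ref_id, h.ref_offset)
                    for h in find_hits_at_tier(Probe("p", seq), ref, idx, m)
                }
                oracle = {
                    (r, o) for (r, o, s) in brute_force_hits(seq, ref, m)
                }
                assert oracle <= mine and mine == oracle

    def test_n_counts_as_mismatch_never_wildcard(self):
        ref = {"r": "A" * 30 + "CCGGTTCCGGAACCGGTTCCGG" + "A" * 30}
        idx = KmerIndex(ref, k=8)
        seq = ref["r"][25:55]
        n_seq = seq[:10] + "N" + seq[11:]
        assert not find_hits_at_tier(Probe("p", n_seq), ref, idx, 0)
        hits = find_hits_at_tier(Probe("p", n_seq), ref, idx, 1)
        assert any(h.ref_offset == 25 and h.tier == 1 for h in hits)

    def test_hits_sorted_deterministically(self):
        ref = {"a": "ACGT" * 30, "b": "ACGT" * 30}
        idx = KmerIndex(ref, k=8)
        hits = find_hits_at_tier(Probe("p", "ACGT" * 5), ref, idx, 0)
        keys = [(h.ref_id, h.ref_offset, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestAlignStepwise:
    def test_exact_transcript_probe_wins_tier0(self, tiny_db, tiny_genome):
        tx = tiny_db.transcripts["TXP"]
        probe = Probe("p", tx.sequence[10:60])
        res = align_stepwise(probe, tiny_db, tiny_genome)
        assert res.outcome == "mrna_hit" and res.winning_tier == 0
        assert all(h.ref_space == "mrna" for h in res.hits)

    def test_winning_tier_is_minimum_distance(self, tiny_db, tiny_genome):
        rng = np.random.default_rng(2)
        tx = tiny_db.transcripts["TXP"]
        seq = _mutate(tx.sequence[20:70], [5, 25, 44], rng)
        res = align_stepwise(Probe("p", seq), tiny_db, tiny_genome)
        assert res.outcome == "mrna_hit"
        oracle = brute_force_hits(seq, tiny_db.sequences(), 4)
        assert res.winning_tier == min(oracle.values())
        assert all(h.tier == res.winning_tier for h in res.hits)

    def test_junction_probe_needs_mrna_reference(self, tiny_db, tiny_genome):
        """A probe across an exon junction aligns via the mRNA but is
        unalignable on the genome — the central mappability property."""
        tx = tiny_db.transcripts["TXP"]
        boundary = tx.coord_map[1].tx_offset
        seq = tx.sequence[boundary - 25 : boundary + 25]
        via_mrna = align_stepwise(Probe("p", seq), tiny_db, tiny_genome)
        assert via_mrna.outcome == "mrna_hit"
        genome_only = align_stepwise(Probe("p", seq), {}, tiny_genome)
        assert genome_only.outcome == "unaligned"

    def test_far_random_probe_unaligned(self, tiny_db, tiny_genome):
        rng = np.random.default_rng(3)
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=50))
            refs = dict(tiny_db.sequences(), **tiny_genome)
            if not brute_force_hits(seq, refs, 4, both_strands=True):
                break
        res = align_stepwise(Probe("p", seq), tiny_db, tiny_genome)
        assert res.outcome == "unaligned" and res.hits == []

    def test_genome_fallback_searches_both_strands(self, tiny_db, tiny_genome):
        seq = reverse_complement(tiny_genome["chr2"][100:150])
        res = align_stepwise(Probe("p", seq), tiny_db, tiny_genome)
        assert res.outcome == "genome_hit"
        assert any(h.strand == "-" and h.ref_offset == 100 for h in res.hits)

    def test_too_short_probe_rejected(self, tiny_db, tiny_genome):
        with pytest.raises(ValueError):
            align_stepwise(Probe("p", "ACG"), tiny_db, tiny_genome)

    def test_max_mismatches_zero_gates_tiers(self, tiny_db, tiny_genome):
        rng = np.random.default_rng(4)
        tx = tiny_db.transcripts["TXP"]
        seq = _mutate(tx.sequence[30:80], [20], rng)
        res = align_stepwise(
            Probe("p", seq), tiny_db, None, AlignerConfig(max_mismatches=0)
        )
        assert res.outcome == "unaligned"

    def test_hit_cap_flags_probe(self, tiny_genome):
        refs = {"low": "ACGTACGTACGT" * 50}
        probe = Probe("p", "ACGTACGTACGT" * 4 + "AC")
        cfg = AlignerConfig(max_reported_hits=3)
        res = align_stepwise(probe, refs, None, cfg)
        assert res.capped


class TestSamRoundTrip:
    def test_sam_coordinates_and_tags(self, tmp_path):
        ref = {"r": "T" * 7 + "ACGTACGTAC" * 5 + "T" * 7}
        idx = KmerIndex(ref, k=10)
        seq = ref["r"][7:57]
        res = align_stepwise(Probe("p", seq), ref, None)
        path = tmp_path / "out.sam"
        write_sam([res], ref, path, probes={"p": seq})
        text = path.read_text()
        line = next(l for l in text.splitlines() if l.startswith("p\t"))
        fields = line.split("\t")
        assert fields[3] == "8"  # 1-based POS for 0-based offset 7
        assert fields[5] == "50M"
        assert "NM:i:0" in line

    def test_secondary_flag_on_extra_hits(self, tmp_path):
        import pysam

        ref = {"r": "AAACGCGTTTACGCAAACGCGTTTACGCAAACGCGTTTACGC"}
        idx = KmerIndex(ref, k=8)
        probe = Probe("p", "AAACGCGTTTACGC")
        hits = find_hits_at_tier(probe, ref, idx, 0)
        assert len(hits) >= 2
        res = pm.StepwiseResult("p", "mrna_hit", hits, 0)
        path = tmp_path / "two.sam"
        write_sam([res], ref, path)
        with pysam.AlignmentFile(str(path)) as fh:
            flags = [rec.is_secondary for rec in fh]
        assert flags.count(False) == 1 and flags.count(True) == len(hits) - 1

    def test_round_trip_preserves_hit_set(self, sim_result, tmp_path):
        refs = dict(sim_result.db.sequences())
        idx = KmerIndex(refs, k=12)
        results = []
        for p in sim_result.probes[:30]:
            res = align_stepwise(p, refs, None)
            if res.hits:
                results.append(res)
        path = tmp_path / "rt.sam"
        write_sam(results, refs, path, probes={p.probe_id: p.sequence for p in sim_result.probes})
        imported = import_sam(path, ref_space="mrna")
        orig = {
            (h.probe_id, h.ref_id, h.ref_offset, h.strand, h.ops)
            for r in results
            for h in r.hits
        }
        back = {
            (h.probe_id, h.ref_id, h.ref_offset, h.strand, h.ops)
            for h in imported.hits
        }
        assert orig == back

    def test_unmapped_records_counted(self, tmp_path):
        res = pm.StepwiseResult("ghost", "unaligned", [], None)
        path = tmp_path / "un.sam"
        write_sam([res], {"r": "ACGTACGT"}, path, probes={"ghost": "TTTT"})
        imported = import_sam(path)
        assert imported.n_unmapped == 1 and not imported.hits


class TestSamImportDecoding:
    def _roundtrip_record(self, tmp_path, cigar, md, seq):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "r", "LN": 1000}]}
        path = tmp_path / "ext.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = "q"
            rec.reference_id = 0
            rec.reference_start = 10
            rec.cigarstring = cigar
            rec.query_sequence = seq
            if md is not None:
                rec.set_tag("MD", md)
            out.write(rec)
        return import_sam(path).hits

    def test_md_tag_mismatch_decoded(self, tmp_path):
        hits = self._roundtrip_record(tmp_path, "50M", "49A0", "G" * 50)
        assert hits[0].ops == "M" * 49 + "X"
        assert hits[0].tier == 1

    def test_insertion_cigar_decoded(self, tmp_path):
        hits = self._roundtrip_record(tmp_path, "20M1I29M", "49", "G" * 50)
        ops = hits[0].ops
        assert ops[20] == "I" and ops.count("I") == 1
        assert hits[0].aligned_length == 49  # I consumes no reference

    def test_record_without_md_or_eqx_rejected(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "r", "LN": 1000}]}
        path = tmp_path / "bad.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = "q"
            rec.reference_id = 0
            rec.reference_start = 0
            rec.cigarstring = "50M"
            rec.query_sequence = "G" * 50
            out.write(rec)
        imported = import_sam(path)
        assert imported.n_unreconstructable == 1 and not imported.hits

    def test_eqx_cigar_decoded_without_md(self, tmp_path):
        hits = self._roundtrip_record(tmp_path, "30=1X19=", None, "G" * 50)
        assert hits[0].ops == "M" * 30 + "X" + "M" * 19


class TestProbeInput:
    def test_tsv_manifest(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("Probe_Id\tProbe_Sequence\np1\tACGTACGT\n")
        probes = pm.read_probes(p)
        assert probes == [Probe("p1", "ACGTACGT")]

    def test_fasta_manifest(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">p1\nACGTACGT\n")
        assert pm.read_probes(p) == [Probe("p1", "ACGTACGT")]

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tseq\np1\tACGT\n")
        with pytest.raises(ValueError, match="Probe_Id"):
            pm.read_probes(p)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            Probe("p", "ACGU")
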