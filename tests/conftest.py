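"""Shared fixtures: a tiny hand-built reference and one full synthetic run."""

import numpy as np
import pytest

import probemap as pm


def brute_force_hits(probe_seq, refs, max_mm, both_strands=False):
    """Independent sliding-window Hamming oracle.

    Returns {(ref_id, offset, strand): distance} for every window with
    distance <= max_mm.  N (either side) counts as mismatch.  Written
    directly from the definition, independent of the package's seeded
    search.
    """
    out = {}
    queries = [(probe_seq, "+")]
    if both_strands:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        rc = "".join(comp[b] for b in reversed(probe_seq))
        queries.append((rc, "-"))
    for rid, ref in refs.items():
        ref = ref.upper()
        r = np.frombuffer(ref.encode(), dtype=np.uint8)
        for q, strand in queries:
            L = len(q)
            if len(ref) < L:
                continue
            p = np.frombuffer(q.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(r, L)
            n = ord("N")
            d = ((win != p) | (win == n) | (p == n)).sum(axis=1)
            for off in np.nonzero(d <= max_mm)[0]:
                out[(rid, int(off), strand)] = int(d[off])
    return out


@pytest.fixture(scope="session")
def tiny_genome():
    # chr1 carries a 2-exon plus gene and a 2-exon minus gene, far apart
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return {"chr1": seq, "chr2": "".join(rng.choice(list("ACGT"), size=3000))}


@pytest.fixture(scope="session")
def tiny_models():
    return [
        pm.GeneModel("TXP", "GENEP", "chr1", "+", (100, 400), (250, 600),
                     cds_start=100, cds_end=600),
        pm.GeneModel("TXM", "GENEM", "chr1", "-", (2000, 2500), (2200, 2800),
                     cds_start=2000, cds_end=2800),
    ]


@pytest.fixture(scope="session")
def tiny_db(tiny_models, tiny_genome):
    return pm.build_insilico_mrna(tiny_models, tiny_genome)


@pytest.fixture(scope="session")
def sim_result(tmp_path_factory):
    """One default-configuration synthetic dataset, written to disk."""
    outdir = tmp_path_factory.mktemp("sim")
    return pm.simulate(pm.SimConfig(seed=7), outdir=outdir)


@pytest.fixture(scope="session")
def pipeline_run(sim_result, tmp_path_factory):
    """The full pipeline executed on the synthetic dataset."""
    outdir = tmp_path_factory.mktemp("run")
    annotations, summary = pm.run_pipeline(
        sim_result.paths["genome"],
        sim_result.paths["genes"],
        sim_result.paths["probes"],
        vcf_path=sim_result.paths["vcf"],
        outdir=outdir,
    )
    return {
        "annotations": {a.probe_id: a for a in annotations},
        "summary": summary,
        "outdir": outdir,
        "truth": sim_result.truth.set_index("probe_id"),
    }
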