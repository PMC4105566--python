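import math
import random

import pytest

from transqc.align import shares_kmer
from transqc.annotation import filter_hits, subject_coverage
from transqc.core_io import revcomp
from transqc.simulate import (
    HomopolymerErrorModel,
    gen_assembly_variants,
    gen_hit_table,
    gen_reads,
    gen_transcriptome,
    plant_ssrs,
)


def test_transcriptome_deterministic_and_in_range():
    t1 = gen_transcriptome(5, (300, 800), seed=1)
    t2 = gen_transcriptome(5, (300, 800), seed=1)
    assert t1 == t2
    for _, seq in t1:
        assert 300 <= len(seq) <= 800
        assert set(seq) <= set("ACGT")
    assert gen_transcriptome(5, (300, 800), seed=2) != t1


def test_transcriptome_gc_fraction():
    transcripts = gen_transcriptome(60, (1500, 2000), gc=0.40, seed=3)
    pooled = "".join(seq for _, seq in transcripts)
    assert len(pooled) >= 90_000
    gc = sum(base in "GC" for base in pooled) / len(pooled)
    assert abs(gc - 0.40) < 0.02


def test_transcripts_pairwise_kmer_disjoint():
    transcripts = gen_transcriptome(
        10, (300, 600), seed=5, disjoint_k=11, max_shared_kmers=0
    )
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            assert not shares_kmer(transcripts[i][1], transcripts[j][1], 11)


def test_error_free_reads_are_exact_substrings():
    transcripts = gen_transcriptome(6, (400, 900), seed=7)
    reads, truth = gen_reads(transcripts, n_reads=50, mean_len=200, seed=7)
    by_tid = dict(transcripts)
    for read in reads:
        tid, span, strand = truth.read_provenance[read.id]
        insert = by_tid[tid][span[0] : span[1]]
        if strand == "-":
            insert = revcomp(insert)
        assert read.seq == insert


def test_reads_deterministic_under_seed():
    transcripts = gen_transcriptome(4, (300, 500), seed=9)
    r1, _ = gen_reads(transcripts, n_reads=20, seed=13)
    r2, _ = gen_reads(transcripts, n_reads=20, seed=13)
    assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]


def test_certain_overcall_lengthens_every_homopolymer():
    transcripts = [("t0", "AAATTTGGGCCCAAATTT")]
    model = HomopolymerErrorModel(overcall_rate=1.0)
    reads, truth = gen_reads(
        transcripts, n_reads=5, mean_len=18, seed=1, min_len=18, error_model=model
    )
    for read in reads:
        _tid, span, strand = truth.read_provenance[read.id]
        insert = transcripts[0][1][span[0] : span[1]]
        if strand == "-":
            insert = revcomp(insert)
        runs = _runs(insert)
        expected = "".join(base * (n + 1 if n >= 2 else n) for base, n in runs)
        assert read.seq == expected


def _runs(seq):
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append((seq[i], j - i))
        i = j
    return out


def test_certain_undercall_shortens_every_homopolymer():
    transcripts = [("t0", "AATTGGCCAATTGGCC")]
    model = HomopolymerErrorModel(undercall_rate=1.0)
    reads, truth = gen_reads(
        transcripts, n_reads=3, mean_len=16, seed=2, min_len=16, error_model=model
    )
    for read in reads:
        assert len(read.seq) < 16


def test_adapter_flanking():
    adapter = "GCCTCCCTCGCGCCATCAG"
    transcripts = gen_transcriptome(3, (300, 500), seed=4)
    reads, _ = gen_reads(transcripts, n_reads=10, mean_len=100, adapter=adapter, seed=4)
    for read in reads:
        assert read.seq.startswith(adapter) and read.seq.endswith(adapter)


def test_variant_structure(small_dataset):
    variants = small_dataset["variants"]
    truth_asm, truth_m = variants["truth"]
    # every clustered read maps to the transcript it was sampled from
    for rid, cid in truth_m.items():
        assert small_dataset["truth"].read_provenance[rid][0] == cid
    split_asm, split_m = variants["split"]
    assert len(split_asm.contigs) == 2 * len(truth_asm.contigs)
    for contig in split_asm.contigs:
        base = contig.id.rsplit(".", 1)[0]
        parent = dict(small_dataset["transcripts"])[base]
        assert contig.consensus in parent
        cut = math.ceil(0.85 * len(parent))
        assert len(contig.consensus) == cut
    mut_asm, _ = variants["mutated"]
    for contig, truth_contig in zip(mut_asm.contigs, truth_asm.contigs):
        assert len(contig.consensus) == len(truth_contig.consensus)
        assert contig.consensus != truth_contig.consensus
        assert contig.members == truth_contig.members


def test_variants_deterministic(small_dataset):
    again = gen_assembly_variants(
        small_dataset["transcripts"],
        small_dataset["reads"],
        small_dataset["truth"],
        mutation_rate=0.05,
    )
    for name, (asm, mem) in small_dataset["variants"].items():
        asm2, mem2 = again[name]
        assert mem == mem2
        assert [(c.id, c.consensus, c.members) for c in asm.contigs] == [
            (c.id, c.consensus, c.members) for c in asm2.contigs
        ]


def test_hit_table_coverage_exact():
    subjects = {"s1": 200, "s2": 333}
    planted = [("q1", "s1", 0.95, 1e-30), ("q2", "s2", 0.42, 1e-12)]
    hits = gen_hit_table(subjects, planted, seed=6)
    for qid, sid, frac, _ev in planted:
        pair_hits = [h for h in hits if h.qid == qid and h.sid == sid]
        cov = subject_coverage(pair_hits, subjects[sid])
        assert cov == pytest.approx(round(frac * subjects[sid]) / subjects[sid])
    assert gen_hit_table(subjects, planted, seed=6) == hits


def test_hit_table_evalue_passthrough():
    subjects = {"s1": 100}
    hits = gen_hit_table(subjects, [("q1", "s1", 0.5, 1e-3)], seed=1)
    assert filter_hits(hits, 1e-5) == []
    assert filter_hits(hits, 1e-2) == hits


def test_hit_table_infeasible_coverage_rejected():
    with pytest.raises(ValueError):
        gen_hit_table({"s1": 100}, [("q1", "s1", 0.001, 1e-30)], seed=1)
    with pytest.raises(ValueError):
        gen_hit_table({"s1": 100}, [("q1", "s1", 1.5, 1e-30)], seed=1)
    with pytest.raises(KeyError):
        gen_hit_table({"s1": 100}, [("q1", "sX", 0.5, 1e-30)], seed=1)


def test_plant_ssrs_class_mix_and_determinism():
    records, planted = plant_ssrs(200, seed=8)
    records2, planted2 = plant_ssrs(200, seed=8)
    assert [(r.id, r.seq) for r in records] == [(r.id, r.seq) for r in records2]
    assert planted == planted2
    classes = {l.cls for l in planted}
    assert {"tetra", "penta", "tri"} <= classes  # dominant classes present
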