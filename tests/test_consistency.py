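import random

import pytest

from transqc.consistency import (
    assembly_eci,
    assembly_ici,
    evaluate_assemblies,
    pair_eci,
    read_ici,
)
from transqc.core_io import Assembly, Contig, Read
from transqc.simulate import gen_transcriptome

from oracles import dp_local_align


def random_dna(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


def test_read_equal_to_consensus_substring_scores_100(rng):
    consensus = random_dna(rng, 400)
    read = Read(id="r", seq=consensus[100:250])
    assert read_ici(read, consensus) == 100.0


def test_partial_mapping_penalized_by_full_read_length(rng):
    """A read with 10 unalignable tail bases out of 100 scores about 90."""
    consensus = random_dna(rng, 300)
    tail = "".join(
        {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in consensus[290:300]
    )
    read = Read(id="r", seq=consensus[200:290] + tail)
    score, ident = max(
        dp_local_align(read.seq, consensus),
        dp_local_align(read.seq, consensus[::-1].translate(str.maketrans("ACGT", "TGCA"))),
    )
    assert read_ici(read, consensus) == pytest.approx(100.0 * ident / 100)
    assert 88.0 <= read_ici(read, consensus) <= 92.0


def test_substitutions_lower_ici_proportionally(rng):
    consensus = random_dna(rng, 300)
    read_seq = list(consensus[100:200])
    for pos in (10, 30, 50, 70, 90):
        read_seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read_seq[pos]]
    ici = read_ici(Read(id="r", seq="".join(read_seq)), consensus)
    assert ici == pytest.approx(95.0)


def test_ici_monotone_in_consensus_substitutions(rng):
    consensus = random_dna(rng, 500)
    reads = {
        f"r{i}": Read(id=f"r{i}", seq=consensus[i * 40 : i * 40 + 120]) for i in range(5)
    }
    previous = 101.0
    mutable = list(consensus)
    positions = rng.sample(range(500), 10)
    scores = []
    for n_subs in range(0, 11, 2):
        seq = list(consensus)
        for pos in positions[:n_subs]:
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        contig = Contig(id="c", consensus="".join(seq), members=list(reads))
        asm = Assembly(contigs=[contig], name=f"m{n_subs}")
        result = assembly_ici(asm, reads, {rid: "c" for rid in reads})
        scores.append(result.mean_ici)
    assert scores[0] == 100.0
    assert all(a >= b for a, b in zip(scores, scores[1:]))


def test_assembly_ici_errors(rng):
    consensus = random_dna(rng, 100)
    contig = Contig(id="c1", consensus=consensus, members=["r1"])
    asm = Assembly(contigs=[contig])
    with pytest.raises(KeyError, match="r1"):
        assembly_ici(asm, {}, {"r1": "c1"})
    with pytest.raises(ValueError, match="nothing to score"):
        assembly_ici(Assembly(contigs=[]), {}, {})


def test_duplicated_contig_eci_is_exactly_100(rng):
    seq = random_dna(rng, 350)
    a = Contig(id="a", consensus=seq, members=[])
    b = Contig(id="b", consensus=seq, members=[])
    assert pair_eci(a, b) == 100.0


def test_contained_contig_scores_100(rng):
    seq = random_dna(rng, 500)
    a = Contig(id="a", consensus=seq, members=[])
    b = Contig(id="b", consensus=seq[200:], members=[])  # last 60% of a
    assert pair_eci(a, b) == 100.0


def test_unrelated_contigs_score_low():
    transcripts = gen_transcriptome(6, (450, 550), seed=23, max_shared_kmers=0)
    contigs = [Contig(id=t, consensus=s, members=[]) for t, s in transcripts]
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            assert pair_eci(contigs[i], contigs[j]) < 10.0


def test_pair_eci_rejects_self_pair(rng):
    a = Contig(id="a", consensus=random_dna(rng, 50), members=[])
    with pytest.raises(ValueError):
        pair_eci(a, a)


def test_assembly_eci_flags_duplicates_not_unrelated():
    transcripts = gen_transcriptome(5, (400, 600), seed=31, max_shared_kmers=0)
    contigs = [Contig(id=t, consensus=s, members=[]) for t, s in transcripts]
    result = assembly_eci(Assembly(contigs=contigs, name="null"))
    assert result.n_flagged == 0
    assert 0.0 <= result.mean_eci < 10.0
    dup = contigs + [Contig(id="dup", consensus=contigs[0].consensus, members=[])]
    result2 = assembly_eci(Assembly(contigs=dup, name="dup"))
    assert result2.per_contig["dup"] == ("t0000", 100.0)
    assert result2.per_contig["t0000"] == ("dup", 100.0)
    assert result2.n_flagged == 2


def test_single_contig_assembly_warns_and_returns_zero(rng, caplog):
    asm = Assembly(contigs=[Contig(id="c", consensus=random_dna(rng, 100), members=[])])
    with caplog.at_level("WARNING"):
        result = assembly_eci(asm)
    assert result.mean_eci == 0.0 and result.n_flagged == 0
    assert "at least 2" in caplog.text


def test_split_variant_every_contig_flagged(small_dataset):
    asm, _membership = small_dataset["variants"]["split"]
    result = assembly_eci(asm)
    assert result.n_flagged == len(asm.contigs)
    for _partner, score in result.per_contig.values():
        assert score > 75.0


def test_truth_assembly_mean_ici_is_exactly_100(small_dataset):
    asm, membership = small_dataset["variants"]["truth"]
    result = assembly_ici(asm, small_dataset["reads_by_id"], membership)
    assert result.mean_ici == 100.0
    assert result.n_reads_scored == sum(len(c.members) for c in asm.contigs)


def test_shuffled_reads_score_below_truth(small_dataset):
    reads = small_dataset["reads_by_id"]
    truth_asm, truth_m = small_dataset["variants"]["truth"]
    shuf_asm, shuf_m = small_dataset["variants"]["shuffled"]
    truth_ici = assembly_ici(truth_asm, reads, truth_m).mean_ici
    shuf_ici = assembly_ici(shuf_asm, reads, shuf_m).mean_ici
    assert shuf_ici < truth_ici


def test_evaluate_ranks_truth_first_and_is_order_invariant(small_dataset):
    reads = small_dataset["reads_by_id"]
    cands = [
        (asm, reads, mem, None)
        for name, (asm, mem) in small_dataset["variants"].items()
        if name in {"truth", "mutated", "split"}
    ]
    rows = evaluate_assemblies(cands)
    assert rows[0].assembly_name == "truth"
    reordered = evaluate_assemblies(list(reversed(cands)))
    assert [r.assembly_name for r in reordered] == [r.assembly_name for r in rows]
    for row in rows:
        assert row.n_unigenes == row.n_contigs + (
            row.n_unigenes - row.n_contigs
        )  # structural identity holds
        assert 0.0 <= row.mean_ici <= 100.0
        assert 0.0 <= row.mean_eci <= 100.0


def test_evaluate_annotation_tiebreak(rng):
    """Equal-ICI candidates are separated by annotated-unigene count."""
    from transqc.core_io import TabularHit

    seq = random_dna(rng, 300)
    reads = {"r1": Read(id="r1", seq=seq[:100]), "r2": Read(id="r2", seq=seq[100:200])}
    contig = Contig(id="c", consensus=seq, members=["r1", "r2"])

    def make(name):
        return Assembly(contigs=[Contig(id="c", consensus=seq, members=["r1", "r2"])], name=name)

    hit = TabularHit(
        qid="c", sid="s1", pident=95.0, aln_len=50, mismatches=2, gapopens=0,
        qstart=1, qend=150, sstart=1, send=50, evalue=1e-30, bitscore=120.0,
    )
    membership = {"r1": "c", "r2": "c"}
    rows = evaluate_assemblies(
        [
            (make("without_hits"), reads, membership, []),
            (make("with_hits"), reads, membership, [hit]),
        ]
    )
    assert rows[0].assembly_name == "with_hits"
    assert rows[0].n_annotated == 1 and rows[1].n_annotated == 0


def test_evaluate_requires_candidates():
    with pytest.raises(ValueError):
        evaluate_assemblies([])
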