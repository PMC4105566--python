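"""Synthetic 454-style data generator.

Produces every input the other modules consume: random transcripts, reads
sampled from them (optionally adapter-flanked, optionally with homopolymer
over/undercall and substitution errors), assembly variants with known
read-to-contig truth, planted SSR sequences, and planted tabular homology
hits. Ground truth is recorded alongside each output so module results can
be checked exactly.

Defaults echo the study conditions this toolkit targets at roughly 1/100
scale: reads average 554 bases, transcripts span 300-2000 bases at GC 0.40,
and the planted SSR class mix follows the observed transcriptome-wide
frequencies (tetra 35.7%, penta 30.8%, tri 16.3%, hexa 13.4%, di 4.0%).

All randomness flows through :class:`random.Random` seeded explicitly, so
output is byte-identical across platforms for a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .align import shares_kmer
from .core_io import Assembly, Contig, Read, TabularHit, revcomp
from .ssr import DEFAULT_MIN_UNITS, CLASS_SIZES, SsrLocus, canonical_motif, find_ssrs, is_primitive

import random

DEFAULT_READ_LEN = 554
DEFAULT_LEN_RANGE = (300, 2000)
DEFAULT_GC = 0.40

# observed SSR class frequencies in the target transcriptome, normalized
DEFAULT_SSR_CLASS_MIX = {
    "tetra": 0.3568,
    "penta": 0.3075,
    "tri": 0.1630,
    "hexa": 0.1337,
    "di": 0.0398,
}


@dataclass
class HomopolymerErrorModel:
    """454-style error model: per-homopolymer +/-1 length errors plus
    uniform substitutions. Rates are per homopolymer run (length >= 2) and
    per base respectively."""

    overcall_rate: float = 0.0
    undercall_rate: float = 0.0
    subst_rate: float = 0.0


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    transcripts: list[tuple[str, str]]
    read_provenance: dict[str, tuple[str, tuple[int, int], str]]
    planted_ssrs: list[SsrLocus] = field(default_factory=list)
    planted_full_length: set[str] = field(default_factory=set)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "transcripts": [{"id": t, "length": len(s)} for t, s in self.transcripts],
            "read_provenance": {
                rid: {"transcript": tid, "span": list(span), "strand": strand}
                for rid, (tid, span, strand) in sorted(self.read_provenance.items())
            },
            "planted_ssrs": [
                {
                    "seq_id": l.seq_id, "start": l.start, "end": l.end,
                    "motif": l.motif, "n_repeats": l.n_repeats, "cls": l.cls,
                }
                for l in self.planted_ssrs
            ],
            "planted_full_length": sorted(self.planted_full_length),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def count_shared_kmers(a: str, b: str, k: int = 11) -> int:
    """Number of distinct k-mers of ``b`` (either strand) present in ``a``."""
    if len(a) < k or len(b) < k:
        return 0
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    kmers_b = {b[i : i + k] for i in range(len(b) - k + 1)}
    rb = revcomp(b)
    kmers_b.update(rb[i : i + k] for i in range(len(rb) - k + 1))
    return len(kmers_a & kmers_b)


def _random_seq(rng: random.Random, length: int, gc: float) -> str:
    half_gc, half_at = gc / 2.0, (1.0 - gc) / 2.0
    return "".join(
        rng.choices("ACGT", weights=[half_at, half_gc, half_gc, half_at], k=length)
    )


def gen_transcriptome(
    n: int,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    disjoint_k: int = 11,
    max_shared_kmers: int = 8,
) -> list[tuple[str, str]]:
    """Random unrelated transcripts.

    Sequences are i.i.d. with the given GC content; any sequence sharing
    more than ``max_shared_kmers`` exact ``disjoint_k``-mers (either strand)
    with an earlier one is resampled, keeping pairwise alignments between
    distinct transcripts negligible — the null condition the redundancy
    index is tested against. ``max_shared_kmers=0`` demands strict pairwise
    k-mer disjointness, feasible at small scales; the default ceiling of 8
    stays feasible for chance k-mer collisions between kilobase-scale
    sequences while still capping any spurious alignment at a few dozen
    columns — far below the redundancy merge threshold.
    """
    if n < 1:
        raise ValueError("need at least one transcript")
    rng = random.Random(seed)
    transcripts: list[tuple[str, str]] = []
    for i in range(n):
        for _attempt in range(200):
            length = rng.randint(*len_range)
            seq = _random_seq(rng, length, gc)
            if all(
                count_shared_kmers(prev, seq, disjoint_k) <= max_shared_kmers
                for _, prev in transcripts
            ):
                break
        else:  # pragma: no cover - astronomically unlikely at these sizes
            raise RuntimeError("could not sample a k-mer-disjoint transcript")
        transcripts.append((f"t{i:04d}", seq))
    return transcripts


def _apply_homopolymer_errors(seq: str, rng: random.Random, model: HomopolymerErrorModel) -> str:
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 2:
            roll = rng.random()
            if roll < model.overcall_rate:
                run = run + run[0]
            elif roll < model.overcall_rate + model.undercall_rate:
                run = run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _apply_substitutions(seq: str, rng: random.Random, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, base in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != base])
    return "".join(chars)


def gen_reads(
    transcripts: Sequence[tuple[str, str]],
    n_reads: int,
    mean_len: int = DEFAULT_READ_LEN,
    adapter: Optional[str] = None,
    error_model: Optional[HomopolymerErrorModel] = None,
    seed: int = 0,
    min_len: int = 40,
) -> tuple[list[Read], SimTruth]:
    """Sample reads as substrings of transcripts, either strand.

    Read lengths are Gaussian around ``mean_len`` (sd 15%), clipped to the
    transcript. With ``adapter`` set, the full adapter is attached to both
    read ends. Homopolymer and substitution errors apply to the insert only,
    after strand selection; provenance records the error-free source span.
    """
    if n_reads < 1:
        raise ValueError("need at least one read")
    rng = random.Random(seed)
    reads: list[Read] = []
    provenance: dict[str, tuple[str, tuple[int, int], str]] = {}
    for i in range(n_reads):
        tid, tseq = transcripts[rng.randrange(len(transcripts))]
        length = int(round(rng.gauss(mean_len, 0.15 * mean_len)))
        length = max(min_len, min(length, len(tseq)))
        start = rng.randint(0, len(tseq) - length)
        span = (start, start + length)
        strand = rng.choice("+-")
        insert = tseq[span[0] : span[1]]
        if strand == "-":
            insert = revcomp(insert)
        if error_model is not None:
            insert = _apply_homopolymer_errors(insert, rng, error_model)
            insert = _apply_substitutions(insert, rng, error_model.subst_rate)
        seq = insert if adapter is None else adapter + insert + adapter
        rid = f"r{i:05d}"
        reads.append(Read(id=rid, seq=seq))
        provenance[rid] = (tid, span, strand)
    truth = SimTruth(
        transcripts=list(transcripts), read_provenance=provenance, seed=seed
    )
    return reads, truth


def gen_assembly_variants(
    transcripts: Sequence[tuple[str, str]],
    reads: Sequence[Read],
    truth: SimTruth,
    mutation_rate: float = 0.05,
    seed: Optional[int] = None,
) -> dict[str, tuple[Assembly, dict[str, str]]]:
    """Assembly variants with known truth, for exercising the indexes.

    * ``truth`` — one contig per transcript with >= 2 sampled reads, the
      transcript itself as consensus; transcripts with a single read leave it
      a singleton.
    * ``split`` — each truth contig as two fragments covering the first and
      last 85% of the transcript, a ~70% mutual overlap at perfect identity;
      reads go to the fragment containing their midpoint. The geometry is
      chosen so the redundancy index of a split pair (~100 * 0.70/0.85 = 82)
      sits safely above the conventional merge threshold of 75: every split
      gene is flagged.
    * ``mutated`` — truth consensi with i.i.d. substitutions at
      ``mutation_rate``.
    * ``shuffled`` — truth contigs with reads reassigned at random (negative
      control).
    """
    rng = random.Random(truth.seed + 1 if seed is None else seed)
    members: dict[str, list[str]] = {tid: [] for tid, _ in transcripts}
    for rid, (tid, _span, _strand) in sorted(truth.read_provenance.items()):
        members[tid].append(rid)
    seq_by_tid = dict(transcripts)

    truth_contigs: list[Contig] = []
    singles: list[str] = []
    for tid, _ in transcripts:
        if len(members[tid]) >= 2:
            truth_contigs.append(
                Contig(id=tid, consensus=seq_by_tid[tid], members=list(members[tid]))
            )
        else:
            singles.extend(members[tid])
    truth_membership = {
        rid: c.id for c in truth_contigs for rid in c.members
    }
    variants: dict[str, tuple[Assembly, dict[str, str]]] = {
        "truth": (
            Assembly(contigs=truth_contigs, singletons=list(singles), name="truth"),
            truth_membership,
        )
    }

    # split variant
    split_contigs: list[Contig] = []
    split_membership: dict[str, str] = {}
    for contig in truth_contigs:
        tseq = contig.consensus
        cut_hi = math.ceil(0.85 * len(tseq))
        cut_lo = len(tseq) - cut_hi
        frag_a = tseq[:cut_hi]
        frag_b = tseq[cut_lo:]
        members_a: list[str] = []
        members_b: list[str] = []
        for rid in contig.members:
            _tid, span, _strand = truth.read_provenance[rid]
            midpoint = (span[0] + span[1]) // 2
            if midpoint < cut_hi:
                members_a.append(rid)
                split_membership[rid] = f"{contig.id}.a"
            else:
                members_b.append(rid)
                split_membership[rid] = f"{contig.id}.b"
        split_contigs.append(Contig(id=f"{contig.id}.a", consensus=frag_a, members=members_a))
        split_contigs.append(Contig(id=f"{contig.id}.b", consensus=frag_b, members=members_b))
    variants["split"] = (
        Assembly(contigs=split_contigs, singletons=list(singles), name="split"),
        split_membership,
    )

    # mutated variant
    mutated_contigs = [
        Contig(
            id=c.id,
            consensus=_apply_substitutions(c.consensus, rng, mutation_rate),
            members=list(c.members),
        )
        for c in truth_contigs
    ]
    variants["mutated"] = (
        Assembly(contigs=mutated_contigs, singletons=list(singles), name="mutated"),
        dict(truth_membership),
    )

    # shuffled negative control: same contigs, reads reassigned at random
    if truth_contigs:
        all_members = [rid for c in truth_contigs for rid in c.members]
        assignment = [rng.randrange(len(truth_contigs)) for _ in all_members]
        buckets: dict[int, list[str]] = {i: [] for i in range(len(truth_contigs))}
        for rid, idx in zip(all_members, assignment):
            buckets[idx].append(rid)
        shuffled_contigs = [
            Contig(id=c.id, consensus=c.consensus, members=buckets[i])
            for i, c in enumerate(truth_contigs)
            if buckets[i]
        ]
        shuffled_membership = {
            rid: c.id for c in shuffled_contigs for rid in c.members
        }
        variants["shuffled"] = (
            Assembly(contigs=shuffled_contigs, singletons=list(singles), name="shuffled"),
            shuffled_membership,
        )
    return variants


def plant_ssrs(
    n_loci: int,
    class_mix: Mapping[str, float] | None = None,
    min_units: Mapping[str, int] | None = None,
    extra_units_max: int = 4,
    spacer_range: tuple[int, int] = (25, 60),
    seed: int = 0,
) -> tuple[list[Read], list[SsrLocus]]:
    """Sequences each carrying exactly one planted perfect SSR.

    Class is drawn from ``class_mix``; the motif is a random primitive motif
    of that length; unit count is the class minimum plus 0..``extra_units_max``.
    Each record is validated to contain exactly the planted locus (spacers
    are resampled otherwise), so detection must recover every locus exactly.
    """
    mix = dict(class_mix or DEFAULT_SSR_CLASS_MIX)
    classes = sorted(mix)
    weights = [mix[c] for c in classes]
    units_table = dict(DEFAULT_MIN_UNITS)
    if min_units:
        units_table.update(min_units)
    rng = random.Random(seed)
    records: list[Read] = []
    planted: list[SsrLocus] = []
    for i in range(n_loci):
        cls = rng.choices(classes, weights=weights, k=1)[0]
        m = CLASS_SIZES[cls]
        for _attempt in range(100):
            motif = "".join(rng.choice("ACGT") for _ in range(m))
            if not is_primitive(motif):
                continue
            units = units_table[cls] + rng.randint(0, extra_units_max)
            tract = motif * units
            left = _random_seq(rng, rng.randint(*spacer_range), DEFAULT_GC)
            right = _random_seq(rng, rng.randint(*spacer_range), DEFAULT_GC)
            seq = left + tract + right
            seq_id = f"ssr{i:05d}"
            found = find_ssrs(seq_id, seq, min_units)
            expected = SsrLocus(
                seq_id=seq_id,
                start=len(left),
                end=len(left) + len(tract),
                motif=motif,
                canonical=canonical_motif(motif),
                n_repeats=units,
                cls=cls,
            )
            if found == [expected]:
                records.append(Read(id=seq_id, seq=seq))
                planted.append(expected)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not plant an unambiguous SSR locus")
    return records, planted


def gen_hit_table(
    subjects: Mapping[str, int],
    planted: Sequence[tuple[str, str, float, float]],
    seed: int = 0,
) -> list[TabularHit]:
    """Tabular hits whose merged subject coverage per (query, subject) pair
    is the planted fraction, exact to the residue.

    ``planted`` rows are (qid, sid, coverage_frac, evalue); each becomes one
    or two overlapping HSPs whose subject-interval union has length
    ``round(coverage_frac * slen)``. Bit scores decrease monotonically with
    e-value so best-hit selection follows the planted e-values.
    """
    rng = random.Random(seed)
    hits: list[TabularHit] = []
    for qid, sid, frac, evalue in planted:
        if sid not in subjects:
            raise KeyError(f"unknown subject {sid!r}")
        slen = subjects[sid]
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"coverage fraction {frac} outside (0,1]")
        covered = int(round(frac * slen))
        if covered < 1:
            raise ValueError(f"coverage {frac} of subject length {slen} is < 1 residue")
        s0 = rng.randint(1, slen - covered + 1)  # 1-based start
        send_total = s0 + covered - 1
        bitscore = round(40.0 - 10.0 * math.log10(max(evalue, 1e-180)), 1)
        pident = round(rng.uniform(75.0, 99.0), 1)
        if covered >= 40 and rng.random() < 0.5:
            mid = s0 + covered // 2
            overlap = rng.randint(1, 10)
            spans = [(s0, min(mid + overlap, send_total)), (mid + 1, send_total)]
        else:
            spans = [(s0, send_total)]
        for sstart, send in spans:
            aln_res = send - sstart + 1
            hits.append(
                TabularHit(
                    qid=qid,
                    sid=sid,
                    pident=pident,
                    aln_len=aln_res,
                    mismatches=int(aln_res * (100.0 - pident) / 100.0),
                    gapopens=0,
                    qstart=1,
                    qend=3 * aln_res,
                    sstart=sstart,
                    send=send,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits
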