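"""Internal and External Consistency Indexes for assembly selection.

When no reference genome exists, the quality of a clustering-style
transcriptome assembly can be judged from two directions:

* **ICI (Internal Consistency Index)** — how faithfully each member read
  maps back onto the consensus of the contig it was assembled into. For one
  read, ICI = 100 * (matched bases in the best local alignment of the read
  against its consensus, either strand) / (read length). A read that maps
  end-to-end at 100% identity scores 100; partial mapping or mismatches
  lower the score. The denominator is the full read length, so a read whose
  tail the assembler ignored is penalized even if the aligned part is
  perfect.

* **ECI (External Consistency Index)** — how similar distinct contigs are
  to one another. For a contig pair, ECI = 100 * identity_frac *
  (alignment columns / length of the shorter contig), capped at 100. A
  contig duplicated verbatim, or wholly contained in another at perfect
  identity, scores 100; unrelated contigs score near 0. Per-contig ECI is
  taken against the best-scoring other contig, and values above a merge
  threshold (default 75) flag consensi so close that the assembler has
  probably split one gene across contigs.

An assembly is then ranked by mean ICI (higher is better), tie-broken by
the number of annotated unigenes, then by mean ECI (lower is better).
Singletons are excluded from ICI: a singleton trivially maps onto itself at
100 and, with singletons typically outnumbering clustered reads several
fold, would swamp the contig-quality signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .align import LocalAlignment, local_align
from .annotation import filter_hits
from .core_io import Assembly, Contig, Read, TabularHit

logger = logging.getLogger(__name__)

DEFAULT_MERGE_THRESHOLD = 75.0


@dataclass
class IciResult:
    """Per-read internal consistency scores for one assembly."""

    per_read: dict[str, float]
    mean_ici: float
    n_reads_scored: int


@dataclass
class EciResult:
    """Per-contig best-partner external consistency scores."""

    per_contig: dict[str, tuple[Optional[str], float]]
    mean_eci: float
    n_flagged: int
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD


@dataclass
class AssemblyEvaluation:
    """One row of the assembly-selection summary table."""

    assembly_name: str
    n_clustered_reads: int
    n_contigs: int
    mean_contig_len: float
    n_unigenes: int
    mean_unigene_len: float
    mean_ici: float
    mean_eci: float
    n_annotated: Optional[int] = None


@dataclass
class AlignParams:
    """Alignment knobs shared by both indexes."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    prefilter_k: Optional[int] = None


def read_ici(read: Read, consensus: str, params: AlignParams | None = None) -> float:
    """ICI of one read against its contig consensus, in [0, 100]."""
    if len(read.seq) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    params = params or AlignParams()
    aln = local_align(
        read.seq,
        consensus,
        match=params.match,
        mismatch=params.mismatch,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        both_strands=True,
        prefilter_k=params.prefilter_k,
    )
    if aln is None:
        return 0.0
    return min(100.0, 100.0 * aln.n_ident / len(read.seq))


def assembly_ici(
    assembly: Assembly,
    reads: Mapping[str, Read],
    membership: Mapping[str, str],
    params: AlignParams | None = None,
) -> IciResult:
    """Score every clustered read of the assembly against its consensus.

    Exactly the reads that are members of contigs are scored; singletons are
    excluded. A membership entry whose read id has no sequence is an error.
    """
    if not assembly.contigs:
        raise ValueError("nothing to score: assembly has no contigs")
    consensus_by_id = {c.id: c.consensus for c in assembly.contigs}
    per_read: dict[str, float] = {}
    for contig in assembly.contigs:
        consensus = consensus_by_id[contig.id]
        for rid in contig.members:
            if rid not in reads:
                raise KeyError(f"membership references unknown read {rid!r}")
            per_read[rid] = read_ici(reads[rid], consensus, params)
    # membership entries must be resolvable even if redundant with contigs
    for rid in membership:
        if rid not in reads:
            raise KeyError(f"membership references unknown read {rid!r}")
    mean = sum(per_read.values()) / len(per_read) if per_read else 0.0
    return IciResult(per_read=per_read, mean_ici=mean, n_reads_scored=len(per_read))


def pair_eci(a: Contig, b: Contig, params: AlignParams | None = None) -> float:
    """ECI between two distinct contigs, in [0, 100]."""
    if a.id == b.id:
        raise ValueError("pair_eci requires two distinct contigs")
    params = params or AlignParams()
    aln = local_align(
        a.consensus,
        b.consensus,
        match=params.match,
        mismatch=params.mismatch,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        both_strands=True,
        prefilter_k=params.prefilter_k,
    )
    return eci_from_alignment(aln, len(a.consensus), len(b.consensus))


def eci_from_alignment(aln: LocalAlignment | None, len_a: int, len_b: int) -> float:
    if aln is None:
        return 0.0
    shorter = min(len_a, len_b)
    value = 100.0 * aln.identity_frac * (aln.aln_cols / shorter)
    return min(100.0, value)


def assembly_eci(
    assembly: Assembly,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    params: AlignParams | None = None,
) -> EciResult:
    """Best-partner ECI for every contig of the assembly.

    Contigs whose best partner alignment does not exist contribute 0 to the
    mean. With fewer than two contigs there is nothing to compare: the result
    is an empty zero-mean record (warning logged).
    """
    contigs = assembly.contigs
    if len(contigs) < 2:
        logger.warning(
            "assembly %s has %d contig(s); ECI needs at least 2",
            assembly.name,
            len(contigs),
        )
        return EciResult(per_contig={}, mean_eci=0.0, n_flagged=0,
                         merge_threshold=merge_threshold)
    best: dict[str, tuple[Optional[str], float]] = {
        c.id: (None, 0.0) for c in contigs
    }
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            a, b = contigs[i], contigs[j]
            score = pair_eci(a, b, params)
            if score > best[a.id][1]:
                best[a.id] = (b.id, score)
            if score > best[b.id][1]:
                best[b.id] = (a.id, score)
    mean = sum(s for _, s in best.values()) / len(best)
    n_flagged = sum(1 for _, s in best.values() if s > merge_threshold)
    return EciResult(per_contig=best, mean_eci=mean, n_flagged=n_flagged,
                     merge_threshold=merge_threshold)


def _mean_len(lengths: Sequence[int]) -> float:
    return sum(lengths) / len(lengths) if lengths else 0.0


def evaluate_assemblies(
    candidates: Sequence[
        tuple[Assembly, Mapping[str, Read], Mapping[str, str], Optional[Iterable[TabularHit]]]
    ],
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    evalue_max: float = 1e-5,
    params: AlignParams | None = None,
) -> list[AssemblyEvaluation]:
    """Evaluate candidate assemblies and rank them.

    Each candidate is (assembly, reads, membership, optional homology hits on
    its unigenes). Ranking: highest mean ICI, then most annotated unigenes
    (distinct query ids with hits passing the e-value filter; candidates
    without a hit table tie at None), then lowest mean ECI. Output order is
    independent of input order apart from deterministic id tie-breaks.
    """
    if not candidates:
        raise ValueError("no candidate assemblies supplied")
    rows: list[AssemblyEvaluation] = []
    for assembly, reads, membership, hits in candidates:
        ici = assembly_ici(assembly, reads, membership, params)
        eci = assembly_eci(assembly, merge_threshold, params)
        read_lengths = {rid: len(r.seq) for rid, r in reads.items()}
        contig_lens = [len(c.consensus) for c in assembly.contigs]
        unigene_lens = contig_lens + [
            read_lengths[rid] for rid in assembly.singletons if rid in read_lengths
        ]
        n_annotated = None
        if hits is not None:
            n_annotated = len({h.qid for h in filter_hits(list(hits), evalue_max)})
        rows.append(
            AssemblyEvaluation(
                assembly_name=assembly.name,
                n_clustered_reads=assembly.n_clustered_reads,
                n_contigs=len(assembly.contigs),
                mean_contig_len=_mean_len(contig_lens),
                n_unigenes=assembly.n_unigenes,
                mean_unigene_len=_mean_len(unigene_lens),
                mean_ici=ici.mean_ici,
                mean_eci=eci.mean_eci,
                n_annotated=n_annotated,
            )
        )
    rows.sort(
        key=lambda r: (
            -r.mean_ici,
            -(r.n_annotated if r.n_annotated is not None else -1),
            r.mean_eci,
            r.assembly_name,
        )
    )
    return rows
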