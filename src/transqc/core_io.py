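"""Shared sequence/assembly data model and readers/writers for external formats.

The toolkit operates on four kinds of external files:

* FASTA — sequencing reads and assembled unigenes (contigs + singletons);
* two-column TSV or minimal ACE — read-to-contig membership produced by a
  clustering assembler;
* 12- or 14-column tab-separated homology hits, the standard tabular output
  of protein similarity searches (``qseqid sseqid pident length mismatch
  gapopen qstart qend sstart send evalue bitscore [qlen slen]``);
* two-column subject-length TSV.

All intervals are stored internally as 0-based half-open pairs; tabular hit
coordinates keep their native 1-based inclusive convention and expose
half-open accessors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


@dataclass
class Read:
    """A sequencing read with optional adapter-masked intervals.

    ``masked`` holds 0-based half-open intervals flagged as adapter sequence;
    they are kept sorted, non-overlapping and inside ``[0, len(seq))``.
    """

    id: str
    seq: str
    masked: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        prev_end = 0
        for start, end in self.masked:
            if not (0 <= start < end <= len(self.seq)):
                raise ValueError(
                    f"read {self.id!r}: masked interval ({start},{end}) out of bounds"
                )
            if start < prev_end:
                raise ValueError(
                    f"read {self.id!r}: masked intervals overlap or are unsorted"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """A consensus sequence assembled from >= 2 member reads."""

    id: str
    consensus: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.consensus) < 1:
            raise ValueError(f"contig {self.id!r}: empty consensus")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"contig {self.id!r}: duplicate member read ids")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Assembly:
    """Unigene set: contigs (clustered reads) plus singleton reads.

    The unigene count is ``len(contigs) + len(singletons)``: every contig and
    every read that clustered with nothing is one putative transcript
    representative.
    """

    contigs: list[Contig]
    singletons: list[str] = field(default_factory=list)
    name: str = "assembly"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs:
            for rid in contig.members:
                if rid in seen:
                    raise ValueError(f"read {rid!r} appears in two contigs")
                seen.add(rid)
        for rid in self.singletons:
            if rid in seen:
                raise ValueError(f"read {rid!r} is both clustered and singleton")

    @property
    def n_unigenes(self) -> int:
        return len(self.contigs) + len(self.singletons)

    @property
    def n_clustered_reads(self) -> int:
        return sum(len(c.members) for c in self.contigs)


@dataclass
class TabularHit:
    """One row of 12/14-column tabular homology-search output.

    Query/subject coordinates are the native 1-based inclusive values; after
    loading, ``sstart <= send`` always holds and a minus ``strand`` records a
    reversed subject span. ``qlen``/``slen`` are filled only for 14-column
    input.
    """

    qid: str
    sid: str
    pident: float
    aln_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"
    qlen: int | None = None
    slen: int | None = None

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(f"hit {self.qid}->{self.sid}: qstart > qend")
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"hit {self.qid}->{self.sid}: pident out of [0,100]")
        if self.evalue < 0:
            raise ValueError(f"hit {self.qid}->{self.sid}: negative e-value")

    @property
    def q_interval0(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return self.qstart - 1, self.qend

    @property
    def s_interval0(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval."""
        return self.sstart - 1, self.send


SeqRecordLike = Union[Read, Contig]


def read_fasta(path: str | Path) -> list[Read]:
    """Read a FASTA file into :class:`Read` records.

    Sequences are uppercased and U is mapped to T. Duplicate ids are a hard
    error; an empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    reads: list[Read] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        reads.append(Read(id=record.id, seq=_normalize_seq(str(record.seq))))
    if not reads:
        logger.warning("FASTA file %s contains no records", path)
    return reads


def write_fasta(records: Iterable[SeqRecordLike], path: str | Path, width: int = 60) -> None:
    """Write reads or contigs as wrapped FASTA."""
    if width < 1:
        raise ValueError("line width must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            seq = rec.seq if isinstance(rec, Read) else rec.consensus
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_hit_fields(fields: Sequence[str], lineno: int) -> TabularHit:
    qstart, qend = int(fields[6]), int(fields[7])
    sstart, send = int(fields[8]), int(fields[9])
    strand = "+"
    if sstart > send:
        sstart, send = send, sstart
        strand = "-"
    hit = TabularHit(
        qid=fields[0],
        sid=fields[1],
        pident=float(fields[2]),
        aln_len=int(fields[3]),
        mismatches=int(fields[4]),
        gapopens=int(fields[5]),
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=float(fields[10]),
        bitscore=float(fields[11]),
        strand=strand,
    )
    if len(fields) == 14:
        hit.qlen = int(fields[12])
        hit.slen = int(fields[13])
    return hit


def read_tabular_hits(path: str | Path, n_cols: int = 12) -> list[TabularHit]:
    """Parse 12- or 14-column tabular homology hits.

    Comment lines starting with ``#`` are skipped. A data line with the wrong
    column count raises with its line number. Subject coordinates are
    normalized so ``sstart <= send``, recording strand.
    """
    if n_cols not in (12, 14):
        raise ValueError("n_cols must be 12 or 14")
    path = Path(path)
    hits: list[TabularHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            hits.append(_parse_hit_fields(fields, lineno))
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits back out in their native tabular convention.

    Minus-strand hits are emitted with subject coordinates re-reversed, so a
    read/write cycle is the identity.
    """
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            sstart, send = (h.send, h.sstart) if h.strand == "-" else (h.sstart, h.send)
            fields = [
                h.qid, h.sid, f"{h.pident:g}", str(h.aln_len), str(h.mismatches),
                str(h.gapopens), str(h.qstart), str(h.qend), str(sstart), str(send),
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            if h.qlen is not None and h.slen is not None:
                fields += [str(h.qlen), str(h.slen)]
            fh.write("\t".join(fields) + "\n")


def read_membership(path: str | Path, dialect: str = "tsv") -> dict[str, str]:
    """Load a read-id -> contig-id map from TSV or minimal ACE.

    The TSV dialect expects two tab-separated columns (read id, contig id).
    The ACE dialect interprets only ``CO`` lines (opening a contig) and ``AF``
    lines (assigning a read to the open contig); everything else is ignored.
    A read mapped to two contigs is a hard error.
    """
    path = Path(path)
    membership: dict[str, str] = {}

    def assign(rid: str, cid: str, lineno: int) -> None:
        if rid in membership and membership[rid] != cid:
            raise ValueError(
                f"{path}:{lineno}: read {rid!r} mapped to both "
                f"{membership[rid]!r} and {cid!r}"
            )
        membership[rid] = cid

    if dialect == "tsv":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                assign(fields[0], fields[1], lineno)
    elif dialect == "ace":
        current: str | None = None
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields:
                    continue
                if fields[0] == "CO":
                    current = fields[1]
                elif fields[0] == "AF":
                    if current is None:
                        raise ValueError(f"{path}:{lineno}: AF line before any CO line")
                    assign(fields[1], current, lineno)
    else:
        raise ValueError(f"unknown membership dialect {dialect!r}")
    return membership


def write_membership(membership: dict[str, str], path: str | Path) -> None:
    """Write a membership map as two-column TSV (sorted by read id)."""
    path = Path(path)
    with path.open("w") as fh:
        for rid in sorted(membership):
            fh.write(f"{rid}\t{membership[rid]}\n")


def read_subject_lengths(path: str | Path) -> dict[str, int]:
    """Load a two-column (subject id, length in residues) TSV."""
    path = Path(path)
    table: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            table[fields[0]] = int(fields[1])
    return table
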